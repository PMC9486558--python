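# Methods

This document describes the statistical model, the assumptions baked into
each module, the synthetic-cohort generator's scope, and the numerical
choices that matter for reproducing the results.

## 1. Scientific setting

Radiotherapy toxicity in breast-cancer patients appears to depend on the
*time of day* at which daily fractions are delivered, and that dependence
is modulated by common variants in circadian genes (CLOCK, PER3, RASD1).
The package analyses two endpoints from the REQUITE multi-centre breast
cohort design:

- **acute erythema** — skin reddening during/shortly after treatment
  (CTCAE grade ≥ 2 at follow-up, patients with baseline erythema excluded);
- **late atrophy** — skin thinning two years after treatment (worsening of
  ≥ 1 grade from baseline, patients with baseline grade ≥ 2 excluded; a
  sensitivity variant excludes baseline grade > 0).

Because the real cohort is access-controlled, the package ships a
synthetic generator that emulates the cohort's published summary
structure, and validates the modelling stack by *simulate-and-refit
recovery*: cohorts generated from a published coefficient set are pushed
through the full pipeline and the refitted odds ratios are compared with
the generating values.

## 2. Solar time (`chronotox.solar`)

Clock time is a poor circadian exposure because it confounds longitude,
time zone, and daylight-saving time. Treatment times are therefore
converted to **apparent solar time**:

```
solar = clock − utc_offset + longitude · (4 min/deg) + equation_of_time
```

- The **equation of time** and **solar declination** use the standard
  NOAA low-precision trigonometric series in the fractional year; these
  are accurate to well under a minute, far below the precision that
  matters here.
- **Day length** uses the sunrise-equation with zenith 90.833° (accounts
  for refraction and the solar disc). Polar day/night are flagged rather
  than raising.
- **DST** follows the EU rule at date granularity: last Sunday of March
  through the day before the last Sunday of October. Sites can override
  the rule or supply explicit UTC offsets per timestamp.

Per-patient schedules are summarised as the mean and standard deviation
of the per-fraction solar times (`mean_solar_time`, `sd_solar_time`).

## 3. Dose and endpoints (`chronotox.preprocess`)

Physical dose is converted to **biologically effective dose**:

```
BED = n · d · (1 + d / (α/β))
```

with boost BED added to whole-breast BED. Defaults are α/β = 10 Gy for
acute erythema and 3 Gy for late atrophy; both are configurable.

The exclusion cascade is applied in a fixed order and reported per rule:

1. endpoint-specific baseline rule (see §1);
2. wide schedules: `sd_solar_time` > 2 h;
3. completeness: any missing covariate used downstream.

A patient failing several rules is counted once, under the first rule
that caught them. The cascade is idempotent.

## 4. Time-of-day parameterisation

Time of day enters the model as a distance from a **time origin** — the
solar hour of peak (erythema) or trough-anchored (atrophy) toxicity:

```
time_dist = |mean_solar_time − origin|      (no 24 h wrap)
```

- Erythema uses origin 0.0, so `time_dist` is simply hours after solar
  midnight (risk increases through the day, OR 1.05/h).
- Atrophy uses origin 15.5 (15:30 solar); risk decreases with distance
  from mid-afternoon (OR 0.939/h in the base model).

When the origin is not fixed, `scan_time_origin` profiles AIC over a
grid of candidate origins and returns the arg-min (ties resolved to the
earliest origin). A single cohort's AIC profile is nearly flat for
origins outside the daytime treatment window — any out-of-window origin
makes the distance term linear in time-of-day over the bulk of patients —
so `time_origin_scan_experiment` sums the AIC profiles of independent
replicate cohorts (a joint AIC) before taking the arg-min, which
localises the generating origin to within one grid step.

## 5. Genetics (`chronotox.genetics`)

- Genotypes are allele-2 **dosages** (0/1/2, or fractional from
  imputation). VCFs are read with cyvcf2, preferring the `DS` format
  field and falling back to hard calls from `GT`.
- Hardy–Weinberg genotype probabilities `((1−q)², 2q(1−q), q²)` feed the
  **composite score** over CLOCK rs1801260 (q = 0.27), PER3 rs2087947
  (q = 0.31) and RASD1 rs11545787 (q = 0.25). The three SNPs sit on
  different chromosomes, so the score distribution is the exact
  convolution of the three independent genotype distributions. Per
  10,000 patients this yields 1427 with score 0, 632 triple
  heterozygotes, and 4 with score 6 (all computed, not stored).
- The unweighted 3-SNP score (`prs3`) and a weighted PRS (mean-imputed
  missing dosages) are available as model covariates.

## 6. Modelling (`chronotox.modelling`)

- **Fixed-effects logistic regression** wraps `statsmodels` `Logit`
  (Newton, tolerance 1e-10) behind `fit_logistic(ModelSpec, data)`.
  Categorical covariates are dummy-coded; interaction terms
  (`snp:time_dist`) require their main effects (hierarchy is enforced).
  Perfect separation and singular designs raise typed errors
  (`SeparationError`, `SingularDesignError`) instead of returning
  garbage.
- **Stepwise AIC**: at each step the single best add/drop move is taken
  (forced terms are never dropped); afterwards, terms with Wald p ≥ 0.05
  are pruned backward, again respecting hierarchy. If a pruning refit
  fails numerically, pruning stops and the current model is kept.
- **Random-intercept logistic** (site as cluster) is fitted by direct
  maximum likelihood with **adaptive Gauss–Hermite quadrature**: for
  each cluster an inner Newton iteration finds the posterior mode and
  curvature of the random intercept, quadrature nodes are recentred at
  the mode and rescaled by the curvature, and the marginal likelihood is
  accumulated with `logsumexp`. The outer optimiser is L-BFGS-B over
  (β, log σ); standard errors come from a numerical Hessian. With 10
  quadrature points this matches `lme4::glmer(nAGQ = 10)` to four
  decimals (checked in the test suite by calling R when available).
  Non-adaptive quadrature is *not* sufficient here: with cluster sizes
  in the hundreds the per-cluster posteriors are much narrower than the
  prior, and fixed nodes mis-place the mass.
- The **latent-scale ICC** is σ²/(σ² + π²/3); the published site
  random-intercept SD 0.59 gives ICC ≈ 0.1.
- **Cross-validated AUC** uses repeated stratified k-fold with
  fold-level fits by scikit-learn's `LogisticRegression(C = 1e6)` —
  effectively unpenalised, but a vanishing ridge keeps separated
  training folds finite. AUC is rank-based, so the ridge does not move
  it. AUCs are averaged over folds and repeats.
- **Power/alpha search** (`power_alpha`): given effect sizes and n, the
  per-test significance level needed to reach a target power is found by
  bisection on Monte-Carlo power estimates with common random numbers;
  unattainable targets are flagged rather than extrapolated.

## 7. Synthetic cohort generator (`chronotox.cohort`)

The generator emulates the *published summary structure* of the
eight-centre cohort; it does not attempt to reproduce individual-level
data. Scope and assumptions:

- **Sites**: the eight centres with their published latitude, longitude,
  time zone, cohort share, treatment-time means/SDs and wide-schedule
  (SD > 2 h) rates. One printed longitude carries a sign error relative
  to the city's true position; it is kept as printed because day length
  depends only on latitude and solar-time emulation adopts the printed
  summaries verbatim.
- **Schedules**: consecutive weekdays in 2015–2017; per-patient mean
  local times are truncated-normal around the site mean; fraction-level
  jitter SDs are lognormal (σ = 0.55) with the median calibrated per
  site so that P(SD > 2 h) matches the published rate.
- **Covariates**: BMI, surgery type, smoking, whole-breast and boost
  prescriptions drawn from plausible marginal distributions; genotypes
  are Hardy–Weinberg draws at the published allele frequencies.
- **Outcomes** follow a logistic model on the generating coefficient
  set. The intercept is calibrated by fixed-seed Monte Carlo so that the
  *analysis cohort* (after exclusions) hits the published prevalence
  (0.35 atrophy, 0.20 erythema). The calibration sample is conditioned
  on `sd_solar_time ≤ 2 h` because the wide-schedule exclusion is
  outcome-correlated whenever the model carries a schedule-SD term
  (erythema's OR 0.645 per hour of SD): calibrating on the full
  population would overshoot the included-cohort prevalence.
- **Site random intercepts** (SD configurable, default 0) add
  between-centre heterogeneity on the latent scale.
- CTCAE grades at baseline/follow-up are synthesised to be consistent
  with the drawn binary outcome, so the full preprocessing cascade
  (including dichotomisation) can run on generated data.
- Everything is driven by one `numpy` `default_rng` seed; identical
  configs produce identical cohorts, and the generating truth (term
  coefficients, intercept, site effects) is recorded alongside.

Generator parameters encode study conditions; they are never adjusted to
make a downstream check pass.

## 8. Recovery experiments and replicate counts

`recovery_experiment` refits the generating model on each of several
independently seeded cohorts of n = 5000 and averages the fitted odds
ratios. The Monte-Carlo error of such a mean scales as the per-replicate
spread over √(number of replicates), and the spread differs by term:
the atrophy `time_dist` OR is tightly estimated per cohort, while SNP
main-effect ORs (a 3-level dosage covariate) are noisier. Replicate
counts in the test suite and the reproduction script are therefore sized
per experiment (20 cohorts for the atrophy base model, 60 for the CLOCK
model, 100 for the erythema model) so that each mean's Monte-Carlo error
sits well inside its comparison tolerance. The estimator itself is
unbiased; the counts only control its variance.

## 9. Numerical choices (summary)

- `statsmodels` Newton with `tol=1e-10` for all fixed-effects fits.
- Adaptive Gauss–Hermite (10 nodes, inner Newton to 1e-10) + L-BFGS-B
  for the mixed model; `log σ` parameterisation with a floor of 1e-6 on
  σ to keep the degenerate boundary finite.
- `scipy.special.logsumexp` everywhere likelihoods are accumulated.
- Seeds: all randomness flows from explicit integer seeds; derived
  seeds are spawned via `numpy.random.SeedSequence` and reduced mod 2³¹.
- Ridge `C = 1e6` in CV fold fits (rank-based AUC is invariant to it).

## 10. Limitations

- The generator matches published *summaries*, not the joint
  distribution of the real cohort; covariate correlations (e.g. BMI ×
  smoking) are not modelled beyond what the outcome model induces.
- DST handling is at date granularity and uses the EU rule by default;
  historical or non-EU rules must be supplied explicitly.
- `time_dist` does not wrap around midnight; it is adequate for daytime
  treatment windows but would misbehave for origins near 0 combined
  with post-midnight treatment times.
- The mixed model supports a single random intercept (site); no random
  slopes or crossed effects.
- The AIC origin scan identifies the origin only up to grid resolution,
  and only reliably when profiles from several replicate cohorts are
  pooled (see §4).
- CTCAE grade synthesis is consistent with the binary outcome but is not
  a calibrated ordinal model of grade severity.
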