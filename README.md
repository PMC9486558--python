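# chronotox

Chronoradiotherapy toxicity analysis: does the **time of day** at which
breast-cancer radiotherapy fractions are delivered change the risk of
skin toxicity, and is that effect modulated by common variants in
circadian genes?

The package implements the full analysis stack for the REQUITE
multi-centre breast cohort design:

- conversion of fraction clock times to **apparent solar time**
  (equation of time, longitude, time zone, EU daylight-saving rule);
- **biologically effective dose** (BED) with endpoint-specific α/β;
- endpoint dichotomisation (acute erythema, late atrophy) and a
  reported, idempotent exclusion cascade;
- logistic models with a `|mean solar time − origin|` time term,
  SNP × time interactions, stepwise-AIC covariate selection, an AIC scan
  for the peak-toxicity origin, a hand-rolled **adaptive Gauss–Hermite
  random-intercept model** for between-centre heterogeneity, repeated
  cross-validated AUC, and a power/alpha search;
- Hardy–Weinberg **composite genotype scores** over CLOCK rs1801260,
  PER3 rs2087947 and RASD1 rs11545787;
- genotype-conditional **risk curves and optimal-treatment-time**
  recommendations;
- a deterministic **synthetic multi-centre cohort generator** that
  emulates the cohort's published summary structure (the real cohort is
  access-controlled) and powers simulate-and-refit validation.

See [docs/methods.md](docs/methods.md) for the model, assumptions and
numerical choices.

## Worked example

Simulate a cohort of 1727 patients whose late-atrophy outcomes follow
the CLOCK-augmented model, then run the full pipeline on the written
CSV files:

```bash
chronotox simulate --endpoint atrophy --model atrophy+rs1801260 \
    --n 1727 --seed 11 --outdir cohort
chronotox fit --patients cohort/patients.csv --fractions cohort/fractions.csv \
    --sites cohort/sites.csv --genotypes cohort/genotypes.csv \
    --endpoint atrophy --time-origin 15.5 --snps rs1801260 \
    --cv-repeats 3 --outdir run
```

Output (base stepwise model, SNP-augmented model, site-random-intercept
refit; odds ratios with 95% Wald CIs):

```
      model                term       or   ci_low  ci_high            p         aic    n
       base                 bmi 1.046628 1.024052 1.069701 4.199679e-05 1672.357609 1364
       base         surgery_wle 2.502219 1.973713 3.172243 3.546926e-14 1672.357609 1364
       base                 bed 1.015311 1.004510 1.026227 5.357794e-03 1672.357609 1364
       base   neoadj_non_anthra 1.577795 1.035327 2.404491 3.388205e-02 1672.357609 1364
       base          adj_anthra 1.445417 1.086807 1.922357 1.133729e-02 1672.357609 1364
       base           time_dist 0.919849 0.875392 0.966563 9.479719e-04 1672.357609 1364
 +rs1801260                 bmi 1.048003 1.025218 1.071295 2.907628e-05 1656.965486 1364
 +rs1801260         surgery_wle 2.543649 2.001966 3.231896 2.153013e-14 1656.965486 1364
 +rs1801260                 bed 1.015244 1.004367 1.026240 5.909291e-03 1656.965486 1364
 +rs1801260   neoadj_non_anthra 1.549724 1.012381 2.372273 4.373663e-02 1656.965486 1364
 +rs1801260          adj_anthra 1.436601 1.077186 1.915939 1.365978e-02 1656.965486 1364
 +rs1801260           time_dist 0.838876 0.783666 0.897975 4.235006e-07 1656.965486 1364
 +rs1801260           rs1801260 0.620929 0.429100 0.898516 1.148632e-02 1656.965486 1364
 +rs1801260 rs1801260:time_dist 1.167460 1.081583 1.260155 7.134080e-05 1656.965486 1364
base(mixed)                 bmi 1.046469 1.023849 1.069589 4.623655e-05 1674.127558 1364
base(mixed)         surgery_wle 2.522527 1.985414 3.204946 3.618342e-14 1674.127558 1364
base(mixed)                 bed 1.015378 1.004558 1.026314 5.238900e-03 1674.127558 1364
base(mixed)   neoadj_non_anthra 1.574235 1.031796 2.401848 3.527576e-02 1674.127558 1364
base(mixed)          adj_anthra 1.444391 1.085059 1.922721 1.175877e-02 1674.127558 1364
base(mixed)           time_dist 0.922346 0.876189 0.970933 2.027915e-03 1674.127558 1364
```

The generating values (time_dist OR 0.874, SNP OR 0.616, interaction
OR 1.13) sit inside the fitted confidence intervals. Adding
`chronotox predict` (same flags, plus an optional `--window`) writes
risk curves and per-genotype optimal treatment times:

```
      snp  dosage  optimal_time  predicted_risk  flat
rs1801260       0           8.0        0.202997 False
rs1801260       1           8.0        0.335597 False
rs1801260       2          15.5        0.268343 False
```

Carriers of two protective G alleles invert the time-of-day gradient:
their predicted atrophy risk is lowest mid-afternoon, while
non-carriers do best early in the morning.

From Python:

```python
import datetime as dt
from chronotox.solar import GeoSite, LocalTimestamp, local_to_solar
from chronotox.genetics import composite_score_distribution, all_heterozygote_probability
from chronotox.modelling import latent_icc

milan = GeoSite(name="Milan", latitude=45.5, longitude=9.2, utc_base_offset=1)
ts = LocalTimestamp(date=dt.date(2016, 7, 25), clock_time=14.0, site=milan)
print(round(local_to_solar(ts), 2))                              # 12.5
dist = composite_score_distribution()
print(round(dist[0] * 10_000))                                   # 1427
print(round(all_heterozygote_probability() * 10_000))            # 632
print(round(dist[6] * 10_000))                                   # 4
print(round(latent_icc(0.59), 3))                                # 0.096
```

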