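"""Logistic toxicity models: fitting, selection, time-origin scan, mixing.

The analysis centres on fixed-effects logistic regression of a dichotomous
toxicity endpoint on clinical covariates, biologically effective dose, and
the treatment-time term ``time_dist`` = |mean solar time - origin|.  On top
of that base model sit:

* stepwise AIC selection (single best add/drop move per step, then backward
  pruning of Wald-non-significant terms at p >= 0.05),
* SNP augmentation (dosage main effect plus dosage x time_dist interaction),
* an AIC scan over candidate time origins that locates the solar hour of
  peak toxicity,
* a confirmatory random-intercept (recruiting-centre) logistic model whose
  marginal likelihood is evaluated by Gauss-Hermite quadrature,
* repeated stratified cross-validated AUC, and a simulation-based power
  calculation for a per-allele test.

Fixed-effects fits delegate to statsmodels' Newton maximum-likelihood
logistic; inference is Wald (OR = exp(beta), 95% CI = exp(beta +/- 1.96 se))
matching the reporting convention of the fitted-model tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .genetics import hwe_genotype_probs

__all__ = [
    "ModelSpec",
    "FitResult",
    "MixedFitResult",
    "TimeScanResult",
    "SeparationError",
    "SingularDesignError",
    "design_matrix",
    "fit_logistic",
    "stepwise_select",
    "augment_with_snp",
    "scan_time_origin",
    "fit_mixed_logistic",
    "latent_icc",
    "cv_auc",
    "power_alpha",
    "PowerResult",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Perfect separation: some term predicts the outcome deterministically."""


class SingularDesignError(RuntimeError):
    """Collinear or constant design columns; carries their names."""


#: categorical covariates: reference level and the non-reference levels
#: that enter as treatment-coded dummies
CATEGORICAL_TERMS = {
    "smoking": ("never", ["ex_before", "ex_since", "current"]),
    "menopausal": ("post", ["pre", "peri"]),
}


@dataclass(frozen=True)
class ModelSpec:
    """A logistic model: outcome, ordered terms, and the time origin.

    Terms are analysis-table column names, plus the derived ``time_dist``
    term and products written ``a:b`` (both constituents must also appear —
    model hierarchy is enforced).
    """

    outcome: str = "outcome"
    terms: tuple[str, ...] = ()
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":", 1)
                if a not in self.terms or b not in self.terms:
                    raise ValueError(
                        f"interaction {t!r} lacks a constituent main effect"
                    )

    def with_terms(self, terms) -> "ModelSpec":
        return ModelSpec(self.outcome, tuple(terms), self.time_origin)

    def with_origin(self, origin: float) -> "ModelSpec":
        return ModelSpec(self.outcome, self.terms, origin)


def _expand_single(term: str, data: pd.DataFrame, origin: float) -> pd.DataFrame:
    if term == "time_dist":
        return pd.DataFrame(
            {"time_dist": np.abs(data["mean_solar_time"].to_numpy(float) - origin)},
            index=data.index,
        )
    if term == "surgery":
        vals = data["surgery"]
        return pd.DataFrame(
            {"surgery_wle": (vals == "wle").astype(float).where(vals.notna())},
            index=data.index,
        )
    if term in CATEGORICAL_TERMS:
        ref, levels = CATEGORICAL_TERMS[term]
        vals = data[term]
        out = {}
        for lv in levels:
            out[f"{term}_{lv}"] = (vals == lv).astype(float).where(vals.notna())
        return pd.DataFrame(out, index=data.index)
    col = data[term]
    if col.dtype == bool:
        col = col.astype(float)
    return pd.DataFrame({term: pd.to_numeric(col)}, index=data.index)


def design_matrix(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand a spec's terms into numeric design columns (no intercept).

    Returns the design frame and a map from each term to the columns it
    produced (categoricals expand to several dummies; interactions to the
    elementwise products of their constituents' columns).
    """
    blocks: dict[str, pd.DataFrame] = {}
    term_cols: dict[str, list[str]] = {}
    cols: list[pd.Series] = []
    for term in spec.terms:
        if ":" in term:
            a, b = term.split(":", 1)
            da = blocks[a] if a in blocks else _expand_single(a, data, spec.time_origin)
            db = blocks[b] if b in blocks else _expand_single(b, data, spec.time_origin)
            names = []
            for ca in da.columns:
                for cb in db.columns:
                    name = f"{ca}:{cb}"
                    cols.append((da[ca] * db[cb]).rename(name))
                    names.append(name)
            term_cols[term] = names
        else:
            block = _expand_single(term, data, spec.time_origin)
            blocks[term] = block
            term_cols[term] = list(block.columns)
            cols.extend(block[c] for c in block.columns)
    X = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=data.index)
    return X, term_cols


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    bad = [c for c, v in zip(X.columns, arr.T) if np.nanstd(v) == 0.0]
    if bad:
        raise SingularDesignError(f"constant design column(s): {bad}")
    full = np.column_stack([np.ones(len(arr)), arr])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        # identify offending columns via small R-diagonal entries
        _, rmat = np.linalg.qr(full)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(full.shape) * np.finfo(float).eps
        names = ["(intercept)"] + list(X.columns)
        bad = [names[i] for i in range(len(diag)) if diag[i] < tol]
        raise SingularDesignError(f"collinear design column(s): {bad or names}")


@dataclass
class FitResult:
    """A fitted fixed-effects logistic model with Wald inference."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    n: int
    term_cols: dict[str, list[str]] = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def odds_ratio(self, name: str) -> float:
        return float(np.exp(self.params[name]))

    def conf_int(self, name: str) -> tuple[float, float]:
        b, se = self.params[name], self.bse[name]
        return float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se))

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            if name == "const":
                continue
            lo, hi = self.conf_int(name)
            rows.append(
                {
                    "term": name,
                    "coef": self.params[name],
                    "se": self.bse[name],
                    "or": np.exp(self.params[name]),
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.pvalues[name],
                }
            )
        return pd.DataFrame(rows)


def fit_logistic(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood logistic fit of ``spec`` on complete-case data.

    Newton iterations to tight gradient tolerance; perfect separation and
    singular designs raise dedicated errors naming the offending terms.
    """
    y = pd.to_numeric(data[spec.outcome]).to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X, term_cols = design_matrix(spec, data)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"design has missing values in columns {bad}")
    _check_design(X)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise SeparationError(f"perfect separation or singular fit: {e}") from e
    return FitResult(
        spec=spec,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        cov=res.cov_params(),
        llf=float(res.llf),
        aic=float(res.aic),
        n=len(y),
        term_cols=term_cols,
    )


def _droppable(terms: tuple[str, ...], term: str, forced) -> bool:
    """A main effect cannot leave while one of its interactions remains."""
    if term in forced:
        return False
    return not any(":" in t and term in t.split(":", 1) for t in terms if t != term)


def stepwise_select(
    data: pd.DataFrame,
    initial_terms,
    candidate_terms=None,
    forced=(),
    spec: ModelSpec | None = None,
    p_remove: float = 0.05,
) -> tuple[ModelSpec, FitResult]:
    """Stepwise AIC selection with forward/backward replacement.

    Each step tries dropping every current non-forced term and adding every
    absent candidate, takes the single move with the lowest AIC, and stops
    when no move improves it.  Afterwards, remaining terms whose Wald p
    (the smallest p among a term's design columns) is >= ``p_remove`` are
    dropped one at a time, largest p first, refitting after each drop.
    """
    if spec is None:
        spec = ModelSpec(terms=tuple(initial_terms))
    else:
        spec = spec.with_terms(tuple(initial_terms))
    candidates = list(candidate_terms) if candidate_terms is not None else list(initial_terms)
    forced = set(forced)

    def _fit(terms):
        try:
            return fit_logistic(spec.with_terms(terms), data)
        except (SeparationError, SingularDesignError, ValueError):
            return None

    current = tuple(initial_terms)
    best_fit = _fit(current)
    if best_fit is None:
        raise RuntimeError("initial model failed to fit")
    while True:
        moves: list[tuple[float, tuple[str, ...]]] = []
        for t in current:
            if _droppable(current, t, forced):
                trial = tuple(x for x in current if x != t)
                f = _fit(trial)
                if f is not None:
                    moves.append((f.aic, trial))
        for t in candidates:
            if t not in current:
                trial = current + (t,)
                f = _fit(trial)
                if f is not None:
                    moves.append((f.aic, trial))
        if not moves:
            break
        best_aic, best_terms = min(moves, key=lambda m: m[0])
        if best_aic < best_fit.aic - 1e-9:
            current = best_terms
            best_fit = _fit(current)
        else:
            break

    # backward pruning of non-significant terms
    while True:
        worst, worst_p = None, p_remove
        for t in current:
            if not _droppable(current, t, forced):
                continue
            pcols = [best_fit.pvalues[c] for c in best_fit.term_cols[t]]
            p = min(pcols)
            if p >= worst_p:
                worst, worst_p = t, p
        if worst is None:
            break
        trial = tuple(x for x in current if x != worst)
        if not trial:
            break
        refit = _fit(trial)
        if refit is None:
            # dropping this term breaks the fit; keep the current model
            break
        current, best_fit = trial, refit
    return best_fit.spec, best_fit


def augment_with_snp(base: ModelSpec, snp: str, data: pd.DataFrame) -> FitResult:
    """Fit base + SNP dosage + SNP x time_dist interaction.

    Requires the base model to contain the ``time_dist`` term; a constant
    dosage column surfaces as a singular-design error.
    """
    if "time_dist" not in base.terms:
        raise ValueError("base model must contain the time_dist term")
    spec = base.with_terms(base.terms + (snp, f"{snp}:time_dist"))
    return fit_logistic(spec, data)


@dataclass
class TimeScanResult:
    """AIC profile over candidate time origins."""

    origins: np.ndarray
    aics: np.ndarray
    best_origin: float

    @property
    def best_aic(self) -> float:
        return float(np.nanmin(self.aics))


def scan_time_origin(
    spec: ModelSpec, data: pd.DataFrame, grid_step: float = 0.5
) -> TimeScanResult:
    """Scan candidate peak-toxicity origins on a grid over [0, 24).

    For each origin, ``time_dist`` is rebuilt as |mean solar time - origin|
    and the model refit; the profile of AICs and the arg-min origin (ties
    broken toward the earliest hour) are returned.  Failed fits are
    recorded as NaN and excluded from the arg-min.
    """
    n_steps = 24.0 / grid_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("grid_step must divide 24 evenly")
    origins = np.arange(0.0, 24.0, grid_step)
    aics = np.full(origins.shape, np.nan)
    for i, t0 in enumerate(origins):
        try:
            aics[i] = fit_logistic(spec.with_origin(float(t0)), data).aic
        except (SeparationError, SingularDesignError, ValueError):
            continue
    if np.all(np.isnan(aics)):
        raise RuntimeError("every origin on the grid failed to fit")
    best = float(origins[np.nanargmin(aics)])  # nanargmin takes first minimum
    return TimeScanResult(origins=origins, aics=aics, best_origin=best)


@dataclass
class MixedFitResult(FitResult):
    """Random-intercept logistic fit (marginal ML via quadrature)."""

    random_intercept_sd: float = 0.0
    random_intercept_sd_se: float = float("nan")

    @property
    def icc(self) -> float:
        return latent_icc(self.random_intercept_sd)


def fit_mixed_logistic(
    spec: ModelSpec,
    data: pd.DataFrame,
    group: str = "site_name",
    n_quad: int = 25,
) -> MixedFitResult:
    """Random-intercept logistic regression, one intercept per group.

    The marginal likelihood integrates the cluster intercepts out with
    adaptive Gauss-Hermite quadrature (``n_quad`` nodes, centred and
    scaled at each cluster's posterior mode) and is maximised over
    (beta, log sd) with L-BFGS-B.  With one node this reduces to the
    Laplace approximation; the default node count makes the quadrature
    error negligible next to sampling error.  Standard errors come from
    the numerical Hessian at the optimum.
    """
    groups, labels = pd.factorize(data[group])
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    y = pd.to_numeric(data[spec.outcome]).to_numpy(float)
    X, term_cols = design_matrix(spec, data)
    Xc = sm.add_constant(X, has_constant="add")
    names = list(Xc.columns)
    Xa = Xc.to_numpy(float)
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(wts)
    n_groups = len(labels)

    def nll(theta: np.ndarray) -> float:
        beta, log_sd = theta[:-1], theta[-1]
        sd = max(np.exp(log_sd), 1e-6)
        eta = Xa @ beta  # (n,)

        # cluster-mode Newton: maximise sum_i ll(eta_i + b) - b^2/(2 sd^2)
        b = np.zeros(n_groups)
        for _ in range(50):
            z = eta + b[groups]
            mu = special.expit(z)
            grad = np.bincount(groups, weights=y - mu, minlength=n_groups) - b / sd**2
            curv = np.bincount(groups, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / sd**2
            step = grad / curv
            b += step
            if np.abs(step).max() < 1e-10:
                break
        tau = 1.0 / np.sqrt(curv)  # (C,) adaptive scale from the final curvature

        # adaptive GH: b_ck = b_c + sqrt(2) tau_c x_k
        bk = b[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (C, K)
        z = eta[:, None] + bk[groups, :]  # (n, K)
        ll_obs = y[:, None] * z - np.logaddexp(0.0, z)
        ll_grp = np.zeros((n_groups, len(nodes)))
        np.add.at(ll_grp, groups, ll_obs)
        log_prior = -0.5 * (bk / sd) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(sd)
        log_int = special.logsumexp(
            log_w[None, :] + nodes[None, :] ** 2 + ll_grp + log_prior, axis=1
        ) + 0.5 * np.log(2.0) + np.log(tau)
        return -float(log_int.sum())

    start_fit = fit_logistic(spec, data)
    x0 = np.append(start_fit.params.to_numpy(), np.log(0.3))
    res = optimize.minimize(nll, x0, method="L-BFGS-B")
    # retry from a larger starting sd if needed
    if not res.success:
        res2 = optimize.minimize(nll, np.append(start_fit.params.to_numpy(), np.log(1.0)), method="Nelder-Mead", options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
        if not res2.success:
            raise RuntimeError(f"mixed model did not converge: {res.message}; {res2.message}")
        res = res2
    theta = res.x
    sd_hat = float(np.exp(theta[-1]))

    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta, nll)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    k_fixed = Xa.shape[1]
    cov = pd.DataFrame(cov_all[:k_fixed, :k_fixed], index=names, columns=names)
    params = pd.Series(theta[:k_fixed], index=names)
    bse = pd.Series(np.sqrt(np.clip(np.diag(cov.to_numpy()), 0, None)), index=names)
    zstat = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(zstat)), index=names)
    # delta method: se(sd) = sd * se(log sd)
    var_log_sd = float(cov_all[-1, -1])
    sd_se = sd_hat * np.sqrt(var_log_sd) if var_log_sd > 0 else float("nan")
    llf = -float(res.fun)
    k = k_fixed + 1
    return MixedFitResult(
        spec=spec,
        params=params,
        bse=bse,
        pvalues=pvals,
        cov=cov,
        llf=llf,
        aic=2 * k - 2 * llf,
        n=len(y),
        term_cols=term_cols,
        random_intercept_sd=sd_hat,
        random_intercept_sd_se=sd_se,
    )


def latent_icc(random_intercept_sd: float) -> float:
    """Latent-scale intraclass correlation: sd^2 / (sd^2 + pi^2/3)."""
    if random_intercept_sd < 0:
        raise ValueError("random-intercept sd must be >= 0")
    v = random_intercept_sd**2
    return v / (v + np.pi**2 / 3.0)


def cv_auc(
    spec: ModelSpec,
    data: pd.DataFrame,
    folds: int = 4,
    repeats: int = 100,
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold cross-validated AUC.

    For each repeat, the cohort is partitioned into ``folds`` strata-
    balanced folds; the model is fitted on the complement of each fold and
    scored on it by rank-based AUC.  Returns the mean over folds x repeats
    plus the empirical 95% interval of the fold AUCs.  A degenerate fold
    (one outcome class, possible only at tiny n) triggers a redraw of that
    repeat with a warning.
    """
    y = pd.to_numeric(data[spec.outcome]).to_numpy(float)
    X, _ = design_matrix(spec, data)
    Xc = X.to_numpy(float)  # sklearn supplies the intercept itself
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    rep = 0
    attempts = 0
    while rep < repeats:
        attempts += 1
        if attempts > repeats * 5:
            raise RuntimeError("too many degenerate cross-validation draws")
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        fold_aucs = []
        ok = True
        for train, test in skf.split(Xc, y):
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                ok = False
                break
            # near-unpenalised ridge keeps separated training folds finite
            # without materially changing the ranking (AUC is rank-based)
            clf = LogisticRegression(C=1e6, max_iter=2000)
            clf.fit(Xc[train], y[train])
            p = clf.predict_proba(Xc[test])[:, 1]
            fold_aucs.append(roc_auc_score(y[test], p))
        if not ok:
            warnings.warn("degenerate fold; repeat redrawn")
            continue
        aucs.extend(fold_aucs)
        rep += 1
    arr = np.asarray(aucs)
    return {
        "auc": float(arr.mean()),
        "ci": (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
        "n_folds": len(arr),
    }


@dataclass
class PowerResult:
    """Significance threshold achieving a target power, by simulation."""

    alpha: float | None
    target_power: float
    attained_power: float
    power_ci: tuple[float, float]
    attainable: bool
    n_replicates: int


def _hwe_dosages(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    probs = hwe_genotype_probs(maf)
    return rng.choice(np.array([0.0, 1.0, 2.0]), size=n, p=probs)


def _calibrated_intercept(beta: float, maf: float, prevalence: float) -> float:
    probs = np.asarray(hwe_genotype_probs(maf))
    dose = np.array([0.0, 1.0, 2.0])

    def marg(b0):
        return float(probs @ special.expit(b0 + beta * dose)) - prevalence

    return optimize.brentq(marg, -20, 20)


def _vectorized_wald_p(y: np.ndarray, dose: np.ndarray) -> np.ndarray:
    """Wald p-values for the dosage slope, fitted per replicate row.

    ``y`` and ``dose`` are (R, n); a 2-parameter (intercept, slope) Newton
    solver runs vectorised across replicates.
    """
    R, n = y.shape
    b0 = np.zeros(R)
    b1 = np.zeros(R)
    for _ in range(50):
        eta = b0[:, None] + b1[:, None] * dose
        mu = special.expit(eta)
        w = mu * (1 - mu)
        r = y - mu
        g0 = r.sum(axis=1)
        g1 = (r * dose).sum(axis=1)
        s00 = w.sum(axis=1)
        s01 = (w * dose).sum(axis=1)
        s11 = (w * dose * dose).sum(axis=1)
        det = s00 * s11 - s01 * s01
        db0 = (s11 * g0 - s01 * g1) / det
        db1 = (s00 * g1 - s01 * g0) / det
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < 1e-10:
            break
    eta = b0[:, None] + b1[:, None] * dose
    mu = special.expit(eta)
    w = mu * (1 - mu)
    s00 = w.sum(axis=1)
    s01 = (w * dose).sum(axis=1)
    s11 = (w * dose * dose).sum(axis=1)
    det = s00 * s11 - s01 * s01
    var_b1 = s00 / det
    z = b1 / np.sqrt(var_b1)
    return 2 * stats.norm.sf(np.abs(z))


def power_alpha(
    n: int,
    prevalence: float,
    per_allele_or: float,
    maf: float,
    target_power: float = 0.8,
    n_replicates: int = 2000,
    seed: int = 0,
) -> PowerResult:
    """Significance threshold alpha at which a per-allele Wald test reaches
    the target power, by simulation.

    Genotypes are HWE dosages at the given MAF; outcomes follow a logistic
    model with the per-allele OR and an intercept calibrated to the target
    prevalence.  One common set of ``n_replicates`` simulated p-values is
    drawn, and alpha is located by bisection of the (monotone) empirical
    power curve on that set.  If even alpha = 0.5 cannot reach the target
    power, the result is flagged unattainable rather than raising.
    """
    if not (0 < prevalence < 1 and 0 < maf < 1 and 0 < target_power < 1):
        raise ValueError("parameters out of range")
    rng = np.random.default_rng(seed)
    beta = np.log(per_allele_or)
    b0 = _calibrated_intercept(beta, maf, prevalence)
    dose = _hwe_dosages(rng, n_replicates * n, maf).reshape(n_replicates, n)
    p_out = special.expit(b0 + beta * dose)
    y = (rng.random((n_replicates, n)) < p_out).astype(float)
    pvals = _vectorized_wald_p(y, dose)

    def power(alpha: float) -> float:
        return float(np.mean(pvals < alpha))

    if power(0.5) < target_power:
        att = power(0.5)
        se = np.sqrt(att * (1 - att) / n_replicates)
        return PowerResult(None, target_power, att, (att - Z95 * se, att + Z95 * se), False, n_replicates)
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if power(mid) < target_power:
            lo = mid
        else:
            hi = mid
    alpha = hi
    att = power(alpha)
    se = np.sqrt(att * (1 - att) / n_replicates)
    return PowerResult(
        float(alpha), target_power, att, (att - Z95 * se, att + Z95 * se), True, n_replicates
    )
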