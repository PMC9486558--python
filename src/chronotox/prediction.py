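"""Genotype-conditional risk over treatment time and scheduling advice.

Given a fitted toxicity model whose time term is distance from a peak
origin and which may carry a genotype dosage plus dosage x time
interaction, this module evaluates predicted risk curves (with delta-method
confidence bands on the linear predictor), finds the treatment time at
which genotypes carry equal risk, and recommends the in-window treatment
time minimising predicted risk.  Because risk depends on time only through
|t - origin|, every curve is symmetric about the origin and monotone on
each side, so optima sit at the origin or a window endpoint.

Recommendations are confined to the observed daytime treatment window
(default 08:00-18:00 solar); night-time extrapolation is refused because
the underlying cohorts contain almost no evening treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .modelling import FitResult, Z95

__all__ = [
    "predict_prob",
    "risk_curve",
    "equalization_time",
    "optimal_time",
    "risk_difference",
    "EqualizationResult",
]

DEFAULT_WINDOW = (8.0, 18.0)


def _genotype_column(fit: FitResult) -> str | None:
    for term in fit.spec.terms:
        if ":" in term:
            a, b = term.split(":", 1)
            if b == "time_dist":
                return a
            if a == "time_dist":
                return b
    return None


def _design_vector(
    fit: FitResult, profile: dict[str, float], dosage: float | None, time: float
) -> np.ndarray:
    origin = fit.spec.time_origin
    dist = abs(time - origin)
    geno = _genotype_column(fit)
    x = np.empty(len(fit.params))
    for i, name in enumerate(fit.params.index):
        if name == "const":
            x[i] = 1.0
        elif name == "time_dist":
            x[i] = dist
        elif geno is not None and name == geno:
            if dosage is None:
                raise ValueError(f"model contains genotype term {geno!r}; dosage required")
            x[i] = dosage
        elif geno is not None and name in (f"{geno}:time_dist", f"time_dist:{geno}"):
            x[i] = dosage * dist
        elif name in profile:
            x[i] = float(profile[name])
        else:
            raise ValueError(f"profile missing model term {name!r}")
    return x


def predict_prob(
    fit: FitResult,
    profile: dict[str, float],
    dosage: float | None,
    time: float,
) -> tuple[float, tuple[float, float]]:
    """Predicted toxicity probability at a solar treatment time, with CI.

    ``profile`` fixes every non-time, non-genotype design column (e.g.
    ``bmi``, ``bed``, ``surgery_wle``).  The 95% interval comes from the
    delta method on the linear predictor using the fit's covariance, then
    mapping through the inverse logit — the standard GLM prediction band.
    """
    x = _design_vector(fit, profile, dosage, time)
    lp = float(x @ fit.params.to_numpy())
    se = float(np.sqrt(x @ fit.cov.to_numpy() @ x))
    return float(expit(lp)), (float(expit(lp - Z95 * se)), float(expit(lp + Z95 * se)))


def risk_curve(
    fit: FitResult,
    profile: dict[str, float],
    dosages,
    times=None,
) -> pd.DataFrame:
    """Risk over a time grid for each genotype dosage (long format)."""
    if times is None:
        times = np.arange(6.0, 20.0 + 1e-9, 0.25)
    rows = []
    for d in dosages:
        for t in np.asarray(times, float):
            p, (lo, hi) = predict_prob(fit, profile, d, float(t))
            rows.append({"dosage": d, "time": t, "prob": p, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EqualizationResult:
    """Treatment times at which all genotypes carry equal predicted risk."""

    distance: float | None
    before_origin: float | None
    after_origin: float | None
    exists: bool


def equalization_time(
    snp_or: float, interaction_or: float, origin: float
) -> EqualizationResult:
    """Solar times at which genotype terms cancel.

    At distance h from the origin, genotypes differ in the linear predictor
    by dosage x (ln snp_or + h ln interaction_or); this vanishes at
    h = -ln(snp_or)/ln(interaction_or).  Both the pre-origin and mirrored
    post-origin solutions are returned.  With no interaction and a nonzero
    main effect, no solution exists.
    """
    if snp_or <= 0 or interaction_or <= 0:
        raise ValueError("odds ratios must be positive")
    if interaction_or == 1.0:
        if snp_or == 1.0:
            return EqualizationResult(0.0, origin, origin, True)
        return EqualizationResult(None, None, None, False)
    h = -np.log(snp_or) / np.log(interaction_or)
    if h < 0:
        # genotype effects never cancel at any real distance
        return EqualizationResult(float(h), None, None, False)
    return EqualizationResult(float(h), float(origin - h), float(origin + h), True)


def optimal_time(
    fit: FitResult,
    profile: dict[str, float],
    dosage: float | None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[float, float, bool]:
    """Treatment time in ``window`` minimising predicted risk.

    The risk curve is monotone in |t - origin| for a fixed genotype, so the
    minimiser is the origin (if inside the window) or a window endpoint;
    only those candidates are evaluated.  Returns (time, probability,
    flat); a perfectly flat curve returns the window start by convention,
    flagged.  Ties break toward the earlier time.
    """
    start, end = window
    if not (0 <= start < end < 24):
        raise ValueError("window must satisfy 0 <= start < end < 24")
    candidates = [start, end]
    if start <= fit.spec.time_origin <= end:
        candidates.append(fit.spec.time_origin)
    probs = {t: predict_prob(fit, profile, dosage, t)[0] for t in candidates}
    flat = max(probs.values()) - min(probs.values()) < 1e-12
    if flat:
        return float(start), probs[start], True
    best = min(sorted(probs), key=lambda t: (probs[t], t))
    return float(best), probs[best], False


def risk_difference(
    fit: FitResult,
    profile: dict[str, float],
    dosage: float | None,
    t1: float,
    t2: float,
) -> tuple[float, tuple[float, float]]:
    """Difference in predicted risk between two treatment times, with CI.

    Delta method on the difference of probabilities: the gradient of each
    probability with respect to the coefficients is p(1-p) x.
    """
    x1 = _design_vector(fit, profile, dosage, t1)
    x2 = _design_vector(fit, profile, dosage, t2)
    beta = fit.params.to_numpy()
    p1 = float(expit(x1 @ beta))
    p2 = float(expit(x2 @ beta))
    g = p1 * (1 - p1) * x1 - p2 * (1 - p2) * x2
    var = float(g @ fit.cov.to_numpy() @ g)
    se = np.sqrt(max(var, 0.0))
    d = p1 - p2
    return d, (d - Z95 * se, d + Z95 * se)
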