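"""End-to-end analysis pipeline: preprocess, scan, fit, validate, predict.

Mirrors the study workflow for one endpoint:

1. preprocessing (solar schedules, BED at the endpoint's alpha/beta,
   dichotomisation, exclusion cascade);
2. time-origin handling — either a fixed peak-toxicity origin or an AIC
   scan over a grid of candidate origins;
3. stepwise-AIC base model over the clinical and temporal covariates (the
   time term is retained throughout so genotype interactions remain
   estimable);
4. per-SNP augmentation (dosage + dosage x time interaction), no
   multiple-testing correction;
5. confirmatory random-intercept (site) refit of the base model;
6. repeated stratified cross-validated AUC;
7. genotype-conditional risk curves at a mean-covariate profile.

`run_pipeline` works on in-memory tables; `run_pipeline_files` wraps it
with delimited-text input/output plus a provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import study
from .io import (
    REQUIRED_FRACTION_COLS,
    REQUIRED_PATIENT_COLS,
    RunConfig,
    provenance,
    read_sites,
    read_table,
    write_table,
)
from .modelling import (
    FitResult,
    ModelSpec,
    SeparationError,
    SingularDesignError,
    augment_with_snp,
    cv_auc,
    fit_logistic,
    fit_mixed_logistic,
    scan_time_origin,
    stepwise_select,
)
from .prediction import risk_curve
from .preprocess import build_analysis_table
from .solar import GeoSite

__all__ = ["run_pipeline", "run_pipeline_files", "INITIAL_TERMS"]

#: covariates offered to stepwise selection (time terms included)
INITIAL_TERMS = (
    "age",
    "diabetes",
    "smoking",
    "bmi",
    "surgery",
    "bed",
    "imrt",
    "neoadj_anthra",
    "neoadj_non_anthra",
    "adj_anthra",
    "adj_non_anthra",
    "day_length",
    "latitude",
    "max_solar_elevation",
    "time_dist",
    "sd_solar_time",
)


def _fit_rows(model_name: str, fit: FitResult) -> list[dict]:
    tab = fit.summary_table()
    rows = []
    for _, r in tab.iterrows():
        rows.append(
            {
                "model": model_name,
                "term": r["term"],
                "or": r["or"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p": r["p"],
                "aic": fit.aic,
                "n": fit.n,
            }
        )
    return rows


def _mean_profile(fit: FitResult, data: pd.DataFrame) -> dict[str, float]:
    from .modelling import design_matrix

    X, _ = design_matrix(fit.spec, data)
    prof = {c: float(X[c].mean()) for c in X.columns}
    prof.pop("time_dist", None)
    return prof


def run_pipeline(
    patients: pd.DataFrame,
    fractions: pd.DataFrame,
    sites: dict[str, GeoSite],
    config: RunConfig,
    genotypes: pd.DataFrame | None = None,
) -> dict:
    """Run the full endpoint analysis; returns the report bundle.

    The bundle maps: ``analysis`` (model-ready table), ``exclusions``,
    ``scan`` (origin grid + AICs, if scanned), ``origin``, ``base_spec``,
    ``base_fit``, ``snp_fits``, ``mixed_fit``, ``cv`` and ``results``
    (tidy per-term table across models), plus ``risk_curves`` when SNP
    models were fitted.
    """
    endpoint = config.endpoint
    if endpoint not in ("erythema", "atrophy"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    data, exclusions = build_analysis_table(
        patients, fractions, sites, endpoint, config.alpha_beta, config.sensitivity
    )
    snp_cols: list[str] = []
    if genotypes is not None:
        geno = genotypes.set_index("patient_id")
        comp = [s.rsid for s in study.COMPOSITE_SNPS]
        if all(c in geno.columns for c in comp):
            geno = geno.assign(prs3=geno[comp].sum(axis=1))
        data = data.join(geno, how="left")
        snp_cols = list(config.snps) if config.snps else list(geno.columns)

    terms = tuple(t for t in INITIAL_TERMS if t == "time_dist" or t in data.columns)
    bundle: dict = {"analysis": data, "exclusions": exclusions}

    # time origin: fixed or AIC scan
    if config.time_origin is not None:
        origin = float(config.time_origin)
    else:
        scan_spec = ModelSpec(terms=terms, time_origin=0.0)
        scan = scan_time_origin(scan_spec, data, grid_step=config.scan_grid_step)
        bundle["scan"] = scan
        origin = scan.best_origin
    bundle["origin"] = origin

    base_spec, base_fit = stepwise_select(
        data,
        terms,
        forced=("time_dist",),
        spec=ModelSpec(terms=terms, time_origin=origin),
    )
    bundle["base_spec"] = base_spec
    bundle["base_fit"] = base_fit
    results = _fit_rows("base", base_fit)

    # per-SNP augmentation on genotyped complete cases
    snp_fits: dict[str, FitResult] = {}
    for snp in snp_cols:
        sub = data.dropna(subset=[snp])
        if sub.empty:
            continue
        try:
            snp_fits[snp] = augment_with_snp(base_spec, snp, sub)
        except (SeparationError, SingularDesignError) as e:
            results.append(
                {"model": f"+{snp}", "term": "(failed)", "or": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "aic": np.nan, "n": len(sub)}
            )
            continue
        results.extend(_fit_rows(f"+{snp}", snp_fits[snp]))
    bundle["snp_fits"] = snp_fits

    # confirmatory mixed model (site random intercept)
    if "site_name" in data.columns and data["site_name"].nunique() > 1:
        mixed = fit_mixed_logistic(base_spec, data)
        bundle["mixed_fit"] = mixed
        results.extend(_fit_rows("base(mixed)", mixed))

    bundle["cv"] = cv_auc(
        base_spec, data, folds=config.cv_folds, repeats=config.cv_repeats, seed=config.seed
    )

    # genotype-conditional risk curves at the mean-covariate profile
    curves = {}
    profile = _mean_profile(base_fit, data)
    for snp, fit in snp_fits.items():
        curves[snp] = risk_curve(fit, _mean_profile_for(fit, profile, data), dosages=(0, 1, 2))
    bundle["risk_curves"] = curves

    bundle["results"] = pd.DataFrame(results)
    return bundle


def _mean_profile_for(fit: FitResult, base_profile: dict, data: pd.DataFrame) -> dict:
    """Extend the base profile with any extra non-genotype columns."""
    from .modelling import design_matrix

    X, _ = design_matrix(fit.spec, data.dropna(subset=[t for t in fit.spec.terms if ":" not in t and t in data.columns]))
    prof = dict(base_profile)
    geno_terms = {t.split(":")[0] for t in fit.spec.terms if ":" in t} | {
        t.split(":")[1] for t in fit.spec.terms if ":" in t
    }
    for c in X.columns:
        if c not in prof and c != "time_dist" and c not in geno_terms and ":" not in c:
            prof[c] = float(X[c].mean())
    return prof


def _report_text(bundle: dict, config: RunConfig) -> str:
    lines = [f"# chronotox report — endpoint: {config.endpoint}", ""]
    lines.append("## Exclusions")
    for k, v in bundle["exclusions"].items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append(f"## Time origin: {bundle['origin']:.2f} h solar"
                 + (" (AIC scan)" if "scan" in bundle else " (fixed)"))
    lines.append("")
    lines.append("## Models (odds ratios, 95% CI, Wald p)")
    res: pd.DataFrame = bundle["results"]
    for model, grp in res.groupby("model", sort=False):
        lines.append(f"### {model} (AIC {grp['aic'].iloc[0]:.1f}, n={int(grp['n'].iloc[0])})")
        for _, r in grp.iterrows():
            lines.append(
                f"- {r['term']}: OR {r['or']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f}), p={r['p']:.3g}"
            )
        lines.append("")
    cv = bundle.get("cv")
    if cv:
        lines.append(f"## Cross-validated AUC: {cv['auc']:.3f} (95% {cv['ci'][0]:.3f}-{cv['ci'][1]:.3f})")
    mixed = bundle.get("mixed_fit")
    if mixed is not None:
        lines.append(
            f"## Site random intercept: sd {mixed.random_intercept_sd:.3f}, latent ICC {mixed.icc:.3f}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline_files(config: RunConfig) -> dict:
    """File-based pipeline wrapper: read inputs, run, write the bundle."""
    patients = read_table(config.patients, REQUIRED_PATIENT_COLS)
    fractions = read_table(config.fractions, REQUIRED_FRACTION_COLS)
    sites = read_sites(config.sites)
    genotypes = read_table(config.genotypes, ("patient_id",)) if config.genotypes else None
    bundle = run_pipeline(patients, fractions, sites, config, genotypes)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(bundle["results"], out / "results.csv")
    write_table(bundle["analysis"].reset_index(), out / "analysis_table.csv")
    if "scan" in bundle:
        write_table(
            pd.DataFrame({"origin": bundle["scan"].origins, "aic": bundle["scan"].aics}),
            out / "time_scan.csv",
        )
    (out / "report.md").write_text(_report_text(bundle, config))
    prov = provenance(config, bundle["exclusions"], {"origin": bundle["origin"]})
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return bundle
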