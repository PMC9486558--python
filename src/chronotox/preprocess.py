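"""Cohort preprocessing: BED, schedule summaries, endpoints, exclusions.

Turns raw patient, fraction and site tables into a model-ready analysis
table.  Conventions:

* Biologically effective dose follows the linear-quadratic model,
  ``BED = n d (1 + d / (alpha/beta))`` summed over the main and boost
  courses; alpha/beta defaults to 10 Gy for acute endpoints (erythema) and
  3 Gy for late endpoints (atrophy).
* Per-patient treatment schedules are summarised by the arithmetic mean and
  sample standard deviation of the per-fraction apparent solar times.
  Circular statistics are unnecessary: all treatments fall in a bounded
  daytime window (~07:00-20:00), so the 24 h wrap never binds.  For the
  same reason ``time_distance`` is a plain absolute difference, and a
  midnight time origin reduces to linear hours-from-midnight.
* Exclusions are applied in a fixed, reported order: endpoint baseline rule,
  then wide-schedule rule (solar-time SD > 2 h), then completeness.  A
  patient failing several rules is counted once, under the first rule.
* Missing values are never imputed; incomplete rows are dropped entirely.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import GeoSite, local_to_solar_arrays, solar_declination

__all__ = [
    "RadiotherapyCourse",
    "ScheduleSummary",
    "compute_bed",
    "summarize_schedule",
    "time_distance",
    "dichotomize_erythema",
    "dichotomize_atrophy",
    "apply_exclusions",
    "schedule_summaries",
    "build_analysis_table",
    "ALPHA_BETA",
    "MODEL_COVARIATES",
]

#: alpha/beta ratio (Gy) by endpoint tissue-effect class
ALPHA_BETA = {"erythema": 10.0, "atrophy": 3.0}

#: maximum within-patient solar-time standard deviation (hours)
SD_LIMIT = 2.0

#: covariates a complete model row must provide (beyond outcome/time terms)
MODEL_COVARIATES = [
    "age",
    "bmi",
    "diabetes",
    "smoking",
    "surgery",
    "imrt",
    "neoadj_anthra",
    "neoadj_non_anthra",
    "adj_anthra",
    "adj_non_anthra",
]


@dataclass(frozen=True)
class RadiotherapyCourse:
    """Fractionation of one patient's radiotherapy: main plus optional boost."""

    n_fractions: int
    dose_per_fraction: float
    boost_n_fractions: int = 0
    boost_dose_per_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n_fractions <= 0 or self.dose_per_fraction <= 0:
            raise ValueError("main course must have positive fraction count and dose")
        if self.boost_n_fractions < 0:
            raise ValueError("boost fraction count must be >= 0")
        if self.boost_n_fractions > 0:
            d = self.boost_dose_per_fraction
            if d is not None and d <= 0:
                raise ValueError("boost dose per fraction must be positive")


@dataclass(frozen=True)
class ScheduleSummary:
    """Per-patient apparent-solar treatment-time summary."""

    mean_solar_time: float
    sd_solar_time: float
    n_fractions_timed: int


def compute_bed(course: RadiotherapyCourse, alpha_beta: float) -> float:
    """Biologically effective dose (Gy) of a course at a given alpha/beta.

    Main and boost courses are additive; if the boost dose per fraction is
    unspecified it defaults to the main course's dose per fraction.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    n, d = course.n_fractions, course.dose_per_fraction
    bed = n * d * (1.0 + d / alpha_beta)
    if course.boost_n_fractions > 0:
        bd = course.boost_dose_per_fraction
        if bd is None:
            bd = d
        bed += course.boost_n_fractions * bd * (1.0 + bd / alpha_beta)
    return bed


def summarize_schedule(solar_times) -> ScheduleSummary:
    """Arithmetic mean and sample SD (ddof=1) of per-fraction solar hours."""
    t = np.asarray(list(solar_times), dtype=float)
    if t.size == 0:
        raise ValueError("schedule has no timed fractions")
    sd = float(np.std(t, ddof=1)) if t.size > 1 else 0.0
    return ScheduleSummary(float(np.mean(t)), sd, int(t.size))


def time_distance(mean_solar_time: float, origin: float):
    """Hours between a mean solar treatment time and a time origin.

    Plain absolute difference (no 24 h wrap): treatment times live in a
    bounded daytime window, so wraparound never binds, and an origin of
    0 h makes the distance identical to raw hours from solar midnight.
    """
    return abs(np.asarray(mean_solar_time, dtype=float) - origin) if np.ndim(
        mean_solar_time
    ) else abs(float(mean_solar_time) - origin)


def _check_grade(g, what: str) -> int | None:
    if g is None or (isinstance(g, float) and math.isnan(g)):
        return None
    if float(g) != int(g) or not (0 <= int(g) <= 4):
        raise ValueError(f"{what} grade {g!r} is not an integer in 0..4")
    return int(g)


def dichotomize_erythema(baseline, followup):
    """Acute-erythema endpoint: 1 if follow-up grade >= 2, else 0.

    Patients with any baseline erythema (grade > 0, likely surgical
    inflammation) are excluded (returns ``"excluded"``); a missing grade
    returns ``None``.
    """
    b = _check_grade(baseline, "baseline erythema")
    f = _check_grade(followup, "follow-up erythema")
    if b is None or f is None:
        return None
    if b > 0:
        return "excluded"
    return 1 if f >= 2 else 0


def dichotomize_atrophy(baseline, at_24m, sensitivity: bool = False):
    """Late-atrophy endpoint: 1 if worsening >= 1 grade at 24 months.

    Main analysis excludes gross baseline atrophy (grade >= 2, attributable
    to surgery); the sensitivity analysis excludes any baseline atrophy
    (grade > 0).  Missing grades return ``None``.
    """
    b = _check_grade(baseline, "baseline atrophy")
    a = _check_grade(at_24m, "24-month atrophy")
    if b is None or a is None:
        return None
    if (sensitivity and b > 0) or b >= 2:
        return "excluded"
    return 1 if a - b >= 1 else 0


def _day_length_hours(doy: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Vectorised day length; polar cases clamp to 0/24 h."""
    decl = np.radians(solar_declination(doy))
    latr = np.radians(lat)
    cos_h = (np.sin(np.radians(-0.833)) - np.sin(latr) * np.sin(decl)) / (
        np.cos(latr) * np.cos(decl)
    )
    h = np.degrees(np.arccos(np.clip(cos_h, -1.0, 1.0)))
    return 2.0 * h / 15.0


def schedule_summaries(
    fractions: pd.DataFrame, sites: dict[str, GeoSite]
) -> pd.DataFrame:
    """Per-patient solar-time schedule summaries from a fraction table.

    ``fractions`` needs columns ``patient_id``, ``site_name``, ``date``
    (datetime-like or ISO string), ``local_time`` (decimal hours or
    "HH:MM"), and optionally ``utc_offset`` (explicit offsets override the
    site's DST rule).  Besides the solar-time mean/SD/count, the light-
    exposure covariates are summarised: mean day length and mean maximum
    solar elevation over the course, plus the site latitude.
    """
    df = fractions.copy()
    dates = pd.to_datetime(df["date"])
    lt = df["local_time"]
    if lt.dtype == object:
        parts = lt.astype(str).str.split(":", expand=True)
        clock = parts[0].astype(float) + parts[1].astype(float) / 60.0
    else:
        clock = lt.astype(float)

    lat = df["site_name"].map({k: s.latitude for k, s in sites.items()}).to_numpy(float)
    lon = df["site_name"].map({k: s.longitude for k, s in sites.items()}).to_numpy(float)
    if np.isnan(lat).any():
        missing = sorted(set(df.loc[np.isnan(lat), "site_name"]))
        raise KeyError(f"fraction table references unknown site(s): {missing}")
    utc_base = df["site_name"].map({k: s.utc_base_offset for k, s in sites.items()}).to_numpy(float)
    dst_off = df["site_name"].map(
        {k: (s.dst_offset if s.dst_rule == "eu" else 0.0) for k, s in sites.items()}
    ).to_numpy(float)

    # EU DST window per calendar year (date granularity)
    years = dates.dt.year.to_numpy()
    bounds = {}
    for y in np.unique(years):
        mar = _dt.date(y, 4, 1) - _dt.timedelta(days=1)
        oct_ = _dt.date(y, 11, 1) - _dt.timedelta(days=1)
        bounds[y] = (
            (mar - _dt.timedelta(days=(mar.weekday() + 1) % 7)).toordinal(),
            (oct_ - _dt.timedelta(days=(oct_.weekday() + 1) % 7)).toordinal(),
        )
    ords = np.array([d.toordinal() for d in dates.dt.date])
    lo = np.array([bounds[y][0] for y in years])
    hi = np.array([bounds[y][1] for y in years])
    offsets = utc_base + dst_off * ((ords >= lo) & (ords < hi))
    if "utc_offset" in df.columns:
        explicit = pd.to_numeric(df["utc_offset"], errors="coerce").to_numpy(float)
        offsets = np.where(np.isnan(explicit), offsets, explicit)

    doy = dates.dt.dayofyear.to_numpy()
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "solar": local_to_solar_arrays(doy, clock.to_numpy(float), lon, offsets),
            "daylen": _day_length_hours(doy, lat),
            "elev": 90.0 - np.abs(lat - solar_declination(doy)),
            "latitude": lat,
        }
    )
    g = out.groupby("patient_id", sort=False)
    res = g.agg(
        mean_solar_time=("solar", "mean"),
        sd_solar_time=("solar", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        n_fractions_timed=("solar", "size"),
        day_length=("daylen", "mean"),
        max_solar_elevation=("elev", "mean"),
        latitude=("latitude", "first"),
    )
    return res


def apply_exclusions(
    cohort: pd.DataFrame,
    endpoint: str,
    sensitivity: bool = False,
    required: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the endpoint's exclusion cascade and report counts.

    ``cohort`` must carry an ``outcome`` column holding 0/1, ``"excluded"``
    (baseline rule) or NaN (missing grades), plus ``sd_solar_time`` and the
    model covariates.  Order: baseline rule, then SD > 2 h, then
    completeness (missing outcome or any required covariate).  Returns the
    analysis table (rows with usable outcomes) and a count per reason.
    """
    if endpoint not in ALPHA_BETA:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = cohort
    report: dict[str, int] = {}

    baseline_mask = df["outcome"].eq("excluded")
    report["baseline"] = int(baseline_mask.sum())
    df = df[~baseline_mask]

    sd_mask = df["sd_solar_time"] > SD_LIMIT
    report["sd_gt_2h"] = int(sd_mask.sum())
    df = df[~sd_mask]

    cols = ["outcome"] + [c for c in (required or MODEL_COVARIATES + ["bed", "mean_solar_time"]) if c in df.columns]
    incomplete = df[cols].isna().any(axis=1)
    report["incomplete"] = int(incomplete.sum())
    df = df[~incomplete].copy()
    df["outcome"] = df["outcome"].astype(int)

    if df.empty:
        raise RuntimeError("all patients excluded; empty analysis cohort")
    report["included"] = len(df)
    return df, report


def build_analysis_table(
    patients: pd.DataFrame,
    fractions: pd.DataFrame,
    sites: dict[str, GeoSite],
    endpoint: str,
    alpha_beta: float | None = None,
    sensitivity: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full preprocessing: schedules, BED, endpoint, exclusions.

    Returns the analysis table (one row per included patient, indexed by
    ``patient_id``, with ``outcome``, ``bed``, ``mean_solar_time``,
    ``sd_solar_time`` and the clinical covariates) plus the exclusion
    report.
    """
    if alpha_beta is None:
        alpha_beta = ALPHA_BETA[endpoint]
    df = patients.set_index("patient_id") if "patient_id" in patients.columns else patients.copy()

    sched = schedule_summaries(fractions, sites)
    df = df.join(sched, how="left")

    def _bed(row):
        try:
            course = RadiotherapyCourse(
                int(row["n_fractions"]),
                float(row["dose_per_fraction"]),
                int(row.get("boost_n_fractions", 0) or 0),
                row.get("boost_dose_per_fraction"),
            )
        except (ValueError, TypeError):
            return np.nan
        return compute_bed(course, alpha_beta)

    df["bed"] = df.apply(_bed, axis=1)

    if endpoint == "erythema":
        df["outcome"] = [
            dichotomize_erythema(b, f)
            for b, f in zip(df["baseline_erythema"], df["followup_erythema"])
        ]
    else:
        df["outcome"] = [
            dichotomize_atrophy(b, a, sensitivity)
            for b, a in zip(df["baseline_atrophy"], df["atrophy_24m"])
        ]
    return apply_exclusions(df, endpoint, sensitivity)
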