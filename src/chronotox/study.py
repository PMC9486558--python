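"""Default study constants: the REQUITE breast-cohort summary structure.

The real multi-centre cohort (eight European recruiting centres, n=1727)
is access-controlled; the synthetic generator emulates its published
summary structure.  This module collects those published quantities —
site geography and treatment-time distributions, candidate circadian-SNP
definitions with allele-2 frequencies, and the fitted odds-ratio sets for
the acute-erythema and late-atrophy logistic models — so that simulations,
recovery experiments and predictions all draw on one authoritative set of
defaults.

All odds ratios are stored as published (OR scale); log-odds coefficients
are derived where needed.  Time-of-day effects are parameterised by a
*time origin*: the solar hour of peak toxicity.  The erythema model uses a
midnight origin (its time term is simply hours from solar midnight); the
atrophy model's origin is 15:30 solar, with risk decreasing per hour of
distance from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .solar import GeoSite

__all__ = [
    "SiteProfile",
    "SnpDef",
    "CoefficientSet",
    "STUDY_SITES",
    "CANDIDATE_SNPS",
    "COMPOSITE_SNPS",
    "ERYTHEMA_PER3_FIXED",
    "ATROPHY_NO_SNP",
    "ATROPHY_CLOCK",
    "ATROPHY_PER3",
    "ATROPHY_RASD1",
    "ATROPHY_PRS3",
    "ERYTHEMA_PREVALENCE",
    "ATROPHY_PREVALENCE",
    "ATROPHY_TIME_ORIGIN",
    "ERYTHEMA_TIME_ORIGIN",
    "SITE_RANDOM_INTERCEPT_SD",
]


@dataclass(frozen=True)
class SiteProfile:
    """Geography plus treatment-time distribution for one recruiting centre.

    ``mean_local_time``/``sd_local_time`` describe the across-patient
    distribution of per-patient mean fraction clock times (decimal hours);
    ``frac_sd_gt2`` is the observed share of patients whose fraction-to-
    fraction solar-time standard deviation exceeded 2 h.
    """

    site: GeoSite
    n_patients: int
    mean_local_time: float
    sd_local_time: float
    mean_solar_time: float
    sd_solar_time: float
    frac_sd_gt2: float


def _site(name, lat, lon, utc, n, mloc, sloc, msol, ssol, gt2) -> SiteProfile:
    return SiteProfile(
        site=GeoSite(name=name, latitude=lat, longitude=lon, utc_base_offset=utc),
        n_patients=n,
        mean_local_time=mloc,
        sd_local_time=sloc,
        mean_solar_time=msol,
        sd_solar_time=ssol,
        frac_sd_gt2=gt2,
    )


#: The eight recruiting centres with their published geography, cohort sizes,
#: treatment-time distributions, and wide-schedule (SD > 2 h) rates.
#: Longitudes are kept exactly as published (Barcelona's printed longitude
#: carries a sign error relative to the city's true position; day lengths
#: depend only on latitude, and the solar-time emulation adopts the printed
#: summary verbatim).
STUDY_SITES: tuple[SiteProfile, ...] = (
    _site("Barcelona", 41.4, -2.2, 1, 193, 13.89, 3.60, 12.08, 3.63, 0.16),
    _site("Gent", 51.1, 3.7, 1, 295, 11.75, 1.76, 10.38, 1.81, 0.43),
    _site("Leicester", 52.6, -1.1, 0, 343, 12.60, 1.89, 12.00, 1.94, 0.29),
    _site("Leuven", 50.9, 4.7, 1, 252, 11.76, 2.02, 10.48, 2.12, 0.17),
    _site("Mannheim", 49.5, 8.5, 1, 37, 10.49, 1.72, 9.51, 1.72, 0.43),
    _site("Milan", 45.5, 9.2, 1, 102, 12.40, 2.38, 11.31, 2.41, 0.001),
    _site("Montpellier", 43.6, 3.9, 1, 405, 12.94, 3.18, 11.61, 3.22, 0.037),
    _site("Santiago", 42.9, -8.5, 1, 100, 14.83, 3.34, 12.53, 3.41, 0.20),
)

#: Published shortest/longest day lengths (hours) per site, same order.
PUBLISHED_DAY_LENGTHS: dict[str, tuple[float, float]] = {
    "Barcelona": (9.2, 15.2),
    "Gent": (7.9, 16.6),
    "Leicester": (7.6, 16.8),
    "Leuven": (7.9, 16.5),
    "Mannheim": (8.1, 16.3),
    "Milan": (8.7, 15.7),
    "Montpellier": (8.9, 15.4),
    "Santiago": (9.0, 15.3),
}


@dataclass(frozen=True)
class SnpDef:
    """A candidate circadian SNP: alleles, allele-2 frequency, chronotype OR."""

    rsid: str
    gene: str
    chromosome: str
    allele1: str
    allele2: str
    allele2_freq: float
    chronotype_or: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.allele2_freq < 1):
            raise ValueError(f"{self.rsid}: allele2_freq must lie in (0, 1)")


#: Candidate SNPs in circadian genes with allele-2 frequencies; the first
#: three validate previously reported genotype-modulated treatment-time
#: effects, the rest come from a chronotype GWAS.
CANDIDATE_SNPS: tuple[SnpDef, ...] = (
    SnpDef("rs2087947", "PER3", "1", "C", "T", 0.31),
    SnpDef("rs1801260", "CLOCK", "4", "A", "G", 0.27),
    SnpDef("rs13116075", "NOCT", "4", "A", "G", 0.15),
    SnpDef("rs11121022", "VAMP3", "1", "A", "C", 0.42, 1.07),
    SnpDef("rs55694368", "PER2", "2", "G", "T", 0.11, 0.86),
    SnpDef("rs11545787", "RASD1", "17", "G", "A", 0.25, 1.08),
    SnpDef("rs35833281", "HCRTR2", "6", "G", "C", 0.23, 0.92),
)

_BY_RSID = {s.rsid: s for s in CANDIDATE_SNPS}

#: The three SNPs of the unweighted composite score, in score order
#: (CLOCK, PER3, RASD1); they sit on chromosomes 4, 1 and 17, so
#: independence under Hardy-Weinberg is exact.
COMPOSITE_SNPS: tuple[SnpDef, ...] = (
    _BY_RSID["rs1801260"],
    _BY_RSID["rs2087947"],
    _BY_RSID["rs11545787"],
)


@dataclass(frozen=True)
class CoefficientSet:
    """A published fitted logistic model, stored as odds ratios.

    ``odds_ratios`` maps model-term names to ORs; ``time_origin`` is the
    solar hour of peak toxicity that defines the ``time_dist`` term
    (``time_dist`` is |mean solar time - origin|; with origin 0 it reduces
    to raw hours from solar midnight).  ``snp`` names the augmenting SNP
    (or ``"prs3"`` for the composite score), if any.
    """

    name: str
    endpoint: str  # "erythema" | "atrophy"
    time_origin: float
    odds_ratios: dict[str, float] = field(default_factory=dict)
    snp: str | None = None

    @property
    def coefficients(self) -> dict[str, float]:
        """Log odds ratios per term."""
        return {k: math.log(v) for k, v in self.odds_ratios.items()}

    @property
    def terms(self) -> list[str]:
        return list(self.odds_ratios)


ERYTHEMA_TIME_ORIGIN = 0.0
ATROPHY_TIME_ORIGIN = 15.5
ERYTHEMA_PREVALENCE = 0.20
ATROPHY_PREVALENCE = 0.35
#: site random-intercept standard deviation (erythema mixed model)
SITE_RANDOM_INTERCEPT_SD = 0.59

# Acute erythema, fixed effects, augmented with PER3 rs2087947.
# Time enters as raw hours from solar midnight plus the within-patient
# fraction-time standard deviation as a second temporal covariate.
ERYTHEMA_PER3_FIXED = CoefficientSet(
    name="erythema+rs2087947",
    endpoint="erythema",
    time_origin=ERYTHEMA_TIME_ORIGIN,
    odds_ratios={
        "bmi": 1.04,
        "bed": 1.02,
        "time_dist": 1.05,
        "sd_solar_time": 0.645,
        "snp": 1.27,
    },
    snp="rs2087947",
)

ATROPHY_NO_SNP = CoefficientSet(
    name="atrophy-base",
    endpoint="atrophy",
    time_origin=ATROPHY_TIME_ORIGIN,
    odds_ratios={"bmi": 1.06, "bed": 1.02, "surgery_wle": 2.13, "time_dist": 0.939},
)

ATROPHY_CLOCK = CoefficientSet(
    name="atrophy+rs1801260",
    endpoint="atrophy",
    time_origin=ATROPHY_TIME_ORIGIN,
    odds_ratios={
        "bmi": 1.06,
        "bed": 1.02,
        "surgery_wle": 2.17,
        "time_dist": 0.874,
        "snp": 0.616,
        "snp_x_time": 1.13,
    },
    snp="rs1801260",
)

ATROPHY_PER3 = CoefficientSet(
    name="atrophy+rs2087947",
    endpoint="atrophy",
    time_origin=ATROPHY_TIME_ORIGIN,
    odds_ratios={
        "bmi": 1.06,
        "bed": 1.02,
        "surgery_wle": 2.19,
        "time_dist": 0.88,
        "snp": 0.653,
        "snp_x_time": 1.10,
    },
    snp="rs2087947",
)

ATROPHY_RASD1 = CoefficientSet(
    name="atrophy+rs11545787",
    endpoint="atrophy",
    time_origin=ATROPHY_TIME_ORIGIN,
    odds_ratios={
        "bmi": 1.06,
        "bed": 1.02,
        "surgery_wle": 2.22,
        "time_dist": 0.867,
        "snp": 0.557,
        "snp_x_time": 1.15,
    },
    snp="rs11545787",
)

ATROPHY_PRS3 = CoefficientSet(
    name="atrophy+prs3",
    endpoint="atrophy",
    time_origin=ATROPHY_TIME_ORIGIN,
    odds_ratios={
        "bmi": 1.06,
        "bed": 1.02,
        "surgery_wle": 2.17,
        "time_dist": 0.772,
        "snp": 0.619,
        "snp_x_time": 1.12,
    },
    snp="prs3",
)
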