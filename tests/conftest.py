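"""Shared fixtures: deterministic hypothesis profile and small cohorts."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from chronotox import study
from chronotox.cohort import GeneratorConfig, generate
from chronotox.experiments import analysis_table_with_genotypes

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sites():
    """Name -> GeoSite map for the default study sites."""
    return {sp.site.name: sp.site for sp in study.STUDY_SITES}


@pytest.fixture(scope="session")
def small_cohort():
    """One small generated atrophy cohort reused across read-only tests."""
    return generate(GeneratorConfig(n_patients=400, seed=123))


@pytest.fixture(scope="session")
def atrophy_table(small_cohort):
    """Model-ready analysis table for the small cohort."""
    return analysis_table_with_genotypes(small_cohort, "atrophy")
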