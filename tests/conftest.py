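"""Shared fixtures: small synthetic cohorts with known generating truth."""

import numpy as np
import pytest

from hippnorm import CohortSpec, generate_cohort


def clean_spec(
    n_female: int = 1000,
    n_male: int = 0,
    noise_sd: float = 150.0,
    pre_slope: float = -2.5,
    slope_change: float = -16.22,
    change_age_female: float = 64.5,
    change_age_male: float = 63.5,
    gm_noise_sd: float = 15000.0,
    gm_slope: float = -2800.0,
    seed: int = 0,
    **kw,
) -> CohortSpec:
    """Cohort spec with confounds and covariates switched off.

    Hippocampal hinge trajectories plus linear total-grey-matter decline
    and pure Gaussian residual noise: the minimal structure needed by
    window/trajectory/joinpoint tests, with everything else (outliers,
    drift, head-size effects, covariate shifts) disabled so analytic
    expectations are exact.
    """
    spec = CohortSpec(
        n_female=n_female,
        n_male=n_male,
        seed=seed,
        outlier_fraction=0.0,
        drift_per_year=0.0,
        head_scaling_sex_offset=0.0,
        covariate_effects={},
        sd_is_noise=True,
        **kw,
    )
    for sex, ca in (("female", change_age_female), ("male", change_age_male)):
        for h in ("hippocampus_left", "hippocampus_right"):
            spec = spec.with_region(
                sex,
                h,
                baseline_sd=noise_sd,
                pre_slope=pre_slope,
                slope_change=slope_change,
                change_age=ca,
                head_slope=0.0,
            )
        spec = spec.with_region(
            sex,
            "total_grey_matter",
            baseline_sd=gm_noise_sd,
            pre_slope=gm_slope,
            slope_change=0.0,
            head_slope=0.0,
        )
        for r in (
            "superior_temporal",
            "middle_temporal",
            "inferior_temporal",
            "fusiform",
            "parahippocampal",
            "temporal_pole",
        ):
            spec = spec.with_region(sex, r, head_slope=0.0)
    return spec


@pytest.fixture(scope="session")
def default_small_cohort():
    """Default-parameter cohort at reduced n (both sexes, outliers on)."""
    return generate_cohort(CohortSpec(n_female=1200, n_male=1000, seed=42))


@pytest.fixture(scope="session")
def flat_cohort():
    """Age-independent single-sex cohort: volume ~ N(mu, sigma), no trends."""
    spec = clean_spec(n_female=20_000, noise_sd=300.0, pre_slope=0.0,
                      slope_change=0.0, seed=7)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
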