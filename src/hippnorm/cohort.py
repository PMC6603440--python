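"""Synthetic cohorts with the statistical structure of a population imaging study.

Generates participant-level tables (one row per person) of regional
grey-matter volumes and covariates that mimic a large single-scanner
cohort of generally healthy middle-aged and older adults: sex-specific
volume means and SDs, piecewise-linear age trajectories with a mid-life
acceleration of hippocampal volume loss, a head-size confound expressed
through the volumetric head-scaling factor, linear scanner drift over
scan date, small lifestyle-covariate effects, and a configurable
fraction of gross outliers.

Every downstream stage of the pipeline (outlier filtering, confound
regression, nomograms, trajectory inflection, joinpoint regression,
percentile lookup) is testable against cohorts from this module because
the generating truth is known.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionParams",
    "CohortSpec",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "average_hippocampus",
    "SchemaError",
    "META_COLUMNS",
    "VOLUME_COLUMNS",
    "GENERATED_REGIONS",
    "HEAD_SCALING_REFERENCE",
]

# Head-scaling factor at which head-size correction is neutral; the
# volumetric scaling to standard space is inversely related to head size.
HEAD_SCALING_REFERENCE = 1.29874

META_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "scan_date",
    "head_scaling",
    "hypertension",
    "smoking",
    "bmi",
    "education",
    "handedness",
    "excluded_selfreport",
]

# Volumes carried by a cohort table, all in mm^3.  The hippocampus is
# generated per hemisphere; the bilateral column is their sum.
GENERATED_REGIONS = [
    "hippocampus_left",
    "hippocampus_right",
    "superior_temporal",
    "middle_temporal",
    "inferior_temporal",
    "fusiform",
    "parahippocampal",
    "temporal_pole",
    "total_grey_matter",
]

VOLUME_COLUMNS = GENERATED_REGIONS[:2] + ["hippocampus_bilateral"] + GENERATED_REGIONS[2:]

ALL_COLUMNS = META_COLUMNS + VOLUME_COLUMNS

_STRING_COLUMNS = {"participant_id", "sex", "smoking", "education", "handedness"}
_BOOL_COLUMNS = {"hypertension", "excluded_selfreport"}
_NUMERIC_COLUMNS = [
    c for c in ALL_COLUMNS if c not in _STRING_COLUMNS and c not in _BOOL_COLUMNS
]


class SchemaError(ValueError):
    """Raised when a cohort file does not match the expected schema."""


@dataclass(frozen=True)
class RegionParams:
    """Generating parameters for one region in one sex.

    The age trajectory is a continuous hinge: volume declines at
    ``pre_slope`` mm^3/year until ``change_age``, after which the slope
    changes by ``slope_change`` (total post slope = pre + change).
    ``baseline_volume`` is the target population mean of the *generated*
    (uncorrected) volume and ``baseline_sd`` its target marginal SD; the
    generator subtracts the analytic mean of every systematic term and
    assigns the residual variance to Gaussian noise so both targets hold
    by construction.  ``head_slope`` is the regression slope b of volume
    on the head-scaling factor (negative: larger scaling = smaller head).
    """

    baseline_volume: float
    baseline_sd: float
    pre_slope: float = 0.0
    slope_change: float = 0.0
    change_age: float = 64.5
    head_slope: float = 0.0

    def age_effect(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.pre_slope * (age - 45.0) + self.slope_change * np.maximum(
            0.0, age - self.change_age
        )


def _default_region_params() -> dict[str, dict[str, RegionParams]]:
    """Sex-specific defaults anchored on the study's printed summaries.

    Average hippocampus: 3,765.18 +/- 366.75 mm^3 (F, n=10,463) and
    3,972.97 +/- 431.03 mm^3 (M, n=9,330); total grey matter
    594,250 +/- 48,028 (F) and 641,307 +/- 51,379 (M).  Hippocampal
    hinges use the joinpoint geometry (break 64-65y F / 63-64y M with
    bilateral slope changes -32.44 / -26.45 mm^3/yr, split evenly across
    hemispheres).  Head-scaling slopes b are the published correction
    table values for left/right hippocampus and total grey matter; other
    regions use b ~ -0.55 x mean, the ratio the grey-matter b implies.
    Temporal-lobe means/SDs are field-realistic choices (not printed in
    the source tables).
    """
    # per-hemisphere SD so that the L/R average has the printed SD given
    # an inter-hemisphere correlation of 0.8: sd_h = sd_avg*sqrt(2/(1+rho))
    f_h_sd = 366.75 * np.sqrt(2.0 / 1.8)
    m_h_sd = 431.03 * np.sqrt(2.0 / 1.8)
    female = {
        "hippocampus_left": RegionParams(3721.18, f_h_sd, -5.0, -16.22, 64.5, -1340.89),
        "hippocampus_right": RegionParams(3809.18, f_h_sd, -5.0, -16.22, 64.5, -1532.24),
        "superior_temporal": RegionParams(13400.0, 1400.0, -40.0, 0.0, 64.5, -7400.0),
        "middle_temporal": RegionParams(18600.0, 2000.0, -55.0, 0.0, 64.5, -10300.0),
        "inferior_temporal": RegionParams(17000.0, 1900.0, -50.0, 0.0, 64.5, -9400.0),
        "fusiform": RegionParams(15200.0, 1600.0, -40.0, 0.0, 64.5, -8400.0),
        "parahippocampal": RegionParams(4450.0, 500.0, -12.0, 0.0, 64.5, -2500.0),
        "temporal_pole": RegionParams(8350.0, 900.0, -20.0, 0.0, 64.5, -4600.0),
        "total_grey_matter": RegionParams(594250.0, 48028.0, -2800.0, 0.0, 64.5, -354545.84),
    }
    male = {
        "hippocampus_left": RegionParams(3928.97, m_h_sd, -7.5, -13.225, 63.5, -1340.89),
        "hippocampus_right": RegionParams(4016.97, m_h_sd, -7.5, -13.225, 63.5, -1532.24),
        "superior_temporal": RegionParams(13600.0, 1450.0, -42.0, 0.0, 63.5, -7500.0),
        "middle_temporal": RegionParams(18400.0, 2050.0, -57.0, 0.0, 63.5, -10100.0),
        "inferior_temporal": RegionParams(16800.0, 1950.0, -52.0, 0.0, 63.5, -9200.0),
        "fusiform": RegionParams(15000.0, 1650.0, -42.0, 0.0, 63.5, -8300.0),
        "parahippocampal": RegionParams(4700.0, 520.0, -13.0, 0.0, 63.5, -2600.0),
        "temporal_pole": RegionParams(8850.0, 930.0, -21.0, 0.0, 63.5, -4900.0),
        "total_grey_matter": RegionParams(641307.0, 51379.0, -3200.0, 0.0, 63.5, -354545.84),
    }
    return {"female": female, "male": male}


# Small lifestyle-covariate effects on volumes, on the Hedges' g scale
# (fraction of the region's marginal SD); "bmi" entries are Pearson r.
# The "hippocampus" key shifts both hemispheres by g x SD(average).
_DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "hypertension": {"total_grey_matter": -0.17, "hippocampus": -0.06},
    "smoking_previous": {"total_grey_matter": -0.18, "hippocampus": -0.10},
    "smoking_current": {"total_grey_matter": -0.33, "hippocampus": -0.15},
    "education_lower": {"hippocampus": -0.07},
    "bmi": {"total_grey_matter": -0.11, "hippocampus": -0.03},
}


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the study conditions:
    10,463 female and 9,330 male participants aged 45-80 with a
    triangular age density (thin tails, peak in the mid-60s), head
    scaling ~ Normal(1.29874, 0.1) with a small sex offset (males have
    larger heads, hence *lower* scaling), a mild negative scanner drift,
    and ~0.7% gross outliers per region displaced by 8 SD, matching the
    per-region outlier counts the exclusion step is expected to remove.
    """

    n_female: int = 10_463
    n_male: int = 9_330
    age_range: tuple[float, float] = (45.0, 80.0)
    age_mode: Mapping[str, float] = field(
        default_factory=lambda: {"female": 62.0, "male": 66.0}
    )
    region_params: Mapping[str, Mapping[str, RegionParams]] = field(
        default_factory=_default_region_params
    )
    head_scaling_mean: float = HEAD_SCALING_REFERENCE
    head_scaling_sd: float = 0.1
    # female +, male - (males have larger heads, hence lower scaling).  At
    # 0.065 the head-scaling slopes b explain essentially the whole raw sex
    # gap in grey-matter and hippocampal volume, so head-size-corrected sex
    # differences are near zero -- the pattern the corrected comparisons of
    # large single-scanner cohorts show.
    head_scaling_sex_offset: float = 0.065
    scan_date_range: tuple[float, float] = (0.0, 1460.0)  # days, ~4 years
    drift_per_year: float = -0.002  # relative drift, fraction of region mean / year
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COVARIATE_EFFECTS.items()}
    )
    hippocampus_lr_correlation: float = 0.8
    hypertension_prevalence: float = 0.27
    smoking_probs: tuple[float, float, float] = (0.60, 0.35, 0.05)  # never/previous/current
    education_lower_prob: float = 0.55
    handedness_probs: tuple[float, float, float] = (0.89, 0.10, 0.01)  # right/left/ambi
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    selfreport_exclusion_fraction: float = 0.0
    outlier_fraction: float = 0.007
    outlier_magnitude: float = 8.0
    # False: baseline_sd is the target *marginal* SD (systematic variance is
    # subtracted before drawing noise).  True: baseline_sd is the residual
    # noise SD around the systematic trajectory, used directly.
    sd_is_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_female < 0:
            raise ValueError(f"n_female must be >= 0, got {self.n_female}")
        if self.n_male < 0:
            raise ValueError(f"n_male must be >= 0, got {self.n_male}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range min must be < max, got {self.age_range}")
        if not 0.0 <= self.outlier_fraction <= 0.05:
            raise ValueError(
                f"outlier_fraction must be in [0, 0.05], got {self.outlier_fraction}"
            )
        if self.head_scaling_sd < 0:
            raise ValueError(f"head_scaling_sd must be >= 0, got {self.head_scaling_sd}")
        if not 0.0 <= self.hippocampus_lr_correlation < 1.0:
            raise ValueError(
                "hippocampus_lr_correlation must be in [0, 1), got "
                f"{self.hippocampus_lr_correlation}"
            )
        for sex in ("female", "male"):
            if sex not in self.region_params:
                raise ValueError(f"region_params missing sex {sex!r}")
            for region in GENERATED_REGIONS:
                if region not in self.region_params[sex]:
                    raise ValueError(f"region_params[{sex!r}] missing region {region!r}")
                if self.region_params[sex][region].baseline_sd < 0:
                    raise ValueError(f"baseline_sd must be >= 0 for {sex}/{region}")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)

    def with_region(self, sex: str, region: str, **kw) -> "CohortSpec":
        """Copy of the spec with one region's parameters updated."""
        params = {s: dict(r) for s, r in self.region_params.items()}
        params[sex][region] = dataclasses.replace(params[sex][region], **kw)
        return dataclasses.replace(self, region_params=params)


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _triangular_moments(fn, lo: float, mode: float, hi: float) -> tuple[float, float]:
    """Mean and variance of fn(A) for A ~ Triangular(lo, mode, hi), by quadrature."""
    grid = np.linspace(lo, hi, 4001)
    pdf = np.where(
        grid <= mode,
        2.0 * (grid - lo) / ((hi - lo) * (mode - lo) + 1e-300),
        2.0 * (hi - grid) / ((hi - lo) * (hi - mode) + 1e-300),
    )
    vals = fn(grid)
    mean = np.trapezoid(vals * pdf, grid)
    var = np.trapezoid((vals - mean) ** 2 * pdf, grid)
    return float(mean), float(var)


def _covariate_shifts(spec: CohortSpec, sex: str, region: str, scale_sd: float) -> dict[str, float]:
    """mm^3 shift per covariate level for one region.

    Effects are specified on the Hedges' g scale *as an analyst measures
    them*, i.e. relative to the SD remaining after the confounds (head
    scaling, drift, age) are regressed out -- ``scale_sd``.  Hippocampus
    keys shift both hemispheres equally by g x SD of the L/R average.
    """
    key = "hippocampus" if region.startswith("hippocampus") else region
    out = {cov: 0.0 for cov in _DEFAULT_COVARIATE_EFFECTS}
    for cov, effects in spec.covariate_effects.items():
        out[cov] = effects.get(key, 0.0) * scale_sd
    return out


def _systematic_terms(
    spec: CohortSpec,
    sex: str,
    region: str,
    age: np.ndarray,
    head_scaling: np.ndarray,
    scan_date: np.ndarray,
    covariates: dict[str, np.ndarray],
) -> tuple[np.ndarray, float, float]:
    """Centered systematic signal plus its analytic mean/variance.

    Returns (signal - analytic mean, analytic mean≈0 check unused, variance)
    so that adding Normal(0, baseline_sd^2 - variance) noise yields the
    requested marginal mean and SD.
    """
    p = spec.region_params[sex][region]
    lo, hi = spec.age_range
    mode = spec.age_mode[sex]

    age_mean, age_var = _triangular_moments(p.age_effect, lo, mode, hi)
    age_term = p.age_effect(age) - age_mean

    hs_mean = spec.head_scaling_mean + (
        spec.head_scaling_sex_offset if sex == "female" else -spec.head_scaling_sex_offset
    )
    hs_term = (head_scaling - hs_mean) * p.head_slope
    hs_var = (spec.head_scaling_sd * p.head_slope) ** 2

    drift_slope = spec.drift_per_year * p.baseline_volume / 365.25  # mm^3 per day
    d_lo, d_hi = spec.scan_date_range
    drift_term = drift_slope * (scan_date - 0.5 * (d_lo + d_hi))
    drift_var = drift_slope**2 * (d_hi - d_lo) ** 2 / 12.0

    # residual SD an analyst sees after deconfounding: the covariate
    # effect scale.  For the hippocampus, g applies to the L/R average,
    # whose residual SD relates to the per-hemisphere one through the
    # inter-hemisphere correlation.
    base_var = age_var + hs_var + drift_var
    if spec.sd_is_noise:
        resid_sd = p.baseline_sd
    else:
        resid_sd = float(np.sqrt(max(p.baseline_sd**2 - base_var, 0.0)))
    if region.startswith("hippocampus"):
        resid_sd *= np.sqrt((1.0 + spec.hippocampus_lr_correlation) / 2.0)

    shifts = _covariate_shifts(spec, sex, region, resid_sd)
    p_ht = spec.hypertension_prevalence
    p_prev, p_curr = spec.smoking_probs[1], spec.smoking_probs[2]
    p_edu = spec.education_lower_prob

    cov_term = np.zeros_like(age)
    cov_var = 0.0
    if shifts["hypertension"]:
        s = shifts["hypertension"]
        cov_term += s * (covariates["hypertension"].astype(float) - p_ht)
        cov_var += s**2 * p_ht * (1 - p_ht)
    s_prev, s_curr = shifts["smoking_previous"], shifts["smoking_current"]
    if s_prev or s_curr:
        smoking = covariates["smoking"]
        lev = np.where(smoking == "previous", s_prev, 0.0) + np.where(
            smoking == "current", s_curr, 0.0
        )
        mean_lev = s_prev * p_prev + s_curr * p_curr
        cov_term += lev - mean_lev
        cov_var += s_prev**2 * p_prev + s_curr**2 * p_curr - mean_lev**2
    if shifts["education_lower"]:
        s = shifts["education_lower"]
        cov_term += s * ((covariates["education"] == "lower").astype(float) - p_edu)
        cov_var += s**2 * p_edu * (1 - p_edu)
    if shifts["bmi"]:
        # "bmi" effects are Pearson r: shift = r * residual SD * z(bmi)
        s = shifts["bmi"]
        z = (covariates["bmi"] - spec.bmi_mean) / spec.bmi_sd
        cov_term += s * z
        cov_var += s**2

    signal = age_term + hs_term + drift_term + cov_term
    var = base_var + cov_var
    return signal, 0.0, var


def _noise_sd(spec: CohortSpec, sex: str, region: str, systematic_var: float) -> float:
    target = spec.region_params[sex][region].baseline_sd
    if spec.sd_is_noise:
        return float(target)
    resid = target**2 - systematic_var
    if target > 0 and resid < 0:
        raise ValueError(
            f"baseline_sd for {sex}/{region} ({target:.1f}) is smaller than the SD "
            f"implied by the systematic terms ({np.sqrt(systematic_var):.1f}); "
            "increase baseline_sd or reduce slopes/confound effects"
        )
    return float(np.sqrt(max(resid, 0.0)))


def _generate_sex(
    spec: CohortSpec, sex: str, n: int, ss: np.random.SeedSequence, id_offset: int
) -> pd.DataFrame:
    # one child stream per column/purpose so streams are independent and
    # adding a column never perturbs the others
    names = [
        "age",
        "scan_date",
        "head_scaling",
        "hypertension",
        "smoking",
        "bmi",
        "education",
        "handedness",
        "selfreport",
        "hippo_common",
        "outlier_rows",
    ] + GENERATED_REGIONS
    children = dict(zip(names, ss.spawn(len(names))))
    rng = {k: np.random.default_rng(v) for k, v in children.items()}

    lo, hi = spec.age_range
    age = rng["age"].triangular(lo, spec.age_mode[sex], hi, size=n)
    scan_date = rng["scan_date"].uniform(*spec.scan_date_range, size=n)
    hs_mean = spec.head_scaling_mean + (
        spec.head_scaling_sex_offset if sex == "female" else -spec.head_scaling_sex_offset
    )
    head_scaling = rng["head_scaling"].normal(hs_mean, spec.head_scaling_sd, size=n)

    covariates = {
        "hypertension": rng["hypertension"].random(n) < spec.hypertension_prevalence,
        "smoking": np.asarray(["never", "previous", "current"])[
            rng["smoking"].choice(3, size=n, p=list(spec.smoking_probs))
        ],
        "bmi": rng["bmi"].normal(spec.bmi_mean, spec.bmi_sd, size=n),
        "education": np.where(
            rng["education"].random(n) < spec.education_lower_prob, "lower", "higher"
        ),
        "handedness": np.asarray(["right", "left", "ambidextrous"])[
            rng["handedness"].choice(3, size=n, p=list(spec.handedness_probs))
        ],
    }

    rho = spec.hippocampus_lr_correlation
    hippo_common_z = rng["hippo_common"].standard_normal(n)

    data: dict[str, np.ndarray] = {}
    for region in GENERATED_REGIONS:
        p = spec.region_params[sex][region]
        signal, _, sys_var = _systematic_terms(
            spec, sex, region, age, head_scaling, scan_date, covariates
        )
        noise_sd = _noise_sd(spec, sex, region, sys_var)
        if region.startswith("hippocampus"):
            # shared + idiosyncratic decomposition gives L/R correlation rho
            common = np.sqrt(rho) * noise_sd * hippo_common_z
            idio = np.sqrt(1 - rho) * noise_sd * rng[region].standard_normal(n)
            noise = common + idio
        else:
            noise = noise_sd * rng[region].standard_normal(n)
        values = p.baseline_volume + signal + noise
        # symmetric +/- displacement keeps the median unbiased
        if spec.outlier_fraction > 0 and n > 0:
            r = rng[region]
            k = int(round(spec.outlier_fraction * n))
            if k > 0:
                idx = r.choice(n, size=k, replace=False)
                sign = np.where(r.random(k) < 0.5, -1.0, 1.0)
                values = values.copy()
                values[idx] += sign * spec.outlier_magnitude * p.baseline_sd
        data[region] = values

    excluded = rng["selfreport"].random(n) < spec.selfreport_exclusion_fraction

    df = pd.DataFrame(
        {
            "participant_id": [f"P{(id_offset + i):06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "scan_date": scan_date,
            "head_scaling": head_scaling,
            "hypertension": covariates["hypertension"],
            "smoking": covariates["smoking"],
            "bmi": covariates["bmi"],
            "education": covariates["education"],
            "handedness": covariates["handedness"],
            "excluded_selfreport": excluded,
        }
    )
    for region in GENERATED_REGIONS:
        df[region] = data[region]
    df["hippocampus_bilateral"] = df["hippocampus_left"] + df["hippocampus_right"]
    return df[ALL_COLUMNS]


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort table (one row per participant).

    All randomness flows from ``spec.seed`` through a seed-sequence
    splitting scheme, so generation is bit-reproducible and per-column
    streams are independent.
    """
    spec = spec or CohortSpec()
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_female, ss_male = root.spawn(2)
    frames = [
        _generate_sex(spec, "female", spec.n_female, ss_female, 0),
        _generate_sex(spec, "male", spec.n_male, ss_male, spec.n_female),
    ]
    out = pd.concat(frames, ignore_index=True)
    return out


def average_hippocampus(cohort: pd.DataFrame) -> pd.Series:
    """Per-participant mean of left and right hippocampal volume."""
    return (cohort["hippocampus_left"] + cohort["hippocampus_right"]) / 2.0


# ---------------------------------------------------------------------------
# file round trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (header always present, UTF-8, '' for missing)."""
    missing = [c for c in ALL_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort is missing mandatory columns: {missing}")
    cohort.to_csv(path, index=False, columns=ALL_COLUMNS)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the schema.

    Raises :class:`SchemaError` listing any missing mandatory columns, or
    naming the first row/column holding a non-numeric value where a
    number is required.
    """
    df = pd.read_csv(path, dtype="object", keep_default_na=False, na_values=[""])
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"file is missing mandatory columns: {missing}")
    if len(df) == 0:
        out = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _empty_dtypes().items()})
        return out[ALL_COLUMNS]
    out = pd.DataFrame(index=df.index)
    for col in ALL_COLUMNS:
        raw = df[col]
        if col in _STRING_COLUMNS:
            out[col] = raw.astype(str)
        elif col in _BOOL_COLUMNS:
            vals = raw.astype(str).str.lower()
            bad = ~vals.isin(["true", "false"])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-boolean value {raw.iloc[row]!r} in column {col!r}, row {row}"
                )
            out[col] = vals == "true"
        else:
            converted = pd.to_numeric(raw, errors="coerce")
            bad = converted.isna() & raw.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-numeric value {raw.iloc[row]!r} in column {col!r}, row {row}"
                )
            out[col] = converted.astype(float)
    return out[ALL_COLUMNS]


def _empty_dtypes() -> dict[str, str]:
    d = {}
    for c in ALL_COLUMNS:
        if c in _STRING_COLUMNS:
            d[c] = "object"
        elif c in _BOOL_COLUMNS:
            d[c] = "bool"
        else:
            d[c] = "float64"
    return d
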