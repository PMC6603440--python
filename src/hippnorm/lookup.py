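"""Percentile lookup against a quantile nomogram.

Given sex, age, region and a volume (mm^3 or cm^3), the lookup locates
the query age on the nomogram's age grid (linear interpolation between
the flanking grid columns, or nearest-window when requested), then
converts the volume to a percentile by monotone linear interpolation
between the flanking quantile curves.  Volumes below the lowest (2.5th)
or above the highest (97.5th) estimated curve are censored as "<2.5" /
">97.5" rather than extrapolated -- tail shape beyond the outermost
curves is never guessed.

Ages outside the smoothed grid clamp to the nearest grid column and the
answer is flagged as extrapolated.  When requested, the published
head-size correction volume - (head_scaling - 1.29874) * b is applied
to the query volume first; mixing correction conventions (a
head-corrected query against an uncorrected nomogram or vice versa) is
an error, never silent.

A calibration audit runs every member of a held-out cohort through the
lookup and checks the percentiles for uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HEAD_SCALING_REFERENCE
from .deconfound import mad_filter
from .nomogram import NomogramTable

__all__ = [
    "LookupQuery",
    "LookupResult",
    "AuditResult",
    "lookup",
    "lookup_many",
    "self_percentile_audit",
]


@dataclass(frozen=True)
class LookupQuery:
    sex: str
    region: str
    age: float
    volume: float
    unit: str = "mm3"  # or "cm3"
    head_scaling: float | None = None
    apply_head_correction: bool = False

    def volume_mm3(self) -> float:
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.unit == "mm3":
            return float(self.volume)
        if self.unit == "cm3":
            return float(self.volume) * 1000.0
        raise ValueError(f"unknown unit {self.unit!r} (use 'mm3' or 'cm3')")


@dataclass
class LookupResult:
    percentile: float  # NaN when censored
    label: str  # e.g. "37.4", "<2.5", ">97.5"
    extrapolated: bool  # age clamped to the grid edge
    corrected_volume: float  # mm^3 actually compared against the curves

    @property
    def censored(self) -> bool:
        return self.label.startswith(("<", ">"))


def _check_conventions(nomogram: NomogramTable, query: LookupQuery) -> None:
    corrected_nomogram = "head_scaling" in nomogram.correction_set
    if query.apply_head_correction and not corrected_nomogram:
        raise ValueError(
            "query asks for head-size correction but the nomogram was built "
            "without it; correction conventions must match"
        )
    if query.apply_head_correction and query.head_scaling is None:
        raise ValueError("apply_head_correction requires a head_scaling value")
    if nomogram.sex not in ("all", query.sex):
        raise ValueError(f"nomogram is for sex {nomogram.sex!r}, query is {query.sex!r}")
    if nomogram.region != query.region:
        raise ValueError(
            f"nomogram is for region {nomogram.region!r}, query is {query.region!r}"
        )


def _corrected_volume(nomogram: NomogramTable, query: LookupQuery) -> float:
    v = query.volume_mm3()
    if query.apply_head_correction:
        if nomogram.head_slope is None:
            raise ValueError(
                "nomogram carries no head-scaling slope b; cannot apply correction"
            )
        v = v - (query.head_scaling - HEAD_SCALING_REFERENCE) * nomogram.head_slope
    return v


def _curves_at_age(
    nomogram: NomogramTable, age: float, age_mode: str
) -> tuple[np.ndarray, bool]:
    grid = nomogram.age_grid
    extrapolated = bool(age < grid[0] or age > grid[-1])
    if age_mode == "interpolate":
        at_age = np.array([np.interp(age, grid, c) for c in nomogram.curves])
    elif age_mode == "nearest":
        j = int(np.argmin(np.abs(grid - age)))
        at_age = nomogram.curves[:, j].copy()
    else:
        raise ValueError(f"unknown age_mode {age_mode!r}")
    return at_age, extrapolated


def lookup(
    nomogram: NomogramTable, query: LookupQuery, age_mode: str = "interpolate"
) -> LookupResult:
    """Percentile of a volume relative to a nomogram.

    Monotone non-decreasing in volume at fixed age; continuous except at
    the censoring bounds.
    """
    _check_conventions(nomogram, query)
    v = _corrected_volume(nomogram, query)
    at_age, extrapolated = _curves_at_age(nomogram, float(query.age), age_mode)
    levels = nomogram.quantile_levels
    if v < at_age[0]:
        return LookupResult(np.nan, f"<{levels[0]:g}", extrapolated, v)
    if v > at_age[-1]:
        return LookupResult(np.nan, f">{levels[-1]:g}", extrapolated, v)
    pct = float(np.interp(v, at_age, levels))
    return LookupResult(pct, f"{pct:.1f}", extrapolated, v)


def lookup_many(
    nomogram: NomogramTable, ages, volumes, age_mode: str = "interpolate"
) -> pd.DataFrame:
    """Vectorised lookup of already-corrected volumes (mm^3).

    Returns a frame with columns percentile (NaN when censored),
    censored_low / censored_high, extrapolated.
    """
    ages = np.asarray(ages, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    grid = nomogram.age_grid
    levels = nomogram.quantile_levels
    at_age = np.vstack([np.interp(ages, grid, c) for c in nomogram.curves])
    if age_mode == "nearest":
        j = np.argmin(np.abs(grid[None, :] - ages[:, None]), axis=1)
        at_age = nomogram.curves[:, j]
    low = volumes < at_age[0]
    high = volumes > at_age[-1]
    pct = np.full(volumes.shape, np.nan)
    mid = ~(low | high)
    for i in np.flatnonzero(mid):
        pct[i] = np.interp(volumes[i], at_age[:, i], levels)
    return pd.DataFrame(
        {
            "percentile": pct,
            "censored_low": low,
            "censored_high": high,
            "extrapolated": (ages < grid[0]) | (ages > grid[-1]),
        }
    )


@dataclass
class AuditResult:
    """Calibration of self-percentiles of a held-out cohort.

    If the nomogram describes the population, the percentile of each
    held-out member's own volume is uniform; censoring at the outer
    curves leaves the *conditional* distribution of the non-censored
    percentiles uniform on (low, high), which is what the KS statistic
    tests after rescaling to (0, 1).

    Because the percentile of a held-out member is its rank within the
    *estimated* nomogram, the comparison is a two-sample one (held-out
    members vs the training sample the curves summarise): ``ks_p`` uses
    the two-sample null with effective n = n_train*n_test/(n_train+n_test)
    when the nomogram records its training size, falling back to the
    (anti-conservative) one-sample null otherwise.
    """

    percentiles: np.ndarray  # NaN where censored
    frac_low: float
    frac_high: float
    histogram: np.ndarray  # counts per decile of the full 0-100 range
    ks_stat: float
    ks_p: float
    n: int


def self_percentile_audit(
    cohort: pd.DataFrame,
    nomogram: NomogramTable,
    region: str | None = None,
    values=None,
    mad_cutoff: float | None = 5.0,
) -> AuditResult:
    """Look up every member of a held-out cohort against the nomogram.

    ``values`` supplies volumes already consistent with the nomogram's
    correction set (aligned with the cohort); otherwise the raw region
    column is corrected with the nomogram's own stored correction model,
    so the conventions match by construction.  Outliers are MAD-filtered
    first, mirroring the construction of the nomogram.
    """
    region = region or nomogram.region
    if len(cohort) == 0:
        raise ValueError("held-out set is empty")
    if values is not None:
        v_all = np.asarray(values, dtype=float)
    else:
        v_all = nomogram.correct_volumes(
            cohort[region].to_numpy(dtype=float), cohort
        )
    if len(v_all) != len(cohort):
        raise ValueError("values must align with the cohort rows")
    df = cohort
    if nomogram.sex != "all":
        sel = (cohort["sex"] == nomogram.sex).to_numpy()
        df, v_all = cohort[sel], v_all[sel]
    if len(df) == 0:
        raise ValueError("held-out set is empty")
    v = v_all
    if mad_cutoff is not None:
        mask = mad_filter(v, cutoff=mad_cutoff).excluded
        df, v = df[~mask], v[~mask]
    res = lookup_many(nomogram, df["age"].to_numpy(dtype=float), v)
    pct = res["percentile"].to_numpy()
    n = len(res)
    frac_low = float(res["censored_low"].mean())
    frac_high = float(res["censored_high"].mean())
    finite = pct[np.isfinite(pct)]
    lo, hi = nomogram.quantile_levels[0], nomogram.quantile_levels[-1]
    rescaled = (finite - lo) / (hi - lo)
    ks = stats.kstest(rescaled, "uniform")
    ks_p = float(ks.pvalue)
    if nomogram.n_train:
        n_eff = nomogram.n_train * finite.size / (nomogram.n_train + finite.size)
        ks_p = float(
            np.clip(stats.kstwo.sf(ks.statistic, int(round(n_eff))), 0.0, 1.0)
        )
    full = pct.copy()
    full[np.isnan(full) & res["censored_low"].to_numpy()] = 0.0
    full[np.isnan(full) & res["censored_high"].to_numpy()] = 100.0
    hist, _ = np.histogram(full, bins=np.linspace(0, 100, 11))
    return AuditResult(
        percentiles=pct,
        frac_low=frac_low,
        frac_high=frac_high,
        histogram=hist,
        ks_stat=float(ks.statistic),
        ks_p=ks_p,
        n=n,
    )
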