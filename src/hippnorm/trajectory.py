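"""Trajectory inflections: ratio curves, numerical slopes, peak-age tests.

A region's trajectory relative to global atrophy is summarised by the
ratio of its volume to the *rest* of grey matter (total grey matter
minus the region).  The age at which the smoothed sliding-window ratio
curve peaks marks where the region starts declining faster than the
remaining grey matter.  Sex differences in that peak age are tested by
permutation: sex labels are shuffled within matched 1-year age bins,
both curves and their peaks are recomputed for every permutation, and
the p-value is the (add-one corrected) proportion of permutations with
an absolute male-female peak difference at least as extreme as
observed.  Across regions, Benjamini-Hochberg FDR is applied.

Numerical differentiation of smoothed curves (central differences on
the median-age grid) locates the inflection (most negative slope), with
a participant-resampling bootstrap for pointwise confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .nomogram import build_windows, gaussian_kernel, smooth_curve, window_statistic

__all__ = [
    "RatioCurve",
    "PermutationPeakTest",
    "rest_of_gm_ratio",
    "ratio_curve",
    "numerical_slope",
    "bootstrap_slope_band",
    "permutation_peak_test",
]


def rest_of_gm_ratio(cohort: pd.DataFrame, region: str) -> np.ndarray:
    """Per-participant region / (total grey matter - region), NaN when invalid."""
    v = cohort[region].to_numpy(dtype=float)
    rest = cohort["total_grey_matter"].to_numpy(dtype=float) - v
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rest > 0, v / rest, np.nan)
    return ratio


@dataclass
class RatioCurve:
    """Smoothed rest-of-grey-matter ratio curve for one region x sex."""

    region: str
    sex: str
    age_grid: np.ndarray  # window median ages
    ratio: np.ndarray  # smoothed window means
    sem: np.ndarray
    peak_bin: tuple[float, float]  # age span of the maximising window
    peak_age: float  # median age of the maximising window
    max_slope_bin: tuple[float, float]  # age span at most negative derivative
    window_fraction: float
    kernel_sd: float
    n_dropped: int = 0  # rows with total GM <= region


def _window_age_span(windows, w: int) -> tuple[float, float]:
    s = windows.starts[w]
    return (
        float(windows.sorted_ages[s]),
        float(windows.sorted_ages[s + windows.size - 1]),
    )


def ratio_curve(
    cohort: pd.DataFrame,
    region: str,
    sex: str | None,
    fraction: float = 0.10,
    step: int = 1,
    kernel_sd: float = 20.0,
) -> RatioCurve:
    """Windowed, smoothed ratio-to-rest-of-grey-matter curve.

    Ties in the maximum are broken toward the youngest window.  Volumes
    are used as given: deconfound the cohort consistently first.
    """
    df = cohort
    if sex is not None:
        df = df[df["sex"] == sex]
    ratio = rest_of_gm_ratio(df, region)
    valid = np.isfinite(ratio)
    n_dropped = int((~valid).sum())
    if n_dropped:
        import warnings

        warnings.warn(
            f"{n_dropped} rows with total grey matter <= {region} excluded",
            stacklevel=2,
        )
    df = df[valid]
    ratio = ratio[valid]
    windows = build_windows(df["age"].to_numpy(dtype=float), fraction, step)
    raw = window_statistic(ratio, windows, "mean")
    sem = window_statistic(ratio, windows, "sem")
    smoothed = smooth_curve(raw, kernel_sd) if raw.size > 1 else raw
    w_peak = int(np.argmax(smoothed))
    slope = numerical_slope(smoothed, windows.median_ages)
    w_slope = int(np.argmin(slope))
    return RatioCurve(
        region=region,
        sex=sex if sex is not None else "all",
        age_grid=windows.median_ages,
        ratio=smoothed,
        sem=sem,
        peak_bin=_window_age_span(windows, w_peak),
        peak_age=float(windows.median_ages[w_peak]),
        max_slope_bin=_window_age_span(windows, w_slope),
        window_fraction=fraction,
        kernel_sd=kernel_sd,
        n_dropped=n_dropped,
    )


def numerical_slope(curve, age_grid) -> np.ndarray:
    """Central-difference derivative of a curve on its (strictly increasing) grid."""
    y = np.asarray(curve, dtype=float)
    x = np.asarray(age_grid, dtype=float)
    if y.size < 3:
        raise ValueError("numerical differentiation requires at least 3 grid points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("age grid must be strictly increasing")
    return np.gradient(y, x)


def bootstrap_slope_band(
    ages,
    values,
    fraction: float = 0.10,
    step: int = 1,
    kernel_sd: float = 20.0,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int | None = None,
) -> dict:
    """Pointwise bootstrap percentile band for the windowed-curve slope.

    Participants are resampled with replacement; the windowed, smoothed
    curve and its central-difference slope are rebuilt per replicate and
    interpolated back onto the observed grid.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    windows = build_windows(ages, fraction, step)
    base = smooth_curve(window_statistic(values, windows, "mean"), kernel_sd)
    grid = windows.median_ages
    slope = numerical_slope(base, grid)
    boots = np.empty((n_boot, grid.size))
    n = ages.size
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        w = build_windows(ages[idx], fraction, step)
        c = smooth_curve(window_statistic(values[idx], w, "mean"), kernel_sd)
        # resampling duplicates ages; collapse tied grid points before
        # differentiating
        u, inv = np.unique(w.median_ages, return_inverse=True)
        cu = np.bincount(inv, weights=c) / np.bincount(inv)
        s = numerical_slope(cu, u)
        boots[b] = np.interp(grid, u, s)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [a, 1.0 - a], axis=0)
    return {
        "age_grid": grid,
        "slope": slope,
        "lower": lo,
        "upper": hi,
        "max_slope_index": int(np.argmin(slope)),
        "level": level,
    }


# ---------------------------------------------------------------------------
# permutation test for sex differences in peak-ratio age
# ---------------------------------------------------------------------------


@dataclass
class PermutationPeakTest:
    """Permutation test of the male-female difference in peak-ratio age."""

    results: pd.DataFrame  # region, observed_diff_years, p, p_fdr, n_perm, seed
    n_permutations: int
    seed: int | None
    null_diffs: dict[str, np.ndarray]

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def _curve_peak_age(
    ages_sorted: np.ndarray,
    values_sorted: np.ndarray,
    fraction: float,
    kernel: np.ndarray,
) -> float:
    """Median age of the window maximising the smoothed windowed mean.

    Fast path used inside permutations: cumulative-sum window means over
    age-sorted values, renormalised Gaussian smoothing, first (youngest)
    maximum on ties.
    """
    n = ages_sorted.size
    size = int(np.ceil(fraction * n))
    cs = np.concatenate(([0.0], np.cumsum(values_sorted)))
    means = (cs[size:] - cs[:-size]) / size
    if kernel.size > 1 and means.size > 1:
        start = (kernel.size - 1) // 2
        num = np.convolve(means, kernel, mode="full")[start : start + means.size]
        den = np.convolve(np.ones_like(means), kernel, mode="full")[start : start + means.size]
        means = num / den
    w = int(np.argmax(means))
    lo = w + (size - 1) // 2
    hi = w + size // 2
    return 0.5 * (ages_sorted[lo] + ages_sorted[hi])


def permutation_peak_test(
    cohort: pd.DataFrame,
    regions,
    n_permutations: int = 5000,
    seed: int | None = None,
    fraction: float = 0.10,
    kernel_sd: float = 20.0,
    bin_width: float = 1.0,
    add_one: bool = True,
) -> PermutationPeakTest:
    """Sex difference in peak rest-of-grey-matter-ratio age, by permutation.

    The observed statistic per region is (male peak age - female peak
    age).  The null shuffles sex labels within matched ``bin_width``-year
    age bins -- a label permutation, so per-bin group sizes are exactly
    preserved -- and recomputes both sex curves and peaks from scratch.
    Two-sided p = (#{|null| >= |observed|} + 1) / (n + 1); ``add_one=False``
    recovers the raw-proportion definition.  Region-wise p-values are
    Benjamini-Hochberg adjusted.
    """
    if isinstance(regions, str):
        regions = [regions]
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1 (p undefined otherwise)")
    sexes = set(cohort["sex"].unique())
    if not {"female", "male"} <= sexes:
        raise ValueError("both sexes must be present in the cohort")

    ages = cohort["age"].to_numpy(dtype=float)
    order = np.argsort(ages, kind="stable")
    ages_s = ages[order]
    is_male_obs = (cohort["sex"].to_numpy() == "male")[order]
    bins = np.floor(ages_s / bin_width).astype(int)
    # positions grouped by bin in fixed order; a permutation reassigns the
    # bin's labels to the bin's positions in random order
    base_positions = np.argsort(bins, kind="stable")

    kernel = gaussian_kernel(kernel_sd)
    rng = np.random.default_rng(seed)

    ratios_s = {}
    for region in regions:
        r = rest_of_gm_ratio(cohort, region)[order]
        if np.isnan(r).any():
            raise ValueError(
                f"invalid ratios (total grey matter <= {region}); clean the cohort first"
            )
        ratios_s[region] = r

    def peak_diff(is_male: np.ndarray, region: str) -> float:
        r = ratios_s[region]
        pm = _curve_peak_age(ages_s[is_male], r[is_male], fraction, kernel)
        pf = _curve_peak_age(ages_s[~is_male], r[~is_male], fraction, kernel)
        return pm - pf

    observed = {region: peak_diff(is_male_obs, region) for region in regions}

    null = {region: np.empty(n_permutations) for region in regions}
    labels_by_bin = is_male_obs[base_positions]
    for b in range(n_permutations):
        shuffled_positions = base_positions[
            np.argsort(bins * 1.0 + rng.random(bins.size), kind="stable")
        ]
        perm = np.empty_like(is_male_obs)
        perm[shuffled_positions] = labels_by_bin
        for region in regions:
            null[region][b] = peak_diff(perm, region)

    rows = []
    for region in regions:
        obs = observed[region]
        extreme = int((np.abs(null[region]) >= abs(obs)).sum())
        if add_one:
            p = (extreme + 1) / (n_permutations + 1)
        else:
            p = extreme / n_permutations
        rows.append({"region": region, "observed_diff_years": obs, "p": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["n_perm"] = n_permutations
    df["seed"] = seed
    return PermutationPeakTest(
        results=df, n_permutations=n_permutations, seed=seed, null_diffs=null
    )
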