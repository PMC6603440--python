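"""Joinpoint (piecewise-linear change-point) regression on binned trajectories.

The trend of mean volume per 1-year, non-overlapping age bin is fitted
with continuous piecewise-linear segments joined at *joinpoints*.
Candidate joinpoints sit on the observed bin mid-ages (grid search);
segments are fitted by OLS on a hinge basis, so the hinge coefficients
are directly the slope changes Δm.  Admissibility follows the usual
grid-search constraints: no joinpoint within two data points of either
end of the series, at least two data points between consecutive
joinpoints, and at least seven data points per joinpoint.

The number of joinpoints (0 to k_max, default 4) is selected
sequentially by a Monte Carlo permutation test assuming uncorrelated
errors: to test k vs k+1, the residuals of the k-joinpoint fit are
permuted, both models refitted on each permuted series, and the
improvement statistic compared with its null distribution.  The ladder
is Bonferroni-adjusted (per-step alpha = alpha / k_max).  Slope changes
are reported with their OLS standard errors and a t statistic on
n_bins - 2(k+1) degrees of freedom.  Joinpoint confidence intervals are
the span of candidate bins whose constrained fit is not rejected
against the unconstrained optimum by an F comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedSeries",
    "JoinpointFit",
    "JoinpointModel",
    "bin_series",
    "max_feasible_joinpoints",
    "fit_k_joinpoints",
    "select_model",
    "joinpoint_ci",
]

MIN_EDGE_GAP = 2  # data points required outside the outermost joinpoints
MIN_BETWEEN = 2  # data points required strictly between consecutive joinpoints
POINTS_PER_JOINPOINT = 7


@dataclass
class BinnedSeries:
    """Mean volume per 1-year, non-overlapping age bin."""

    bin_start: np.ndarray  # bin is [start, start + width)
    bin_mid: np.ndarray
    mean_volume: np.ndarray
    n_in_bin: np.ndarray
    bin_width: float = 1.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_mid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_mid": self.bin_mid,
                "mean_volume": self.mean_volume,
                "n": self.n_in_bin,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bin_width: float = 1.0) -> "BinnedSeries":
        return cls(
            bin_start=df["bin_start"].to_numpy(dtype=float),
            bin_mid=df["bin_mid"].to_numpy(dtype=float),
            mean_volume=df["mean_volume"].to_numpy(dtype=float),
            n_in_bin=df["n"].to_numpy(dtype=int),
            bin_width=bin_width,
        )

    def bin_label(self, i: int) -> str:
        a = self.bin_start[i]
        return f"{a:g}-{a + self.bin_width:g}"


def bin_series(
    cohort: pd.DataFrame,
    region: str,
    sex: str | None = None,
    bin_width: float = 1.0,
    values=None,
) -> BinnedSeries:
    """Bin volumes into [a, a + width) age bins and average within bins.

    ``values`` overrides the region column (e.g. deconfounded volumes
    aligned with the cohort rows).  Empty bins are dropped with a warning.
    """
    df = cohort
    keep = np.ones(len(df), dtype=bool)
    if sex is not None:
        keep &= (df["sex"] == sex).to_numpy()
    ages = df["age"].to_numpy(dtype=float)[keep]
    v = (
        np.asarray(values, dtype=float)[keep]
        if values is not None
        else df[region].to_numpy(dtype=float)[keep]
    )
    ok = np.isfinite(v) & np.isfinite(ages)
    ages, v = ages[ok], v[ok]
    if ages.size == 0:
        raise ValueError("no usable observations to bin")
    start0 = np.floor(ages.min() / bin_width) * bin_width
    idx = np.floor((ages - start0) / bin_width).astype(int)
    starts, mids, means, counts = [], [], [], []
    for b in range(idx.max() + 1):
        sel = idx == b
        n = int(sel.sum())
        a = start0 + b * bin_width
        if n == 0:
            warnings.warn(f"empty age bin [{a:g}, {a + bin_width:g}) dropped", stacklevel=2)
            continue
        starts.append(a)
        mids.append(a + bin_width / 2.0)
        means.append(float(v[sel].mean()))
        counts.append(n)
    return BinnedSeries(
        bin_start=np.array(starts),
        bin_mid=np.array(mids),
        mean_volume=np.array(means),
        n_in_bin=np.array(counts, dtype=int),
        bin_width=bin_width,
    )


def max_feasible_joinpoints(n_bins: int, k_max: int = 4) -> int:
    """Largest admissible k for a series length (7 points per joinpoint,
    edge and spacing constraints)."""
    by_points = n_bins // POINTS_PER_JOINPOINT
    # positions exist only if the spacing constraints leave room
    by_spacing = 0
    for k in range(1, k_max + 1):
        if n_bins - 1 - MIN_EDGE_GAP - (k - 1) * (MIN_BETWEEN + 1) >= MIN_EDGE_GAP:
            by_spacing = k
    return max(0, min(k_max, by_points, by_spacing))


def _admissible_placements(n_bins: int, k: int) -> list[tuple[int, ...]]:
    """All index tuples (into bin_mid) satisfying the spacing rules."""
    lo, hi = MIN_EDGE_GAP, n_bins - 1 - MIN_EDGE_GAP
    if k == 0:
        return [()]
    out = []
    for combo in combinations(range(lo, hi + 1), k):
        if all(b - a >= MIN_BETWEEN + 1 for a, b in zip(combo, combo[1:])):
            out.append(combo)
    return out


def _design(x: np.ndarray, taus: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for t in taus:
        cols.append(np.maximum(0.0, x - t))
    return np.column_stack(cols)


@dataclass
class JoinpointFit:
    """Least-squares continuous piecewise-linear fit at fixed k."""

    k: int
    tau_indices: tuple[int, ...]
    taus: np.ndarray  # joinpoint positions (bin mid ages)
    beta: np.ndarray  # [intercept, slope, hinge_1 .. hinge_k]
    rss: float
    fitted: np.ndarray

    @property
    def segment_slopes(self) -> np.ndarray:
        return np.cumsum(self.beta[1:])

    @property
    def slope_changes(self) -> np.ndarray:
        return self.beta[2:]


def fit_k_joinpoints(series: BinnedSeries, k: int) -> JoinpointFit:
    """Exhaustive grid search over admissible joinpoint placements.

    Deterministic: returns the global RSS minimum over all placements at
    bin mid-ages (first placement on exact ties).
    """
    x, y = series.bin_mid, series.mean_volume
    n = series.n_bins
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > 0 and k > max_feasible_joinpoints(n, k):
        raise ValueError(
            f"k={k} infeasible for {n} bins: need >= {POINTS_PER_JOINPOINT} points "
            f"per joinpoint, >= {MIN_BETWEEN} points between joinpoints and "
            f">= {MIN_EDGE_GAP} points from each end"
        )
    best = None
    for combo in _admissible_placements(n, k):
        taus = x[list(combo)]
        X = _design(x, taus)
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        if best is None or rss < best.rss - 1e-12:
            best = JoinpointFit(
                k=k, tau_indices=combo, taus=taus, beta=beta, rss=rss, fitted=fitted
            )
    return best


def _batch_best_rss(x: np.ndarray, placements, Y: np.ndarray) -> np.ndarray:
    """Minimum RSS over placements for each column of Y (n x B), via
    precomputed orthonormal bases: RSS = ||y||^2 - ||Q^T y||^2."""
    norms = np.sum(Y * Y, axis=0)
    best = np.full(Y.shape[1], np.inf)
    for combo in placements:
        taus = x[list(combo)]
        Q, _ = np.linalg.qr(_design(x, taus))
        proj = Q.T @ Y
        rss = norms - np.sum(proj * proj, axis=0)
        np.minimum(best, rss, out=best)
    return np.maximum(best, 0.0)


@dataclass
class JoinpointModel:
    """Selected joinpoint model with slope-change inference."""

    series: BinnedSeries
    k: int
    fit: JoinpointFit
    joinpoint_ages: np.ndarray
    joinpoint_bins: list[str]
    joinpoint_cis: list[tuple[float, float]]  # age intervals
    segment_slopes: np.ndarray
    slope_changes: np.ndarray
    slope_change_se: np.ndarray
    t_stats: np.ndarray
    p_t: np.ndarray
    df: int
    ladder_pvalues: list[float]  # permutation p per sequential step
    alpha: float
    n_perm: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.k):
            rows.append(
                {
                    "joinpoint": self.joinpoint_bins[i],
                    "joinpoint_age": self.joinpoint_ages[i],
                    "ci_low": self.joinpoint_cis[i][0],
                    "ci_high": self.joinpoint_cis[i][1],
                    "slope_change": self.slope_changes[i],
                    "se": self.slope_change_se[i],
                    "t": self.t_stats[i],
                    "p": self.p_t[i],
                    "df": self.df,
                }
            )
        return pd.DataFrame(rows)


def select_model(
    series: BinnedSeries,
    k_max: int = 4,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> JoinpointModel:
    """Sequential Monte Carlo permutation selection of the joinpoint count.

    Tests k vs k+1 starting at k=0 with statistic
    (RSS_k - RSS_{k+1}) / RSS_{k+1}; the null permutes the residuals of
    the k-joinpoint fit and refits both models.  Stops when the
    Bonferroni-adjusted step (alpha / k_max_feasible) is not significant.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve alpha = 0.05")
    n = series.n_bins
    kf = max_feasible_joinpoints(n, k_max)
    x, y = series.bin_mid, series.mean_volume
    rng = np.random.default_rng(seed)
    ladder: list[float] = []
    k = 0
    fit_k = fit_k_joinpoints(series, 0)
    step_alpha = alpha / kf if kf > 0 else alpha
    while k < kf:
        fit_k1 = fit_k_joinpoints(series, k + 1)
        if fit_k1.rss <= 0 or fit_k.rss <= fit_k1.rss:
            obs = np.inf if fit_k.rss > fit_k1.rss else 0.0
        else:
            obs = (fit_k.rss - fit_k1.rss) / fit_k1.rss
        resid = y - fit_k.fitted
        Y = fit_k.fitted[:, None] + np.column_stack(
            [rng.permutation(resid) for _ in range(n_perm)]
        )
        p_k = _admissible_placements(n, k)
        p_k1 = _admissible_placements(n, k + 1)
        rss_k = _batch_best_rss(x, p_k, Y)
        rss_k1 = _batch_best_rss(x, p_k1, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(rss_k1 > 0, (rss_k - rss_k1) / rss_k1, np.inf)
        p_val = (int((stat >= obs).sum()) + 1) / (n_perm + 1)
        ladder.append(p_val)
        if p_val >= step_alpha:
            break
        k += 1
        fit_k = fit_k1

    df = n - 2 * (k + 1)
    if k > 0:
        X = _design(x, fit_k.taus)
        resid = y - fit_k.fitted
        sigma2 = float(resid @ resid) / df if df > 0 else np.nan
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov)[2:])
        t = fit_k.slope_changes / se
        p_t = 2.0 * stats.t.sf(np.abs(t), df)
        cis = joinpoint_ci(series, fit_k, level=ci_level)
        ages = fit_k.taus
        bins = [series.bin_label(i) for i in fit_k.tau_indices]
    else:
        se = np.array([])
        t = np.array([])
        p_t = np.array([])
        cis = []
        ages = np.array([])
        bins = []
    return JoinpointModel(
        series=series,
        k=k,
        fit=fit_k,
        joinpoint_ages=ages,
        joinpoint_bins=bins,
        joinpoint_cis=cis,
        segment_slopes=fit_k.segment_slopes,
        slope_changes=fit_k.slope_changes,
        slope_change_se=se,
        t_stats=t,
        p_t=p_t,
        df=df,
        ladder_pvalues=ladder,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )


def joinpoint_ci(
    series: BinnedSeries, fit: JoinpointFit, level: float = 0.95
) -> list[tuple[float, float]]:
    """Inversion confidence interval for each joinpoint position.

    For joinpoint i, every admissible candidate bin is accepted whose
    best fit with joinpoint i constrained there (others re-optimised) is
    not rejected against the unconstrained optimum by an F comparison at
    1 - level; the CI is the age span of accepted bins.  Always contains
    the point estimate.
    """
    if fit.k < 1:
        raise ValueError("confidence intervals require a model with k >= 1")
    n = series.n_bins
    x, y = series.bin_mid, series.mean_volume
    df = n - 2 * (fit.k + 1)
    if df <= 0:
        raise ValueError("no residual degrees of freedom for the F comparison")
    f_crit = stats.f.ppf(level, 1, df)
    scale = fit.rss / df if fit.rss > 0 else 0.0
    placements = _admissible_placements(n, fit.k)
    # best constrained RSS per (joinpoint i, candidate position)
    out = []
    for i in range(fit.k):
        accepted = []
        candidates = sorted({c[i] for c in placements})
        for cand in candidates:
            best = np.inf
            for combo in placements:
                if combo[i] != cand:
                    continue
                taus = x[list(combo)]
                X = _design(x, taus)
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((y - X @ beta) ** 2))
                best = min(best, rss)
            if scale == 0.0:
                ok = best <= fit.rss + 1e-9
            else:
                ok = (best - fit.rss) / scale <= f_crit
            if ok:
                accepted.append(cand)
        if len(accepted) == len(candidates):
            warnings.warn(
                "all candidate bins accepted; joinpoint CI spans the full range",
                stacklevel=2,
            )
        lo = series.bin_start[min(accepted)]
        hi = series.bin_start[max(accepted)] + series.bin_width
        out.append((float(lo), float(hi)))
    return out
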