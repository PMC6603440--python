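"""Sliding-window quantile nomograms of volume against age.

The normative model is deliberately non-parametric: participants are
sorted by age and a window holding a fixed *fraction* of them (default
10%) slides along the age distribution one observation at a time.
Within each window the nine reference percentiles (2.5, 5, 10, 25, 50,
75, 90, 95, 97.5) and the mean/SEM are computed, plotted against the
window's median age, and the resulting curves are smoothed with a
moving-average Gaussian kernel (default SD = 20 grid steps).  Because
the tails of the age distribution are thin, the outermost windows span
wider age ranges, which is a property of the data rather than of the
method.

Age-adjusted percentile tables are obtained by subtracting the
sliding-window mean curve from each participant's volume (interpolated
at their age) and adding the residual back onto the cohort grand mean.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconfound import fit_confound_model, apply_deconfound, mad_filter

__all__ = [
    "QUANTILE_LEVELS",
    "SlidingWindows",
    "NomogramTable",
    "build_windows",
    "window_statistic",
    "smooth_curve",
    "build_nomogram",
    "age_adjusted_percentiles",
    "fixed_bin_curves",
]

QUANTILE_LEVELS = (2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0, 97.5)


@dataclass
class SlidingWindows:
    """Index structure of overlapping fixed-quantile-width age windows.

    ``order`` sorts the original observations by age; window *w* holds
    sorted positions ``starts[w] : starts[w] + size``.
    """

    order: np.ndarray  # argsort of ages
    sorted_ages: np.ndarray
    starts: np.ndarray
    size: int
    step: int
    median_ages: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def members(self, w: int) -> np.ndarray:
        """Original-index member set of window w."""
        s = self.starts[w]
        return self.order[s : s + self.size]


def _window_medians(sorted_ages: np.ndarray, starts: np.ndarray, size: int) -> np.ndarray:
    lo = starts + (size - 1) // 2
    hi = starts + size // 2
    return 0.5 * (sorted_ages[lo] + sorted_ages[hi])


def build_windows(ages, fraction: float = 0.10, step: int = 1) -> SlidingWindows:
    """Overlapping windows over age-sorted observations.

    Each window contains ceil(fraction * n) members and advances by
    ``step`` sorted observations; the x-coordinate of a window is the
    median age of its members.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if n < 10.0 / fraction:
        raise ValueError(
            f"need at least {int(np.ceil(10.0 / fraction))} observations for "
            f"fraction={fraction}, got {n}"
        )
    size = int(np.ceil(fraction * n))
    order = np.argsort(ages, kind="stable")
    sorted_ages = ages[order]
    starts = np.arange(0, n - size + 1, step)
    med = _window_medians(sorted_ages, starts, size)
    return SlidingWindows(
        order=order,
        sorted_ages=sorted_ages,
        starts=starts,
        size=size,
        step=step,
        median_ages=med,
    )


def _sorted_view(values: np.ndarray, windows: SlidingWindows) -> np.ndarray:
    sv = values[windows.order]
    view = np.lib.stride_tricks.sliding_window_view(sv, windows.size)
    return view[windows.starts]


def window_statistic(values, windows: SlidingWindows, statistic="mean"):
    """Raw per-window curve of a statistic over the window members.

    ``statistic`` is ``"mean"``, ``"sem"`` or ``("quantile", level)``
    with level in percent.  SEM of a window with < 2 members is NaN
    (flagged, not dropped).
    """
    values = np.asarray(values, dtype=float)
    if values.size != windows.order.size:
        raise ValueError("values must align with the observations the windows were built on")
    view = _sorted_view(values, windows)
    if statistic == "mean":
        return view.mean(axis=1)
    if statistic == "sem":
        if windows.size < 2:
            return np.full(windows.n_windows, np.nan)
        return view.std(axis=1, ddof=1) / np.sqrt(windows.size)
    if isinstance(statistic, tuple) and statistic[0] == "quantile":
        level = float(statistic[1])
        return np.quantile(view, level / 100.0, axis=1)  # type 7 / linear
    raise ValueError(f"unknown statistic {statistic!r}")


def gaussian_kernel(sd: float) -> np.ndarray:
    """Normalised Gaussian weights truncated at +/- 3 SD (odd length)."""
    if sd < 0:
        raise ValueError(f"kernel SD must be >= 0, got {sd}")
    if sd == 0:
        return np.array([1.0])
    half = int(np.ceil(3.0 * sd))
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (x / sd) ** 2)
    return w / w.sum()


def smooth_curve(curve, kernel_sd_gridsteps: float = 20.0) -> np.ndarray:
    """Moving-average smoothing with a Gaussian weight profile.

    The SD is expressed in grid steps of the window sequence.  Weights
    are renormalised at the boundaries (no padding), so the smoothed
    curve is defined on the full grid.  A weighted moving average with
    shared positive weights preserves the pointwise ordering of multiple
    curves, hence quantile curves cannot cross through smoothing.
    """
    y = np.asarray(curve, dtype=float)
    if y.size < 2:
        raise ValueError("smoothing requires at least 2 grid points")
    w = gaussian_kernel(kernel_sd_gridsteps)
    if w.size == 1:
        return y.copy()
    # centre-slice of the full convolution: correct also when the kernel
    # is longer than the curve (np.convolve 'same' follows the longer input)
    start = (w.size - 1) // 2
    num = np.convolve(y, w, mode="full")[start : start + y.size]
    den = np.convolve(np.ones_like(y), w, mode="full")[start : start + y.size]
    return num / den


@dataclass
class NomogramTable:
    """Quantile nomogram for one sex x region x correction set."""

    sex: str
    region: str
    correction_set: tuple[str, ...]
    quantile_levels: np.ndarray
    age_grid: np.ndarray  # window median ages, years
    curves: np.ndarray  # smoothed, shape (levels, grid)
    raw_curves: np.ndarray  # pre-smoothing quantile curves
    window_mean: np.ndarray  # raw window means
    mean_curve: np.ndarray  # smoothed mean
    window_sem: np.ndarray
    n_per_window: np.ndarray
    window_fraction: float
    kernel_sd: float
    head_slope: float | None = None  # b of the head-size correction, if fitted
    # full correction model: confound -> (slope, reference), so query
    # volumes can be corrected with the same convention as the curves
    correction_model: dict | None = None
    n_train: int | None = None  # participants the curves were estimated from
    seed: int | None = None

    def correct_volumes(self, volumes, confound_values) -> np.ndarray:
        """Apply the nomogram's own confound correction to query volumes."""
        v = np.asarray(volumes, dtype=float).copy()
        if not self.correction_model:
            return v
        for c, (slope, ref) in self.correction_model.items():
            x = np.asarray(confound_values[c], dtype=float)
            v -= slope * (x - ref)
        return v

    def to_csv(self, path) -> None:
        """CSV with '#'-prefixed metadata lines, then one row per grid age."""
        meta = {
            "sex": self.sex,
            "region": self.region,
            "correction_set": ",".join(self.correction_set),
            "window_fraction": self.window_fraction,
            "kernel_sd": self.kernel_sd,
            "head_slope": "" if self.head_slope is None else repr(self.head_slope),
            "n_train": "" if self.n_train is None else self.n_train,
            "seed": "" if self.seed is None else self.seed,
        }
        for c, (slope, ref) in (self.correction_model or {}).items():
            meta[f"slope_{c}"] = repr(slope)
            meta[f"ref_{c}"] = repr(ref)
        df = pd.DataFrame({"age": self.age_grid, "n": self.n_per_window})
        df["mean"] = self.mean_curve
        df["sem"] = self.window_sem
        for lev, row in zip(self.quantile_levels, self.curves):
            df[f"q{lev:g}"] = row
        buf = io.StringIO()
        for k, v in meta.items():
            buf.write(f"# {k}: {v}\n")
        df.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "NomogramTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        levels = np.array(
            [float(c[1:]) for c in df.columns if c.startswith("q")], dtype=float
        )
        curves = np.vstack([df[f"q{lev:g}"].to_numpy() for lev in levels])
        correction = {}
        for key, val in meta.items():
            if key.startswith("slope_") and val:
                c = key[len("slope_"):]
                correction[c] = (float(val), float(meta.get(f"ref_{c}", "nan")))
        return cls(
            sex=meta.get("sex", ""),
            region=meta.get("region", ""),
            correction_set=tuple(
                c for c in meta.get("correction_set", "").split(",") if c
            ),
            quantile_levels=levels,
            age_grid=df["age"].to_numpy(dtype=float),
            curves=curves,
            raw_curves=curves.copy(),
            window_mean=df["mean"].to_numpy(dtype=float),
            mean_curve=df["mean"].to_numpy(dtype=float),
            window_sem=df["sem"].to_numpy(dtype=float),
            n_per_window=df["n"].to_numpy(dtype=int),
            window_fraction=float(meta.get("window_fraction", np.nan)),
            kernel_sd=float(meta.get("kernel_sd", np.nan)),
            head_slope=float(meta["head_slope"]) if meta.get("head_slope") else None,
            correction_model=correction or None,
            n_train=int(meta["n_train"]) if meta.get("n_train") else None,
            seed=int(meta["seed"]) if meta.get("seed") else None,
        )


def _prepare(
    cohort: pd.DataFrame,
    region: str,
    sex: str | None,
    correction_set,
    mad_cutoff: float | None,
):
    """Filter to sex, drop flagged/outlier rows, regress out the confounds."""
    df = cohort
    if "excluded_selfreport" in df.columns:
        df = df[~df["excluded_selfreport"].astype(bool)]
    if sex is not None:
        df = df[df["sex"] == sex]
    if len(df) == 0:
        raise ValueError(f"no rows for sex={sex!r}")
    values = df[region].to_numpy(dtype=float)
    if mad_cutoff is not None:
        mask = mad_filter(values, cutoff=mad_cutoff).excluded
        df = df[~mask]
        values = values[~mask]
    correction_model = None
    if correction_set:
        model = fit_confound_model(df, region, confounds=list(correction_set))
        values = apply_deconfound(values, model, df)
        correction_model = {
            c: (model.slopes[c], model.reference_values[c]) for c in model.confounds
        }
    return df, values, correction_model


def build_nomogram(
    cohort: pd.DataFrame,
    region: str,
    sex: str | None,
    correction_set=("scan_date", "head_scaling"),
    fraction: float = 0.10,
    step: int = 1,
    kernel_sd: float = 20.0,
    mad_cutoff: float | None = 5.0,
    levels=QUANTILE_LEVELS,
    seed: int | None = None,
) -> NomogramTable:
    """Full nomogram construction: filter, deconfound, window, smooth.

    Nomograms are built per sex (pass ``sex``) because the age
    trajectories differ between sexes; ``correction_set`` lists the
    confounds regressed out first (empty tuple = raw volumes).
    """
    df, values, correction_model = _prepare(cohort, region, sex, correction_set, mad_cutoff)
    windows = build_windows(df["age"].to_numpy(dtype=float), fraction, step)
    levels = np.asarray(levels, dtype=float)
    view = _sorted_view(values, windows)
    raw = np.quantile(view, levels / 100.0, axis=1)
    smoothed = np.vstack([smooth_curve(r, kernel_sd) for r in raw]) if raw.shape[1] > 1 else raw
    wmean = view.mean(axis=1)
    wsem = view.std(axis=1, ddof=1) / np.sqrt(windows.size)
    return NomogramTable(
        sex=sex if sex is not None else "all",
        region=region,
        correction_set=tuple(correction_set),
        quantile_levels=levels,
        age_grid=windows.median_ages,
        curves=smoothed,
        raw_curves=raw,
        window_mean=wmean,
        mean_curve=smooth_curve(wmean, kernel_sd) if wmean.size > 1 else wmean,
        window_sem=wsem,
        n_per_window=np.full(windows.n_windows, windows.size),
        window_fraction=fraction,
        kernel_sd=kernel_sd,
        head_slope=(correction_model or {}).get("head_scaling", (None,))[0],
        correction_model=correction_model,
        n_train=len(df),
        seed=seed,
    )


def age_adjusted_percentiles(
    cohort: pd.DataFrame,
    region: str,
    sex: str | None,
    correction_set=("scan_date", "head_scaling"),
    fraction: float = 0.10,
    step: int = 1,
    kernel_sd: float = 20.0,
    mad_cutoff: float | None = 5.0,
    levels=QUANTILE_LEVELS,
    use_smoothed: bool = False,
) -> pd.DataFrame:
    """Age-adjusted percentile table for one sex x region.

    Each participant's residual from the sliding-window mean curve
    (interpolated at their age; clamped to the nearest grid edge outside
    the grid, with the number of clamped rows reported) is added back
    onto the grand mean, and the nine empirical percentiles of the
    adjusted values form the table.  ``use_smoothed`` interpolates
    against the smoothed rather than the raw mean curve.
    """
    df, values, _ = _prepare(cohort, region, sex, correction_set, mad_cutoff)
    ages = df["age"].to_numpy(dtype=float)
    windows = build_windows(ages, fraction, step)
    mean_raw = window_statistic(values, windows, "mean")
    curve = smooth_curve(mean_raw, kernel_sd) if use_smoothed else mean_raw
    grid = windows.median_ages
    n_clamped = int(((ages < grid[0]) | (ages > grid[-1])).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} ages outside the window grid; nearest-edge curve value used",
            stacklevel=2,
        )
    at_age = np.interp(ages, grid, curve)
    adjusted = values - at_age + values.mean()
    levels = np.asarray(levels, dtype=float)
    table = np.quantile(adjusted, levels / 100.0)
    return pd.DataFrame({"level": levels, "volume": table})


def fixed_bin_curves(
    cohort: pd.DataFrame,
    region: str,
    sex: str | None = None,
    bin_width: float = 5.0,
    correction_set=("scan_date", "head_scaling"),
    mad_cutoff: float | None = 5.0,
) -> pd.DataFrame:
    """Mean/SEM per non-overlapping fixed-width age bin [a, a + width).

    Cross-check for the sliding-window curves; bins are half-open so no
    observation is double counted, empty bins are omitted with a warning.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    df, values, _ = _prepare(cohort, region, sex, correction_set, mad_cutoff)
    ages = df["age"].to_numpy(dtype=float)
    start = np.floor(ages.min() / bin_width) * bin_width
    idx = np.floor((ages - start) / bin_width).astype(int)
    rows = []
    n_bins = idx.max() + 1
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"empty age bin [{start + b * bin_width:g}, "
                          f"{start + (b + 1) * bin_width:g}) omitted", stacklevel=2)
            continue
        v = values[sel]
        rows.append(
            {
                "bin_start": start + b * bin_width,
                "bin_mid": float(ages[sel].mean()),
                "mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
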