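"""Effect sizes and group comparisons for regional volumes.

Hedges' g (pooled-SD standardized mean difference with the small-sample
bias correction J), Student t-tests with Bonferroni-adjusted
significance thresholds, the proportional (percent) difference
2(a - b)/(a + b) x 100 used to compare regions of different size on one
scale, Bland-Altman agreement limits for method comparisons, and the
covariate screen (Pearson r for BMI; two-level contrasts for
hypertension and education; pairwise smoking contrasts with Bonferroni
alpha = 0.05/6 plus a one-way ANOVA).

For paired designs g uses the equal-n pooled SD of the two condition
vectors, which for equal n coincides with the unpaired pooled formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "EffectSizeResult",
    "hedges_g",
    "percent_difference",
    "compare_groups",
    "bland_altman",
    "covariate_effects",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: n, mean, SD (ddof=1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("need at least 2 finite values")
        return cls(label=label, n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _as_summary(g, label: str) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_values(g, label)


def hedges_g(a, b) -> float:
    """Hedges' g = (mean_a - mean_b) / s_pooled * J.

    s_pooled = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2)),
    J = 1 - 3 / (4 (n_a+n_b-2) - 1).  Accepts raw vectors or
    :class:`GroupSummary` objects; the sign follows mean_a - mean_b.
    """
    sa, sb = _as_summary(a, "a"), _as_summary(b, "b")
    dof = sa.n + sb.n - 2
    pooled_var = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / dof
    diff = sa.mean - sb.mean
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise ValueError("both SDs are zero with unequal means: g undefined")
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    return float(diff / np.sqrt(pooled_var) * j)


def percent_difference(a: float, b: float) -> float:
    """Proportional difference 2 (a - b) / (a + b) x 100.

    Antisymmetric and invariant under common rescaling of a and b.
    """
    if a + b <= 0:
        raise ValueError(f"a + b must be > 0, got {a + b}")
    return 200.0 * (a - b) / (a + b)


@dataclass
class EffectSizeResult:
    label: str
    design: str
    n1: int
    n2: int
    g: float
    t: float
    p: float
    alpha_bonferroni: float
    significant: bool


def compare_groups(
    x, y, design: str = "unpaired", family_size: int = 1, label: str = ""
) -> EffectSizeResult:
    """Student t-test plus Hedges' g, with a Bonferroni-adjusted threshold.

    Unpaired uses the pooled-variance t; paired tests the differences.
    ``family_size`` is the number of comparisons in the family; the
    significance flag compares p with 0.05 / family_size.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)] if design == "unpaired" else x
    y = y[np.isfinite(y)] if design == "unpaired" else y
    if design == "paired":
        if x.size != y.size:
            raise ValueError("paired design requires matching lengths")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if design == "unpaired":
        t, p = stats.ttest_ind(x, y, equal_var=True)
    elif design == "paired":
        if np.array_equal(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
    else:
        raise ValueError(f"unknown design {design!r}")
    g = hedges_g(GroupSummary.from_values(x, "x"), GroupSummary.from_values(y, "y"))
    alpha = 0.05 / family_size
    return EffectSizeResult(
        label=label,
        design=design,
        n1=int(x.size),
        n2=int(y.size),
        g=g,
        t=float(t),
        p=float(p),
        alpha_bonferroni=alpha,
        significant=bool(p < alpha),
    )


def bland_altman(x, y) -> dict:
    """Agreement between two paired measurements.

    Returns the mean difference (x - y), limits of agreement at
    mean +/- 1.96 SD(differences), and the plotting coordinates
    (pair means vs differences).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have matching lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "mean_diff": md,
        "loa_low": md - 1.96 * sd,
        "loa_high": md + 1.96 * sd,
        "pair_means": (x + y) / 2.0,
        "differences": diff,
    }


def covariate_effects(cohort, region: str, values=None) -> dict:
    """Screen of lifestyle-covariate effects on one region's volume.

    Expects volumes already deconfounded for scan date, head size and
    age (pass them as ``values`` aligned with the cohort, or use the
    region column).  Returns Pearson r for BMI, two-level contrasts
    (Hedges' g + t) for hypertension and education, the three pairwise
    smoking contrasts at Bonferroni alpha = 0.05/6, and a one-way ANOVA
    over smoking levels.  Levels with n < 2 are skipped with a warning.
    """
    v = (
        np.asarray(values, dtype=float)
        if values is not None
        else cohort[region].to_numpy(dtype=float)
    )
    out: dict = {"region": region}

    bmi = cohort["bmi"].to_numpy(dtype=float)
    ok = np.isfinite(bmi) & np.isfinite(v)
    r, p = stats.pearsonr(bmi[ok], v[ok])
    out["bmi"] = {"r": float(r), "p": float(p), "n": int(ok.sum())}

    ht = cohort["hypertension"].to_numpy(dtype=bool)
    out["hypertension"] = _two_level(v[ht], v[~ht], "hypertension vs none")

    edu = cohort["education"].to_numpy()
    out["education"] = _two_level(
        v[edu == "higher"], v[edu == "lower"], "higher vs lower education"
    )

    smoking = cohort["smoking"].to_numpy()
    groups = {lev: v[smoking == lev] for lev in ("never", "previous", "current")}
    contrasts = {}
    pairs = [("current", "never"), ("current", "previous"), ("previous", "never")]
    for a, b in pairs:
        key = f"{a}_vs_{b}"
        if groups[a].size < 2 or groups[b].size < 2:
            warnings.warn(f"smoking contrast {key} skipped (level with n < 2)", stacklevel=2)
            continue
        contrasts[key] = compare_groups(
            groups[a], groups[b], design="unpaired", family_size=6, label=key
        )
    usable = [g for g in groups.values() if g.size >= 2]
    anova = (
        stats.f_oneway(*usable) if len(usable) >= 2 else None
    )
    out["smoking"] = {
        "contrasts": contrasts,
        "anova_F": float(anova.statistic) if anova else np.nan,
        "anova_p": float(anova.pvalue) if anova else np.nan,
    }
    return out


def _two_level(x, y, label: str):
    if x.size < 2 or y.size < 2:
        warnings.warn(f"contrast {label!r} skipped (level with n < 2)", stacklevel=2)
        return None
    return compare_groups(x, y, design="unpaired", family_size=1, label=label)
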