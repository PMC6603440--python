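"""Outlier exclusion and confound regression for regional brain volumes.

Two preprocessing steps applied before any normative analysis:

1. Robust outlier exclusion: a participant's volume is excluded when its
   median-absolute-deviation (MAD) denominated distance from the region
   median exceeds a cutoff (default 5).  The MAD is *unscaled* (no
   1.4826 Gaussian consistency factor); the consistency factor can be
   switched on.  Masking is per region, so different regions may retain
   different participant sets.

2. Confound regression ("regressing out"): an ordinary least-squares
   model of volume on the confounds (scan date for scanner drift, the
   volumetric head-scaling factor for head size, and optionally age),
   after which corrected = volume - sum_c slope_c * (confound_c - reference_c).
   The head-scaling reference is the published neutral value 1.29874, so
   a participant scanned at exactly that scaling is left untouched;
   other confounds default to their cohort means, which preserves the
   cohort mean under correction.

Correction is by regression rather than by a ratio measure because
regional volumes do not all scale proportionately with head size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import HEAD_SCALING_REFERENCE

__all__ = [
    "OutlierMask",
    "DeconfoundModel",
    "mad_filter",
    "mad_mask_regions",
    "fit_confound_model",
    "apply_deconfound",
    "deconfound_cohort",
]

MAD_CONSISTENCY = 1.4826


@dataclass
class OutlierMask:
    """Per-observation exclusion mask from the MAD filter."""

    excluded: np.ndarray  # bool, True = excluded
    mad_distance: np.ndarray
    cutoff: float

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())


def mad_filter(values, cutoff: float = 5.0, scaled: bool = False) -> OutlierMask:
    """Flag outliers by MAD-denominated distance from the median.

    distance_i = |x_i - median(x)| / MAD(x), with MAD the raw median of
    absolute deviations (multiplied by 1.4826 when ``scaled``).  When the
    MAD is zero the distances are undefined; nothing is excluded and a
    warning is emitted.  NaN values are excluded and get infinite distance.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_filter requires at least one value")
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("mad_filter requires at least one finite value")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    if scaled:
        mad *= MAD_CONSISTENCY
    distance = np.full(x.shape, np.inf)
    if mad == 0:
        warnings.warn(
            "MAD is zero; no observations excluded (distances undefined)",
            stacklevel=2,
        )
        distance[finite] = 0.0
        excluded = ~finite
    else:
        distance[finite] = np.abs(x[finite] - med) / mad
        excluded = distance > cutoff
    return OutlierMask(excluded=excluded, mad_distance=distance, cutoff=cutoff)


def mad_mask_regions(
    cohort: pd.DataFrame, regions, cutoff: float = 5.0, scaled: bool = False
) -> pd.DataFrame:
    """Per-region boolean exclusion table (True = outlier), aligned to the cohort."""
    out = {}
    for region in regions:
        out[region] = mad_filter(cohort[region].to_numpy(), cutoff, scaled).excluded
    return pd.DataFrame(out, index=cohort.index)


@dataclass
class DeconfoundModel:
    """Fitted confound slopes for one region.

    Applying the model at all-reference confound values returns the
    input unchanged; with mean references the cohort mean is preserved.
    """

    region: str
    confounds: list[str]
    slopes: dict[str, float]
    reference_values: dict[str, float]
    grand_mean: float
    intercept: float = 0.0
    n_fit: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "region": self.region,
                    "confounds": self.confounds,
                    "slopes": self.slopes,
                    "reference_values": self.reference_values,
                    "grand_mean": self.grand_mean,
                    "n_fit": self.n_fit,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "DeconfoundModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            region=d["region"],
            confounds=list(d["confounds"]),
            slopes={k: float(v) for k, v in d["slopes"].items()},
            reference_values={k: float(v) for k, v in d["reference_values"].items()},
            grand_mean=float(d["grand_mean"]),
            n_fit=int(d.get("n_fit", 0)),
        )


def fit_confound_model(
    cohort: pd.DataFrame,
    region: str,
    confounds=("scan_date", "head_scaling"),
    exclude: np.ndarray | None = None,
    head_scaling_reference: float | None = HEAD_SCALING_REFERENCE,
) -> DeconfoundModel:
    """OLS fit of a region's volume on the confounds (plus intercept).

    ``exclude`` is an optional boolean mask of rows to drop (outliers).
    Reference values default to the confound means over the fitted rows,
    except head_scaling which uses the published neutral constant when
    ``head_scaling_reference`` is given.
    """
    confounds = list(confounds)
    y = cohort[region].to_numpy(dtype=float)
    keep = np.isfinite(y)
    X = np.column_stack([cohort[c].to_numpy(dtype=float) for c in confounds])
    keep &= np.isfinite(X).all(axis=1)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    n = int(keep.sum())
    if n < len(confounds) + 2:
        raise ValueError(
            f"need at least {len(confounds) + 2} rows to fit {len(confounds)} "
            f"confounds, got {n}"
        )
    Xk, yk = X[keep], y[keep]
    design = np.column_stack([np.ones(n), Xk])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(Xk, confounds)
        raise ValueError(f"rank-deficient confound design; collinear confounds: {bad}")
    beta, *_ = np.linalg.lstsq(design, yk, rcond=None)
    slopes = dict(zip(confounds, beta[1:]))
    refs = {c: float(Xk[:, i].mean()) for i, c in enumerate(confounds)}
    if "head_scaling" in refs and head_scaling_reference is not None:
        refs["head_scaling"] = float(head_scaling_reference)
    return DeconfoundModel(
        region=region,
        confounds=confounds,
        slopes={k: float(v) for k, v in slopes.items()},
        reference_values=refs,
        grand_mean=float(yk.mean()),
        intercept=float(beta[0]),
        n_fit=n,
    )


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Name confounds involved in exact collinearity (constant or duplicated)."""
    bad = [nm for i, nm in enumerate(names) if np.ptp(X[:, i]) == 0]
    corr = np.corrcoef(X, rowvar=False) if X.shape[1] > 1 else np.ones((1, 1))
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 1 - 1e-12:
                bad.extend([names[i], names[j]])
    return sorted(set(bad)) or list(names)


def apply_deconfound(
    volumes, model: DeconfoundModel, confound_values: pd.DataFrame
) -> np.ndarray:
    """corrected = volume - sum_c slope_c * (confound_c - reference_c).

    Linear and order-independent across confounds.  Rows with a missing
    confound value come back NaN (flagged, never silently dropped).
    """
    v = np.asarray(volumes, dtype=float)
    corrected = v.copy()
    for c in model.confounds:
        x = confound_values[c].to_numpy(dtype=float)
        corrected = corrected - model.slopes[c] * (x - model.reference_values[c])
    return corrected


def deconfound_cohort(
    cohort: pd.DataFrame,
    regions,
    confounds=("scan_date", "head_scaling"),
    cutoff: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, DeconfoundModel]]:
    """MAD-filter then regress confounds out of each region.

    Returns (corrected cohort copy, per-region outlier mask, fitted models).
    Outlier rows keep their corrected values but remain flagged in the mask;
    downstream windowing drops them.
    """
    mask = mad_mask_regions(cohort, regions, cutoff=cutoff)
    out = cohort.copy()
    models = {}
    for region in regions:
        model = fit_confound_model(
            cohort, region, confounds, exclude=mask[region].to_numpy()
        )
        out[region] = apply_deconfound(cohort[region], model, cohort)
        models[region] = model
    return out, mask, models
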