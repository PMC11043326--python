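"""Image intensity clipping and morphological-feature normalisation.

Feature profiles are normalised per plate against the DMSO control wells:
``x -> (x - median_controls) / max(MAD_controls, epsilon)`` feature-wise, the
standard robust z-score used in high-content screening.  The MAD is used raw
(no 1.4826 Gaussian-consistency factor); pass ``scale_mad=True`` for the
consistent variant.  Features whose post-normalisation variance falls below a
threshold (default 1.0) are dropped as uninformative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic import ProfileTable

__all__ = [
    "aggregate_replicates",
    "clip_percentiles",
    "robust_z_normalize",
    "variance_filter",
]

logger = logging.getLogger(__name__)

MAD_EPSILON = 1e-6
MAD_CONSISTENCY = 1.4826


def clip_percentiles(image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Clip intensities to the [low_pct, high_pct] percentile range.

    Percentiles are computed per channel for ``(C, H, W)`` stacks and over the
    whole array otherwise.  The bounds are taken as order statistics (the
    ``lower``/``higher`` percentile methods) rather than interpolated values,
    so the clip limits are actual pixel values and the operation is exactly
    idempotent — with 16-bit integer inputs the difference is visible.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot clip an empty image")
    if not low_pct < high_pct:
        raise ValueError(f"need low_pct < high_pct, got {low_pct} >= {high_pct}")
    out = image.astype(float, copy=True)

    def _clip(channel):
        lo = np.percentile(channel, low_pct, method="lower")
        hi = np.percentile(channel, high_pct, method="higher")
        return np.clip(channel, lo, hi)

    if out.ndim == 3:  # multichannel stack: clip each channel independently
        for c in range(out.shape[0]):
            out[c] = _clip(out[c])
    else:
        out = _clip(out)
    return out


def robust_z_normalize(profiles: ProfileTable, epsilon: float = MAD_EPSILON,
                       scale_mad: bool = False) -> ProfileTable:
    """Plate-wise robust z-score against DMSO controls.

    For every plate and feature, subtract the control median and divide by the
    control MAD (floored at ``epsilon``); control wells are transformed with
    the same parameters.  Plates lacking controls raise; zero-MAD features are
    logged and divided by ``epsilon`` (the variance filter usually removes
    them downstream).
    """
    frame = profiles.frame.reset_index(drop=True)
    profiles = ProfileTable(frame)
    feat_cols = profiles.feature_columns
    values = profiles.features.copy()
    mad_scale = MAD_CONSISTENCY if scale_mad else 1.0

    plate_codes = frame["plate_id"].to_numpy()
    is_control = frame["is_control"].to_numpy(bool)
    for plate in pd.unique(plate_codes):
        idx = np.flatnonzero(plate_codes == plate)
        ctrl = is_control[idx]
        if ctrl.sum() < 4:
            raise ValueError(f"plate {plate!r} has {int(ctrl.sum())} control wells; >= 4 required")
        block = values[idx]
        ctrl_block = block[ctrl]
        med = np.median(ctrl_block, axis=0)
        mad = mad_scale * np.median(np.abs(ctrl_block - med), axis=0)
        degenerate = mad < epsilon
        if degenerate.any():
            names = [feat_cols[j] for j in np.flatnonzero(degenerate)[:10]]
            logger.warning(
                "plate %s: %d features with zero control MAD (e.g. %s); dividing by epsilon",
                plate, int(degenerate.sum()), names,
            )
        values[idx] = (block - med) / np.maximum(mad, epsilon)
    return profiles.with_features(values)


def variance_filter(profiles: ProfileTable, threshold: float = 1.0
                    ) -> tuple[ProfileTable, list[str]]:
    """Drop features with variance below ``threshold`` (computed over all wells).

    Returns the filtered table and the names of the *kept* features; the
    removed set is logged.  Raises when nothing survives.
    """
    feat_cols = profiles.feature_columns
    variances = profiles.features.var(axis=0, ddof=0)
    keep = variances >= threshold
    if not keep.any():
        raise ValueError(f"variance filter at threshold {threshold} removed all features")
    kept = [c for c, k in zip(feat_cols, keep) if k]
    removed = [c for c, k in zip(feat_cols, keep) if not k]
    if removed:
        logger.info("variance filter removed %d/%d features", len(removed), len(feat_cols))
    out = ProfileTable(profiles.frame[list(ProfileTable.META_COLUMNS) + kept].copy())
    return out, kept


def aggregate_replicates(rows: np.ndarray) -> np.ndarray:
    """Column-wise arithmetic mean over a compound's replicate rows."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] == 0:
        raise ValueError("cannot aggregate zero replicates")
    return rows.mean(axis=0)
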