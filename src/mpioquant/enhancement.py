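"""Per-ROI quantification of contrast-agent accumulation.

Two read-outs from the pre/post T2*-weighted pair, both computed through
ROI statistics only (never voxelwise subtraction, which in vivo is defeated
by slight brain movement between acquisitions):

* absolute signal reduction — mean pre-contrast SI minus mean post-contrast
  SI over the ROI;
* contrast-enhanced (CE) volume percentage — voxels more than ``n_sd``
  (default 2) sample standard deviations below the ROI's pre-contrast mean
  are counted on both images, and the difference in their volume is
  expressed as a percentage of ROI volume. Negative values are reported,
  not clamped, so the no-contrast null is testably unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Volume3D

__all__ = [
    "ROIBaselineStats",
    "QuantResult",
    "roi_baseline_stats",
    "ce_voxel_mask",
    "eq1_signal_reduction",
    "eq3_ce_volume_fraction",
    "quantify_roi",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROIBaselineStats:
    """Pre-contrast signal statistics of one ROI."""

    roi_name: str
    mean: float
    sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_voxels < 2:
            raise ValueError("baseline stats require >= 2 voxels")


@dataclass(frozen=True)
class QuantResult:
    """Per-ROI quantification of one pre/post pair."""

    roi_name: str
    signal_reduction: float  # a.u., mean(pre) - mean(post)
    ce_volume_percent: float  # % of ROI volume, may be negative
    ce_count_pre: int
    ce_count_post: int
    roi_n_voxels: int
    timing_tag: str = "30 min post-injection"


def roi_baseline_stats(pre: Volume3D, roi: np.ndarray, name: str = "roi") -> ROIBaselineStats:
    """Mean and sample SD (n-1 denominator) of pre-contrast SI over the ROI."""
    roi = np.asarray(roi, dtype=bool)
    vals = pre.data[roi]
    if vals.size < 2:
        raise ValueError(f"ROI {name!r} has {vals.size} voxels; need >= 2 for baseline stats")
    return ROIBaselineStats(
        roi_name=name,
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        n_voxels=int(vals.size),
    )


def ce_voxel_mask(
    volume: Volume3D, roi: np.ndarray, stats: ROIBaselineStats, n_sd: float = 2.0
) -> np.ndarray:
    """Voxels in the ROI strictly below mean - n_sd * SD of the pre-contrast ROI.

    A zero SD is degenerate but well-defined (threshold = mean); it is
    logged when any voxel falls below it.
    """
    roi = np.asarray(roi, dtype=bool)
    threshold = stats.mean - n_sd * stats.sd
    mask = roi & (volume.data < threshold)
    if stats.sd == 0 and mask.any():
        logger.info(
            "ce_voxel_mask: degenerate zero-SD baseline in ROI %r; threshold = mean",
            stats.roi_name,
        )
    return mask


def eq1_signal_reduction(pre: Volume3D, post: Volume3D, roi: np.ndarray) -> float:
    """Absolute signal reduction: mean(pre) - mean(post) over the ROI.

    Positive when the post-contrast image is darker.
    """
    pre.require_same_grid(post, "pre/post volumes")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("signal reduction undefined on an empty ROI")
    return float(np.mean(pre.data[roi]) - np.mean(post.data[roi]))


def eq3_ce_volume_fraction(
    pre: Volume3D, post: Volume3D, roi: np.ndarray, n_sd: float = 2.0
) -> float:
    """CE volume change as a percentage of ROI volume.

    Both images are thresholded with the pre-contrast ROI statistics; the
    difference between post- and pre-image CE volumes is normalised by ROI
    volume and scaled to percent. Not clamped; may be negative.
    """
    pre.require_same_grid(post, "pre/post volumes")
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise ValueError("CE volume fraction undefined on an empty ROI")
    stats = roi_baseline_stats(pre, roi)
    n_post = int(np.count_nonzero(ce_voxel_mask(post, roi, stats, n_sd)))
    n_pre = int(np.count_nonzero(ce_voxel_mask(pre, roi, stats, n_sd)))
    return 100.0 * (n_post - n_pre) / n_roi


def quantify_roi(
    pre: Volume3D,
    post: Volume3D,
    roi: np.ndarray,
    name: str,
    n_sd: float = 2.0,
    timing_tag: str = "30 min post-injection",
) -> QuantResult:
    """Full per-ROI quantification: signal reduction plus CE volume percent."""
    pre.require_same_grid(post, "pre/post volumes")
    roi = np.asarray(roi, dtype=bool)
    stats = roi_baseline_stats(pre, roi, name)
    n_post = int(np.count_nonzero(ce_voxel_mask(post, roi, stats, n_sd)))
    n_pre = int(np.count_nonzero(ce_voxel_mask(pre, roi, stats, n_sd)))
    return QuantResult(
        roi_name=name,
        signal_reduction=eq1_signal_reduction(pre, post, roi),
        ce_volume_percent=100.0 * (n_post - n_pre) / stats.n_voxels,
        ce_count_pre=n_pre,
        ce_count_post=n_post,
        roi_n_voxels=stats.n_voxels,
        timing_tag=timing_tag,
    )
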