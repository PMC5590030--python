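"""Analysis-ROI construction from a lesion-core mask.

The perilesional borderzone is the expansion of the binary core obtained by
two successive convolve-then-binarise passes with an all-ones 3x3 kernel,
applied slice by slice (equivalently: two 8-connected in-plane dilations),
minus the core itself and any excluded anatomy (ventricles, corpus
callosum). The contralesional homolog is built by reflecting the core
across the midsagittal plane and clipping to the contralesional
hemisphere.

Masks are axis-ordered (x, y, z) with slice = z; the expansion never
crosses slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .core import GridMismatchError, ROISet

__all__ = [
    "ROIBuildConfig",
    "expand_lesion_borderzone",
    "mirror_contralesional",
    "build_roi_set",
]

logger = logging.getLogger(__name__)

# 3x3 all-ones in-plane structuring element (slice axis = z)
_INPLANE_3X3 = np.ones((3, 3, 1), dtype=bool)


def _as_binary(mask: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{what} must be binary; found values {vals[:8]}")
        arr = arr.astype(bool)
    if arr.ndim != 3:
        raise ValueError(f"{what} must be 3D, got shape {arr.shape}")
    return arr


def expand_lesion_borderzone(
    core: np.ndarray, exclusions: Iterable[np.ndarray] = ()
) -> np.ndarray:
    """Borderzone = twofold in-plane 3x3 expansion of the core, minus the
    core and any exclusion masks.

    Each pass convolves the binary mask with an all-ones 3x3 kernel within
    each z-slice and binarises (>0); two passes give an 8-connected ring of
    in-plane Chebyshev width 2 around the core.
    """
    core = _as_binary(core, "core mask")
    expanded = ndimage.binary_dilation(core, structure=_INPLANE_3X3, iterations=2)
    borderzone = expanded & ~core
    for excl in exclusions:
        excl = _as_binary(excl, "exclusion mask")
        if excl.shape != core.shape:
            raise GridMismatchError(
                f"exclusion shape {excl.shape} differs from core {core.shape}"
            )
        borderzone &= ~excl
    return borderzone


def mirror_contralesional(
    region: np.ndarray,
    midline_axis: int,
    midline_index: int,
    contra_hemisphere: np.ndarray | None = None,
) -> np.ndarray:
    """Reflect a mask across the midsagittal plane.

    The reflection maps index i to ``2*midline_index - 1 - i`` along
    ``midline_axis`` (the mirror plane sits between indices
    ``midline_index - 1`` and ``midline_index``). Voxels whose reflection
    falls outside the grid are dropped with a logged count; the result is
    clipped to ``contra_hemisphere`` when supplied.
    """
    region = _as_binary(region, "region mask")
    n = region.shape[midline_axis]
    if not 0 < midline_index < n:
        raise ValueError(f"midline_index {midline_index} outside grid axis of size {n}")

    idx = np.flatnonzero(region)
    coords = np.array(np.unravel_index(idx, region.shape)).T
    reflected = coords.copy()
    reflected[:, midline_axis] = 2 * midline_index - 1 - coords[:, midline_axis]
    inside = (reflected[:, midline_axis] >= 0) & (reflected[:, midline_axis] < n)
    n_clipped = int((~inside).sum())
    if n_clipped:
        logger.info("mirror_contralesional: %d reflected voxels fell outside the grid", n_clipped)
    reflected = reflected[inside]

    mirrored = np.zeros_like(region)
    mirrored[tuple(reflected.T)] = True
    if contra_hemisphere is not None:
        mirrored &= _as_binary(contra_hemisphere, "contra_hemisphere")
    return mirrored


@dataclass(frozen=True)
class ROIBuildConfig:
    """Configuration for assembling the analysis ROI set."""

    contralesional_source: str = "core"  # "core" or "core_plus_borderzone"
    midline_axis: int = 0
    midline_index: int | None = None  # default: half the axis length

    def __post_init__(self) -> None:
        if self.contralesional_source not in ("core", "core_plus_borderzone"):
            raise ValueError(
                "contralesional_source must be 'core' or 'core_plus_borderzone', "
                f"got {self.contralesional_source!r}"
            )


def _assert_invariants(rois: ROISet) -> None:
    core = rois["core"]
    bz = rois["borderzone"]
    if np.any(core & bz):
        raise ValueError("ROISet invariant violated: core and borderzone overlap")
    for name in ("ventricles", "corpus_callosum"):
        if name in rois and np.any(bz & rois[name]):
            raise ValueError(f"ROISet invariant violated: borderzone overlaps {name}")
    if "contra_hemisphere" in rois and np.any(
        rois["contralesional"] & ~rois["contra_hemisphere"]
    ):
        raise ValueError(
            "ROISet invariant violated: contralesional extends outside contra_hemisphere"
        )


def build_roi_set(
    core: np.ndarray,
    hemispheres: ROISet,
    exclusions: Iterable[str] = ("ventricles", "corpus_callosum"),
    config: ROIBuildConfig = ROIBuildConfig(),
) -> ROISet:
    """Assemble core / borderzone / contralesional ROIs on one grid.

    ``hemispheres`` must carry ``ipsi_hemisphere`` and ``contra_hemisphere``
    and may carry the exclusion masks. The core is trimmed of any overlap
    with exclusions (logged); the borderzone excludes core and exclusions;
    the contralesional ROI mirrors the configured source region across the
    midline and is clipped to the contralesional hemisphere.
    """
    core = _as_binary(core, "core mask")
    if hemispheres.shape is not None and core.shape != hemispheres.shape:
        raise GridMismatchError(
            f"core shape {core.shape} differs from ROI grid {hemispheres.shape}"
        )
    excl_masks = [hemispheres[name] for name in exclusions if name in hemispheres]

    trimmed = core.copy()
    for name in exclusions:
        if name in hemispheres:
            overlap = int(np.count_nonzero(trimmed & hemispheres[name]))
            if overlap:
                logger.info("build_roi_set: core overlaps %s in %d voxels; removed", name, overlap)
                trimmed &= ~hemispheres[name]

    borderzone = expand_lesion_borderzone(trimmed, excl_masks)

    axis = config.midline_axis
    mid = config.midline_index
    if mid is None:
        mid = core.shape[axis] // 2
    source = trimmed if config.contralesional_source == "core" else (trimmed | borderzone)
    contra = mirror_contralesional(
        source, axis, mid, hemispheres["contra_hemisphere"]
    )

    masks = dict(hemispheres.masks)
    masks.update(core=trimmed, borderzone=borderzone, contralesional=contra)
    rois = ROISet(masks, hemispheres.spacing)
    _assert_invariants(rois)
    return rois
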