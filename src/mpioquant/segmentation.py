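"""Lesion identification on T2 maps and hemispheric lesion fraction.

Lesions show prolonged T2 relative to contralesional tissue. Two routes:

* threshold rule — voxels in the ipsilesional hemisphere whose T2 exceeds
  the contralesional mean by ``k`` standard deviations (k = 2 by default;
  the threshold value is a surfaced config parameter, not a fixed claim);
* supervised voxel classifier — a seeded random-forest over (T2, x, y, z)
  features; template coordinates default to the native grid frame (identity
  mapping), with a hook for externally supplied template coordinates.

Both retain only the largest 26-connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

from .core import GridMismatchError, Volume3D

__all__ = [
    "LesionMask",
    "VoxelFeatureTable",
    "segment_lesion_by_threshold",
    "consensus_mask",
    "build_feature_table",
    "train_lesion_classifier",
    "classify_lesion",
    "hemispheric_lesion_fraction",
    "dice",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LesionMask:
    """A boolean lesion mask with its provenance."""

    mask: np.ndarray
    provenance: str  # threshold | classifier | consensus | ground_truth

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask, dtype=bool)
        if arr.ndim != 3:
            raise ValueError(f"lesion mask must be 3D, got {arr.shape}")
        object.__setattr__(self, "mask", arr)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class VoxelFeatureTable:
    """Per-voxel classifier features: T2 (ms) and template-space coordinates."""

    features: np.ndarray  # (n, 4): t2, x, y, z
    labels: np.ndarray | None = None  # (n,) booleans when training

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 2 or feats.shape[1] != 4:
            raise ValueError(f"features must be (n, 4) [t2, x, y, z], got {feats.shape}")
        if not np.all(np.isfinite(feats)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "features", feats)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=bool)
            if labels.shape != (feats.shape[0],):
                raise ValueError("labels must align with feature rows")
            object.__setattr__(self, "labels", labels)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component."""
    if not mask.any():
        return mask
    labelled = measure.label(mask, connectivity=3)
    counts = np.bincount(labelled.ravel())
    counts[0] = 0
    return labelled == int(np.argmax(counts))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks; 1.0 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.count_nonzero(a & b)) / float(denom)


def segment_lesion_by_threshold(
    t2_map: Volume3D,
    reference_roi: np.ndarray,
    k: float = 2.0,
    ipsi_hemisphere: np.ndarray | None = None,
) -> LesionMask:
    """Threshold rule: ipsilesional voxels with T2 above the reference mean
    plus ``k`` reference standard deviations; largest component kept.

    ``reference_roi`` is typically the contralesional hemisphere. When
    ``ipsi_hemisphere`` is omitted, the complement of the reference is
    searched.
    """
    reference_roi = np.asarray(reference_roi, dtype=bool)
    if not reference_roi.any():
        raise ValueError("reference ROI is empty; cannot derive a T2 threshold")
    ref = t2_map.data[reference_roi]
    threshold = float(np.mean(ref)) + k * float(np.std(ref, ddof=1)) if ref.size > 1 else float(np.mean(ref))
    search = (
        np.asarray(ipsi_hemisphere, dtype=bool)
        if ipsi_hemisphere is not None
        else ~reference_roi
    )
    mask = search & (t2_map.data > threshold)
    return LesionMask(_largest_component(mask), "threshold")


def consensus_mask(mask_a: LesionMask, mask_b: LesionMask, rule: str = "intersection") -> LesionMask:
    """Combine two expert masks; the intersection rule keeps voxels present
    in both."""
    if mask_a.mask.shape != mask_b.mask.shape:
        raise GridMismatchError(
            f"mask grids differ: {mask_a.mask.shape} vs {mask_b.mask.shape}"
        )
    if rule not in ("intersection", "majority"):
        raise ValueError(f"rule must be 'intersection' or 'majority', got {rule!r}")
    # with two raters, majority degenerates to intersection
    return LesionMask(mask_a.mask & mask_b.mask, "consensus")


def build_feature_table(
    t2_map: Volume3D,
    in_brain: np.ndarray,
    labels: np.ndarray | None = None,
    template_coords: np.ndarray | None = None,
) -> VoxelFeatureTable:
    """Assemble (t2, x, y, z) rows for every in-brain voxel.

    ``template_coords`` (shape (3,) + grid) supplies externally computed
    template-space coordinates; by default the native voxel grid scaled by
    spacing serves as the template frame.
    """
    in_brain = np.asarray(in_brain, dtype=bool)
    if template_coords is None:
        grids = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(t2_map.shape, t2_map.spacing)],
            indexing="ij",
        )
        template_coords = np.stack(grids, axis=0)
    coords = np.asarray(template_coords, dtype=float)
    feats = np.column_stack(
        [t2_map.data[in_brain]] + [coords[i][in_brain] for i in range(3)]
    )
    lab = None
    if labels is not None:
        lab = np.asarray(labels, dtype=bool)[in_brain]
    return VoxelFeatureTable(feats, lab)


def train_lesion_classifier(
    table: VoxelFeatureTable, n_trees: int = 100, seed: int = 0
) -> RandomForestClassifier:
    """Train a seeded random forest on (T2, location) voxel features."""
    if table.labels is None:
        raise ValueError("training requires a labelled feature table")
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise ValueError(
            "training table contains a single class; both lesion and "
            "non-lesion voxels are required"
        )
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(table.features, table.labels)
    return model


def classify_lesion(
    model: RandomForestClassifier,
    t2_map: Volume3D,
    in_brain: np.ndarray,
    template_coords: np.ndarray | None = None,
    probability_threshold: float = 0.5,
) -> tuple[LesionMask, Volume3D]:
    """Apply a trained voxel classifier; returns the cleaned mask and the
    per-voxel lesion probability map."""
    if getattr(model, "n_features_in_", 4) != 4:
        raise ValueError(
            f"model expects {model.n_features_in_} features; this pipeline supplies 4"
        )
    in_brain = np.asarray(in_brain, dtype=bool)
    table = build_feature_table(t2_map, in_brain, template_coords=template_coords)
    proba = model.predict_proba(table.features)[:, list(model.classes_).index(True)]
    prob_map = np.zeros(t2_map.shape)
    prob_map[in_brain] = proba
    mask = _largest_component(prob_map > probability_threshold)
    return LesionMask(mask, "classifier"), Volume3D(prob_map, t2_map.spacing)


def hemispheric_lesion_fraction(
    lesion: LesionMask,
    ipsi_hemisphere: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Lesion volume as a percentage of ipsilesional hemisphere volume.

    Volumes are voxel count times voxel volume, so the ratio is invariant
    to voxel spacing. Lesion voxels outside the hemisphere are dropped with
    a logged count.
    """
    hemi = np.asarray(ipsi_hemisphere, dtype=bool)
    n_hemi = int(np.count_nonzero(hemi))
    if n_hemi == 0:
        raise ValueError("ipsilesional hemisphere mask is empty")
    outside = int(np.count_nonzero(lesion.mask & ~hemi))
    if outside:
        logger.info(
            "hemispheric_lesion_fraction: %d lesion voxels outside the hemisphere dropped",
            outside,
        )
    voxel_volume = float(np.prod(spacing))
    lesion_volume = float(np.count_nonzero(lesion.mask & hemi)) * voxel_volume
    hemi_volume = float(n_hemi) * voxel_volume
    return 100.0 * lesion_volume / hemi_volume
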