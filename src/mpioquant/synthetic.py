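"""Synthetic brain-like phantoms and cohorts with known ground truth.

The phantoms reproduce the statistical structure the downstream analysis
assumes: mono-exponential T2 decay sampled at multiple echo times, Rician
(magnitude) noise, a unilateral lesion with prolonged T2, focal post-contrast
hypointensities seeded at a known voxel fraction, and an optional
chronic-stage confound in which a fraction of lesion voxels is already
hypointense before contrast injection.

Geometry is deliberately simple (ellipsoidal brain, spherical lesion,
parametric ventricles and callosal slab); adequacy is judged by pipeline
recovery of the seeded ground truth, not anatomical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import MultiEchoSeries, ROISet, Volume3D

__all__ = [
    "PhantomSpec",
    "ContrastSpec",
    "GroundTruth",
    "SubjectRecord",
    "DEFAULT_ECHO_TIMES_MS",
    "make_phantom",
    "simulate_multiecho",
    "simulate_contrast_pair",
    "add_rician_noise",
    "generate_cohort",
    "round_half_away",
]

#: 8 echoes spanning 12-96 ms in 12 ms steps (multi-echo spin-echo protocol).
DEFAULT_ECHO_TIMES_MS: tuple[float, ...] = tuple(12.0 * k for k in range(1, 9))


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties away from zero.

    Pinned here (rather than banker's rounding) so that seeded
    contrast-voxel counts, and therefore noiseless volume-fraction
    recovery, are exactly reproducible.
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom.

    The grid is axis-ordered (x, y, z) with slice = z. ``midline_axis``
    names the axis whose central plane separates the hemispheres.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 21)
    voxel_spacing: tuple[float, float, float] = (0.104, 0.208, 0.4)
    t2_background: float = 45.0  # ms
    t2_lesion: float = 75.0  # ms, must exceed t2_background
    s0_background: float = 1000.0  # a.u.
    lesion_center: tuple[int, int, int] = (48, 32, 10)
    lesion_radius: float = 6.0  # voxels
    ventricle_radii: tuple[float, float, float] = (3.0, 5.0, 2.5)  # voxels
    ventricle_offset: float = 6.0  # voxels from midline, per hemisphere
    callosum_halfwidth: float = 1.5  # voxels, slab thickness
    callosum_center_frac: float = 0.25  # slab centre as a fraction of the slab axis
    midline_axis: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 4 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints >= 4, got {self.grid_shape}")
        if self.t2_lesion <= self.t2_background:
            raise ValueError(
                "lesion must be T2-hyperintense: t2_lesion "
                f"({self.t2_lesion}) must exceed t2_background ({self.t2_background})"
            )
        if self.t2_background <= 0 or self.s0_background <= 0:
            raise ValueError("t2_background and s0_background must be positive")
        if self.lesion_radius < 0:
            raise ValueError("lesion_radius must be >= 0")
        if self.midline_axis not in (0, 1, 2):
            raise ValueError(f"midline_axis must be 0, 1 or 2, got {self.midline_axis}")

    @property
    def midline_index(self) -> int:
        return self.grid_shape[self.midline_axis] // 2


@dataclass(frozen=True)
class ContrastSpec:
    """Parameters of one simulated pre/post contrast-agent image pair.

    ``ce_fraction_per_roi`` gives, per named ROI, the target fraction of
    voxels rendered hypointense after contrast injection.
    ``pre_hypointense_fraction`` darkens that fraction of lesion voxels in
    BOTH the pre and post image — the chronic-stage confound; those voxels
    never count as true contrast enhancement.
    """

    ce_fraction_per_roi: Mapping[str, float] = field(default_factory=dict)
    ce_amplitude: float = 0.3  # multiplicative signal drop on seeded voxels
    pre_hypointense_fraction: float = 0.0
    noise_sigma: float = 0.0  # a.u., same units as S0
    gre_te_ms: float = 15.0  # effective TE of the gradient-echo pair
    seed: int = 0
    timing_tag: str = "30 min post-injection"

    def __post_init__(self) -> None:
        for name, frac in self.ce_fraction_per_roi.items():
            if not 0.0 <= float(frac) <= 1.0:
                raise ValueError(
                    f"ce_fraction for ROI {name!r} must lie in [0, 1], got {frac}"
                )
        if not 0.0 < self.ce_amplitude < 1.0:
            raise ValueError(f"ce_amplitude must lie in (0, 1), got {self.ce_amplitude}")
        if not 0.0 <= self.pre_hypointense_fraction <= 1.0:
            raise ValueError(
                "pre_hypointense_fraction must lie in [0, 1], "
                f"got {self.pre_hypointense_fraction}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass
class GroundTruth:
    """Per-phantom ground truth carried alongside simulated images."""

    lesion_mask: np.ndarray
    true_ce_mask: np.ndarray
    confound_mask: np.ndarray
    true_t2_map: Volume3D
    labels: dict[str, object] = field(default_factory=dict)


@dataclass
class SubjectRecord:
    """One animal-session: images, masks, labels and (synthetic) truth."""

    subject_id: str
    agent: str
    day: int
    spec: PhantomSpec
    true_t2_map: Volume3D
    s0_map: Volume3D
    base_rois: ROISet
    series: MultiEchoSeries
    pre: Volume3D
    post: Volume3D
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry helpers


def _grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )


def _ellipsoid(
    shape: tuple[int, int, int],
    center: Sequence[float],
    radii: Sequence[float],
) -> np.ndarray:
    """Voxel-center inclusion test for an axis-aligned ellipsoid."""
    xx, yy, zz = _grids(shape)
    r = [max(float(v), 1e-12) for v in radii]
    d2 = (
        ((xx - center[0]) / r[0]) ** 2
        + ((yy - center[1]) / r[1]) ** 2
        + ((zz - center[2]) / r[2]) ** 2
    )
    return d2 <= 1.0


def _check_inside_grid(
    name: str,
    center: Sequence[float],
    radii: Sequence[float],
    shape: tuple[int, int, int],
) -> None:
    for ax in range(3):
        lo = center[ax] - radii[ax]
        hi = center[ax] + radii[ax]
        if lo < 0 or hi > shape[ax] - 1:
            raise ValueError(
                f"{name} extends outside the grid along axis {ax}: "
                f"[{lo:.1f}, {hi:.1f}] vs [0, {shape[ax] - 1}]"
            )


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, Volume3D, ROISet]:
    """Build noiseless parameter maps and base masks for one phantom.

    Returns
    -------
    true_t2_map, s0_map : Volume3D
        T2 equals ``t2_lesion`` inside the lesion sphere and
        ``t2_background`` elsewhere in the brain; S0 is uniform inside the
        brain ellipsoid and zero outside (air).
    base_rois : ROISet
        ``brain``, ``lesion``, ``ipsi_hemisphere``, ``contra_hemisphere``,
        ``ventricles``, ``corpus_callosum``.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    ax = spec.midline_axis
    mid = spec.midline_index

    brain_center = [(s - 1) / 2.0 for s in shape]
    brain_radii = [0.47 * s for s in shape]
    brain = _ellipsoid(shape, brain_center, brain_radii)

    coords = _grids(shape)
    upper = coords[ax] >= mid  # hemisphere on the high-index side of the midline

    # lesion sphere (voxel-center inclusion)
    if spec.lesion_radius > 0:
        _check_inside_grid("lesion", spec.lesion_center, [spec.lesion_radius] * 3, shape)
        lesion = _ellipsoid(shape, spec.lesion_center, [spec.lesion_radius] * 3)
        lesion &= brain
        lesion_upper = spec.lesion_center[ax] >= mid
        hemi = upper if lesion_upper else ~upper
        if np.any(lesion & ~hemi):
            raise ValueError("lesion crosses the midline; it must lie in one hemisphere")
    else:
        lesion = np.zeros(shape, dtype=bool)
        lesion_upper = spec.lesion_center[ax] >= mid

    ipsi = (upper if lesion_upper else ~upper) & brain
    contra = (~upper if lesion_upper else upper) & brain

    # paired ventricles, mirrored about the midline
    ventricles = np.zeros(shape, dtype=bool)
    if all(r > 0 for r in spec.ventricle_radii):
        for side in (-1.0, 1.0):
            center = list(brain_center)
            center[ax] = brain_center[ax] + side * spec.ventricle_offset
            _check_inside_grid("ventricle", center, spec.ventricle_radii, shape)
            ventricles |= _ellipsoid(shape, center, spec.ventricle_radii)
        ventricles &= brain

    # corpus callosum: thin slab spanning the midline
    cc = np.zeros(shape, dtype=bool)
    if spec.callosum_halfwidth > 0:
        slab_axis = 1 if ax != 1 else 0
        c = spec.callosum_center_frac * (shape[slab_axis] - 1)
        cc = np.abs(coords[slab_axis] - c) <= spec.callosum_halfwidth
        cc &= brain & ~ventricles

    t2 = np.full(shape, spec.t2_background, dtype=float)
    t2[lesion] = spec.t2_lesion
    s0 = np.where(brain, spec.s0_background, 0.0)

    spacing = spec.voxel_spacing
    rois = ROISet(
        {
            "brain": brain,
            "lesion": lesion,
            "ipsi_hemisphere": ipsi,
            "contra_hemisphere": contra,
            "ventricles": ventricles,
            "corpus_callosum": cc,
        },
        spacing,
    )
    return Volume3D(t2, spacing), Volume3D(s0, spacing), rois


# ---------------------------------------------------------------------------
# signal simulation


def add_rician_noise(volume: Volume3D, sigma: float, seed: int) -> Volume3D:
    """Magnitude-MRI noise: each voxel v becomes sqrt((v+n1)^2 + n2^2).

    n1, n2 are independent zero-mean Gaussians of standard deviation
    ``sigma`` (same units as the signal). ``sigma == 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return volume
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=volume.shape)
    n2 = rng.normal(0.0, sigma, size=volume.shape)
    noisy = np.hypot(volume.data + n1, n2)
    return Volume3D(noisy, volume.spacing)


def simulate_multiecho(
    true_t2_map: Volume3D,
    s0_map: Volume3D,
    echo_times_ms: Sequence[float] = DEFAULT_ECHO_TIMES_MS,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MultiEchoSeries:
    """Mono-exponential decay s0 * exp(-TE/T2) sampled at each echo time,
    with Rician noise applied independently per echo."""
    true_t2_map.require_same_grid(s0_map, "T2 and S0 maps")
    tes = [float(t) for t in echo_times_ms]
    if any(t <= 0 for t in tes) or any(b <= a for a, b in zip(tes, tes[1:])):
        raise ValueError(f"echo_times must be strictly increasing and > 0, got {tes}")
    t2 = np.maximum(true_t2_map.data, 1e-12)
    seeds = np.random.SeedSequence(seed).generate_state(len(tes))
    echoes = []
    for te, echo_seed in zip(tes, seeds):
        clean = Volume3D(s0_map.data * np.exp(-te / t2), true_t2_map.spacing)
        echoes.append(add_rician_noise(clean, noise_sigma, int(echo_seed)))
    return MultiEchoSeries(tuple(echoes), tuple(tes))


def _draw_without_replacement(
    rng: np.random.Generator, candidates: np.ndarray, count: int, what: str
) -> np.ndarray:
    flat = np.flatnonzero(candidates)
    if count > flat.size:
        raise ValueError(
            f"cannot seed {count} {what} voxels: only {flat.size} candidates available"
        )
    chosen = rng.choice(flat, size=count, replace=False)
    mask = np.zeros(candidates.shape, dtype=bool)
    mask.flat[chosen] = True
    return mask


def simulate_contrast_pair(
    true_t2_map: Volume3D,
    s0_map: Volume3D,
    rois: ROISet,
    cspec: ContrastSpec,
) -> tuple[Volume3D, Volume3D, GroundTruth]:
    """Simulate a pre/post gradient-echo pair with seeded hypointensities.

    The noiseless pre image is ``s0 * exp(-TE/T2)``. Per named ROI,
    ``round_half_away(fraction * roi_size)`` voxels are drawn without
    replacement and have their post-contrast signal multiplied by
    ``ce_amplitude`` before noise. Confound voxels (a fraction of the
    lesion) are darkened in BOTH images and excluded from the true
    enhancement mask.
    """
    true_t2_map.require_same_grid(s0_map, "T2 and S0 maps")
    for name in cspec.ce_fraction_per_roi:
        if name not in rois:
            raise KeyError(f"ce_fraction requested for unknown ROI {name!r}")

    t2 = np.maximum(true_t2_map.data, 1e-12)
    base = s0_map.data * np.exp(-cspec.gre_te_ms / t2)

    ss = np.random.SeedSequence(cspec.seed)
    draw_seed, pre_seed, post_seed = (int(s) for s in ss.generate_state(3))
    rng = np.random.default_rng(draw_seed)

    lesion = rois["lesion"] if "lesion" in rois else np.zeros(base.shape, dtype=bool)
    n_confound = round_half_away(
        cspec.pre_hypointense_fraction * int(np.count_nonzero(lesion))
    )
    confound = _draw_without_replacement(rng, lesion, n_confound, "confound")

    true_ce = np.zeros(base.shape, dtype=bool)
    for name in sorted(cspec.ce_fraction_per_roi):
        frac = float(cspec.ce_fraction_per_roi[name])
        roi = rois[name]
        count = round_half_away(frac * int(np.count_nonzero(roi)))
        candidates = roi & ~confound & ~true_ce
        true_ce |= _draw_without_replacement(rng, candidates, count, f"CE ({name})")

    pre_clean = base.copy()
    pre_clean[confound] *= cspec.ce_amplitude
    post_clean = pre_clean.copy()
    post_clean[true_ce] *= cspec.ce_amplitude

    spacing = true_t2_map.spacing
    pre = add_rician_noise(Volume3D(pre_clean, spacing), cspec.noise_sigma, pre_seed)
    post = add_rician_noise(Volume3D(post_clean, spacing), cspec.noise_sigma, post_seed)

    gt = GroundTruth(
        lesion_mask=lesion.copy(),
        true_ce_mask=true_ce,
        confound_mask=confound,
        true_t2_map=true_t2_map,
        labels={"timing": cspec.timing_tag},
    )
    return pre, post, gt


# ---------------------------------------------------------------------------
# cohorts


def _with_analysis_rois(base: ROISet, spec: PhantomSpec) -> ROISet:
    """Extend phantom base masks with the ground-truth analysis ROIs
    (core / borderzone / contralesional built from the true lesion), so
    contrast can be seeded on the same regions the analysis quantifies."""
    from .roi_geometry import ROIBuildConfig, build_roi_set

    cfg = ROIBuildConfig(
        midline_axis=spec.midline_axis, midline_index=spec.midline_index
    )
    return build_roi_set(base["lesion"], base, config=cfg)


def generate_cohort(
    n_per_group: int,
    groups: Sequence[tuple[str, int]],
    spec: PhantomSpec,
    cspec_per_group: Mapping[tuple[str, int], ContrastSpec],
    seed: int = 0,
    echo_times_ms: Sequence[float] = DEFAULT_ECHO_TIMES_MS,
    jitter_voxels: int = 2,
) -> list[SubjectRecord]:
    """Simulate a cohort of independent phantoms with group labels.

    Each subject gets a per-subject derived seed (one global seed plus the
    subject index) and a lesion jittered in position and radius, so cohorts
    are reproducible yet heterogeneous.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = list(groups)
    if not groups:
        raise ValueError("at least one (agent, day) group is required")
    for g in groups:
        if g not in cspec_per_group:
            raise KeyError(f"no ContrastSpec supplied for group {g!r}")

    records: list[SubjectRecord] = []
    idx = 0
    for agent, day in groups:
        base_cspec = cspec_per_group[(agent, day)]
        for k in range(n_per_group):
            subj_seed = seed + idx
            rng = np.random.default_rng(subj_seed)
            jitter = rng.integers(-jitter_voxels, jitter_voxels + 1, size=3)
            dr = float(rng.integers(-1, 2))
            sspec = replace(
                spec,
                lesion_center=tuple(
                    int(c + j) for c, j in zip(spec.lesion_center, jitter)
                ),
                lesion_radius=max(spec.lesion_radius + dr, 1.0),
            )
            t2_map, s0_map, base = make_phantom(sspec)
            rois = _with_analysis_rois(base, sspec)
            series = simulate_multiecho(
                t2_map, s0_map, echo_times_ms, base_cspec.noise_sigma, subj_seed
            )
            cspec = replace(base_cspec, seed=subj_seed)
            pre, post, gt = simulate_contrast_pair(t2_map, s0_map, rois, cspec)
            gt.labels.update({"agent": agent, "day": day})
            records.append(
                SubjectRecord(
                    subject_id=f"s{idx:03d}",
                    agent=agent,
                    day=int(day),
                    spec=sspec,
                    true_t2_map=t2_map,
                    s0_map=s0_map,
                    base_rois=rois,
                    series=series,
                    pre=pre,
                    post=post,
                    ground_truth=gt,
                )
            )
            idx += 1
    return records
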