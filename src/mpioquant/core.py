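"""Shared data containers for the quantification pipeline.

All volumes in a single analysis share one voxel grid, stored axis-ordered
``(x, y, z)`` with the acquisition slice along ``z``. Voxel spacing is in
millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Volume3D", "MultiEchoSeries", "ROISet", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar image with voxel spacing.

    Parameters
    ----------
    data:
        3D array of signal intensities (a.u.) or a fitted parameter.
    spacing:
        Voxel spacing in mm, one value per axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume3D") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def require_same_grid(self, other: "Volume3D", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} must share one grid: "
                f"{self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )


@dataclass(frozen=True)
class MultiEchoSeries:
    """A stack of volumes acquired at known echo times.

    ``echoes[i]`` is the volume at ``echo_times_ms[i]``; echo times must be
    strictly increasing and positive.
    """

    echoes: tuple[Volume3D, ...]
    echo_times_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        echoes = tuple(self.echoes)
        tes = tuple(float(t) for t in self.echo_times_ms)
        if len(echoes) != len(tes):
            raise ValueError("one echo time per echo volume required")
        if len(echoes) < 1:
            raise ValueError("series must contain at least one echo")
        if any(t <= 0 for t in tes):
            raise ValueError(f"echo times must be positive, got {tes}")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError(f"echo times must be strictly increasing, got {tes}")
        first = echoes[0]
        for e in echoes[1:]:
            first.require_same_grid(e, "echo volumes")
        object.__setattr__(self, "echoes", echoes)
        object.__setattr__(self, "echo_times_ms", tes)

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.echoes[0].spacing

    def as_array(self) -> np.ndarray:
        """Signals stacked along a leading echo axis, shape (n_echoes, x, y, z)."""
        return np.stack([e.data for e in self.echoes], axis=0)


@dataclass
class ROISet:
    """Named boolean masks on a shared grid.

    Conventional names: ``core``, ``borderzone``, ``contralesional``,
    ``ipsi_hemisphere``, ``contra_hemisphere``, ``ventricles``,
    ``corpus_callosum``, ``brain``. Arbitrary extra names are allowed.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, mask in self.masks.items():
            arr = np.asarray(mask, dtype=bool)
            if arr.ndim != 3:
                raise ValueError(f"ROI {name!r} must be a 3D mask, got {arr.shape}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise GridMismatchError(
                    f"ROI {name!r} shape {arr.shape} differs from {shape}"
                )
            clean[name] = arr
        self.masks = clean
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"ROI {name!r} not present; available: {sorted(self.masks)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def names(self) -> list[str]:
        return sorted(self.masks)

    @property
    def shape(self) -> tuple[int, int, int] | None:
        for mask in self.masks.values():
            return mask.shape  # type: ignore[return-value]
        return None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self, name: str) -> float:
        return float(np.count_nonzero(self[name])) * self.voxel_volume_mm3

    def with_mask(self, name: str, mask: np.ndarray) -> "ROISet":
        new = dict(self.masks)
        new[name] = np.asarray(mask, dtype=bool)
        return ROISet(new, self.spacing)

    @classmethod
    def from_mapping(
        cls, masks: Mapping[str, np.ndarray], spacing=(1.0, 1.0, 1.0)
    ) -> "ROISet":
        return cls(dict(masks), tuple(spacing))
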