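"""NIfTI and tabular I/O for the pipeline.

Volumes are written as NIfTI-1 with an RAS+ diagonal affine carrying the
voxel spacing. ROI sets are serialised as a single unsigned-integer bitmask
volume plus a JSON name table (one bit per named mask), which preserves
overlapping masks such as lesion-within-hemisphere.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import ROISet, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_roiset",
    "write_roiset",
    "load_yaml",
    "dump_yaml",
]


def read_volume(path: str | Path) -> Volume3D:
    """Load a 3D NIfTI volume; spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, dtype=np.float64), spacing)


def write_volume(volume: Volume3D, path: str | Path, dtype=np.float64) -> Path:
    """Write a volume as NIfTI-1 with spacing on the affine diagonal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=dtype), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def write_roiset(rois: ROISet, path: str | Path) -> Path:
    """Serialise an ROI set as a uint32 bitmask NIfTI plus a JSON name table
    (``<path>.json``) mapping each ROI name to its bit index."""
    names = rois.names()
    if len(names) > 32:
        raise ValueError(f"at most 32 ROIs supported, got {len(names)}")
    shape = rois.shape
    if shape is None:
        raise ValueError("cannot serialise an empty ROISet")
    encoded = np.zeros(shape, dtype=np.uint32)
    table = {}
    for bit, name in enumerate(names):
        encoded |= rois[name].astype(np.uint32) << np.uint32(bit)
        table[name] = bit
    path = write_volume(Volume3D(encoded.astype(np.float64), rois.spacing), path, dtype=np.uint32)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"bits": table}, indent=2))
    return path


def read_roiset(path: str | Path) -> ROISet:
    """Inverse of :func:`write_roiset`."""
    path = Path(path)
    vol = read_volume(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"ROI name table not found: {sidecar}")
    table = json.loads(sidecar.read_text())["bits"]
    encoded = vol.data.astype(np.uint32)
    masks = {
        name: (encoded >> np.uint32(bit)) & np.uint32(1) > 0
        for name, bit in table.items()
    }
    return ROISet(masks, vol.spacing)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
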