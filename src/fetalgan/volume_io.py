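"""NIfTI volume and mask I/O plus intensity normalization.

The segmentation networks consume a single 3D echo-planar (EPI) reference
volume per scan together with a voxel-aligned binary brain mask.  Volumes are
consumed in stored voxel order; no reorientation or resampling is performed
here (those belong to the upstream fMRI preprocessing pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "BinaryMask",
    "ProbabilityMap",
    "read_volume",
    "read_mask",
    "write_volume",
    "normalize_intensity",
]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with voxel spacing (mm) and an identifier."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume3D values must all be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """A voxel-aligned boolean label grid."""

    values: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"BinaryMask requires a 3D grid, got ndim={self.values.ndim}")
        if self.values.dtype != bool:
            # tolerate masks saved as floats/ints: > 0.5 is foreground
            self.values = self.values > 0.5

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ProbabilityMap:
    """A real-valued grid of per-voxel foreground probabilities in [0, 1]."""

    values: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"ProbabilityMap requires a 3D grid, got ndim={self.values.ndim}")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"probabilities must lie in [0,1], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _squeeze_to_3d(data: np.ndarray, path: Path) -> np.ndarray:
    if data.ndim == 3:
        return data
    if data.ndim == 4 and data.shape[3] == 1:
        return data[..., 0]
    raise ValueError(
        f"{path}: expected a 3D NIfTI (or 4D with a singleton fourth axis), "
        f"got shape {data.shape}"
    )


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI intensity volume.

    A fourth singleton dimension is squeezed; any other 4D layout is rejected
    (time series must be reduced to a single reference volume upstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = _squeeze_to_3d(np.asanyarray(img.dataobj), path)
    zooms = img.header.get_zooms()[:3]
    vid = path.name.removesuffix(".gz").removesuffix(".nii")
    return Volume3D(np.asarray(data, dtype=np.float32), tuple(float(z) for z in zooms), vid)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask; stored values > 0.5 are foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = _squeeze_to_3d(np.asanyarray(img.dataobj), path)
    vid = path.name.removesuffix(".gz").removesuffix(".nii")
    return BinaryMask(np.asarray(data) > 0.5, vid)


def write_volume(v: Volume3D | BinaryMask | ProbabilityMap, path: str | Path) -> Path:
    """Write a volume, mask or probability map as NIfTI-1.

    Masks are stored as unsigned 8-bit 0/1 and round-trip bit-exactly;
    volumes and probability maps are stored as 32-bit float.
    """
    path = Path(path)
    if isinstance(v, BinaryMask):
        data = v.values.astype(np.uint8)
        affine = np.eye(4)
    else:
        data = np.asarray(v.values, dtype=np.float32)
        if not np.all(np.isfinite(data)):
            raise ValueError("refusing to write non-finite voxel values")
        affine = np.eye(4)
        if isinstance(v, Volume3D):
            affine[0, 0], affine[1, 1], affine[2, 2] = v.spacing
    img = nib.Nifti1Image(data, affine)
    if isinstance(v, Volume3D):
        img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


def normalize_intensity(v: Volume3D) -> Volume3D:
    """Min-max rescale intensities to [0, 1] (monotone, idempotent).

    Bounded inputs suit the sigmoid-output networks and the masked-product
    adversarial loss.  Constant volumes carry no contrast and are rejected.
    """
    vals = np.asarray(v.values, dtype=np.float32)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError(f"cannot normalize a constant volume (value={lo})")
    out = (vals - lo) / (hi - lo)
    return Volume3D(out, v.spacing, v.id)
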