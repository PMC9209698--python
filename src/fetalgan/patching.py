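"""Fixed-size 3D patch extraction and overlap-averaged reassembly.

The networks operate on 32x32x32 patches.  For inference a volume is swept
by an overlapping lattice of patches, each patch is segmented independently,
and per-voxel probabilities are reassembled by arithmetic averaging over all
patches covering the voxel.  Patch origins form the lattice {0, s, 2s, ...}
per axis with the final origin clamped to the boundary so that every voxel
is covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import BinaryMask, ProbabilityMap, Volume3D

__all__ = ["PatchSpec", "PatchSet", "extract_patches", "reassemble", "lattice_origins"]


def _as_triple(x) -> tuple[int, int, int]:
    if np.isscalar(x):
        return (int(x),) * 3
    t = tuple(int(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or length-3 sequence, got {x!r}")
    return t


@dataclass
class PatchSpec:
    """Patch geometry: size and stride in voxels per axis.

    A stride smaller than the size yields overlapping patches; the default
    inference stride of 16 on 32-voxel patches gives 50% overlap.  pad_value
    is used only when a grid axis is smaller than the patch.
    """

    size: tuple[int, int, int] = (32, 32, 32)
    stride: tuple[int, int, int] = (16, 16, 16)
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        self.size = _as_triple(self.size)
        self.stride = _as_triple(self.stride)
        for s, z in zip(self.stride, self.size):
            if not 1 <= s <= z:
                raise ValueError(f"stride must satisfy 1 <= stride <= size, got {self}")


@dataclass
class PatchSet:
    """Ordered patches with their 0-based origin offsets in the source grid."""

    patches: np.ndarray  # (n, *size)
    origins: np.ndarray  # (n, 3) int
    source_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.patches)

    def layout_to_csv(self, path) -> None:
        """Dump the origin triplets for debugging patch layouts."""
        import pandas as pd

        pd.DataFrame(self.origins, columns=["z", "y", "x"]).to_csv(path, index=False)


def lattice_origins(axis_len: int, size: int, stride: int) -> list[int]:
    """Origins {0, s, 2s, ...} with the last clamped to axis_len - size."""
    if axis_len < size:
        raise ValueError(f"axis length {axis_len} smaller than patch size {size}")
    last = axis_len - size
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def extract_patches(v: Volume3D | BinaryMask | np.ndarray, spec: PatchSpec) -> PatchSet:
    """Decompose a grid into a covering lattice of fixed-size patches.

    Ordering is deterministic: axis 0 outermost, axis 2 innermost.  Axes
    smaller than the patch size are padded up with spec.pad_value (the padded
    shape is recorded as source_shape).
    """
    grid = v.values if isinstance(v, (Volume3D, BinaryMask, ProbabilityMap)) else np.asarray(v)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={grid.ndim}")
    pad = [max(0, z - n) for n, z in zip(grid.shape, spec.size)]
    if any(pad):
        grid = np.pad(
            grid,
            [(0, p) for p in pad],
            mode="constant",
            constant_values=grid.dtype.type(spec.pad_value) if grid.dtype != bool else False,
        )
    shape = grid.shape

    axes = [lattice_origins(shape[i], spec.size[i], spec.stride[i]) for i in range(3)]
    origins = np.array(
        [(a, b, c) for a in axes[0] for b in axes[1] for c in axes[2]], dtype=np.int64
    )
    sz = spec.size
    patches = np.empty((len(origins), *sz), dtype=grid.dtype)
    for k, (a, b, c) in enumerate(origins):
        patches[k] = grid[a : a + sz[0], b : b + sz[1], c : c + sz[2]]
    return PatchSet(patches=patches, origins=origins, source_shape=tuple(shape))


def reassemble(
    prob_patches,
    origins,
    source_shape: tuple[int, int, int],
) -> ProbabilityMap:
    """Average overlapping per-patch maps back into a whole-volume map.

    Each voxel's value is the arithmetic mean over all patches covering it;
    a voxel covered exactly once reproduces its single patch value.
    """
    prob_patches = np.asarray(prob_patches, dtype=np.float64)
    origins = np.asarray(origins, dtype=np.int64)
    if len(prob_patches) != len(origins):
        raise ValueError(
            f"{len(prob_patches)} patches but {len(origins)} origins"
        )
    if len(prob_patches) == 0:
        raise ValueError("cannot reassemble an empty patch list")
    acc = np.zeros(source_shape, dtype=np.float64)
    count = np.zeros(source_shape, dtype=np.int64)
    for patch, (a, b, c) in zip(prob_patches, origins):
        sz = patch.shape
        if a < 0 or b < 0 or c < 0 or a + sz[0] > source_shape[0] \
                or b + sz[1] > source_shape[1] or c + sz[2] > source_shape[2]:
            raise ValueError(f"patch at origin ({a},{b},{c}) exceeds {source_shape}")
        acc[a : a + sz[0], b : b + sz[1], c : c + sz[2]] += patch
        count[a : a + sz[0], b : b + sz[1], c : c + sz[2]] += 1
    if count.min() == 0:
        n_uncovered = int((count == 0).sum())
        raise ValueError(f"{n_uncovered} voxels not covered by any patch")
    out = (acc / count).astype(np.float32)
    return ProbabilityMap(np.clip(out, 0.0, 1.0))
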