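"""Synthetic fetal-EPI-like phantoms with ground-truth brain masks.

Fetal EPI reference volumes show a bright brain of arbitrary orientation
embedded in surrounding maternal tissue with low-contrast boundaries, smooth
intensity inhomogeneity (bias field) and noise.  The phantom emulates those
traits with a randomly rotated/translated ellipsoidal "brain", smooth
Gaussian "maternal tissue" blobs touching the brain, a low-order cosine bias
field and additive Gaussian noise.  The ground-truth mask is the exact
voxelization of the ellipsoid before noise, so every downstream module is
testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .datasets import TrainingSet
from .volume_io import BinaryMask, Volume3D, write_volume

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "generate_cohort",
    "cohort_item_seeds",
    "write_cohort",
]

_BRAIN_MEAN = 1.0
# acceptable brain volume fraction of the grid; resample semi-axes outside it
_MIN_FRACTION = 0.03
_MAX_FRACTION = 0.40


@dataclass
class PhantomConfig:
    """Parameters of one synthetic phantom.

    contrast is the ratio of mean brain intensity to mean surround-tissue
    intensity; contrast near 1 gives the low-contrast brain boundary that
    makes fetal EPI brain extraction hard.  noise_sigma is the additive
    Gaussian noise SD as a fraction of the mean brain intensity, and
    bias_amplitude the peak-to-trough fraction of the smooth multiplicative
    bias field.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (2.578, 2.578, 3.0)
    brain_semiaxes_range: tuple[float, float] = (10.0, 15.0)
    contrast: float = 1.3
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.2
    n_surround_blobs: int = 6
    seed: int = 0
    # controlled-geometry switches, used by tests and examples
    fixed_semiaxes: tuple[float, float, float] | None = None
    fixed_center: tuple[float, float, float] | None = None
    random_rotation: bool = True

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.contrast <= 0:
            raise ValueError(f"contrast must be > 0, got {self.contrast}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError(f"bias_amplitude must lie in [0, 1), got {self.bias_amplitude}")
        lo, hi = self.brain_semiaxes_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid brain_semiaxes_range {self.brain_semiaxes_range}")
        max_axis = hi if self.fixed_semiaxes is None else max(self.fixed_semiaxes)
        # the ellipsoid (any orientation) must fit inside the grid with a
        # one-voxel margin even at maximum semi-axes
        if 2 * max_axis + 2 > min(self.grid_shape):
            raise ValueError(
                f"brain with max semi-axis {max_axis} cannot fit inside grid "
                f"{self.grid_shape}"
            )


def _sample_semiaxes(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.fixed_semiaxes is not None:
        return np.asarray(cfg.fixed_semiaxes, dtype=np.float64)
    lo, hi = cfg.brain_semiaxes_range
    grid_volume = float(np.prod(cfg.grid_shape))
    for _ in range(200):
        axes = rng.uniform(lo, hi, size=3)
        frac = 4.0 / 3.0 * np.pi * float(np.prod(axes)) / grid_volume
        if _MIN_FRACTION <= frac <= _MAX_FRACTION:
            return axes
    raise ValueError(
        "brain_semiaxes_range incompatible with the target brain volume "
        f"fraction [{_MIN_FRACTION}, {_MAX_FRACTION}] on grid {cfg.grid_shape}"
    )


def _voxel_grid(shape: tuple[int, int, int]) -> np.ndarray:
    # voxel-center coordinates, shape (3, *grid)
    return np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    )


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative field: 1 + sum of 3 low-order cosines, rescaled so its
    peak-to-trough span equals `amplitude`."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    coords = _voxel_grid(shape) / np.asarray(shape, dtype=np.float64).reshape(3, 1, 1, 1)
    b = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        k = rng.integers(1, 3, size=3)  # low spatial order only
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        freq = np.tensordot(k * direction, coords, axes=(0, 0))
        b += np.cos(2 * np.pi * freq + phase)
    span = b.max() - b.min()
    return 1.0 + amplitude * ((b - b.min()) / span - 0.5)


def _surround_blobs(
    cfg: PhantomConfig,
    mask: np.ndarray,
    center: np.ndarray,
    semiaxes: np.ndarray,
    rot: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth Gaussian blobs touching (but zeroed inside) the brain ellipsoid,
    scaled so their mean intensity over their support is brain_mean/contrast."""
    shape = cfg.grid_shape
    coords = _voxel_grid(shape)
    blob_field = np.zeros(shape, dtype=np.float64)
    for _ in range(cfg.n_surround_blobs):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # radius of the ellipsoid surface along direction u (in world frame)
        v = rot.T @ u
        r_surface = 1.0 / np.sqrt(np.sum((v / semiaxes) ** 2))
        sigma = rng.uniform(3.0, 6.0)
        c = center + u * (r_surface + 0.8 * sigma)
        c = np.clip(c, 0, np.asarray(shape) - 1)
        d2 = sum((coords[i] - c[i]) ** 2 for i in range(3))
        blob_field += np.exp(-d2 / (2 * sigma**2))
    blob_field[mask] = 0.0
    support = blob_field > 0.01 * blob_field.max() if blob_field.max() > 0 else None
    if support is not None and support.any():
        target = _BRAIN_MEAN / cfg.contrast
        blob_field *= target / blob_field[support].mean()
    return blob_field


def generate_phantom(config: PhantomConfig, seed: int) -> tuple[Volume3D, BinaryMask]:
    """Generate one phantom volume and its exact ground-truth brain mask.

    The mask is the voxelization of the randomly posed ellipsoid (a voxel is
    in-mask iff its center satisfies the ellipsoid inequality <= 1), computed
    before bias and noise are applied.  Identical (config, seed) pairs yield
    bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    semiaxes = _sample_semiaxes(config, rng)

    if config.random_rotation:
        rot = Rotation.random(rng=rng).as_matrix()
    else:
        rot = np.eye(3)

    # world-frame half-extent of the rotated ellipsoid along each axis
    extent = np.sqrt(((rot * semiaxes[None, :]) ** 2).sum(axis=1))
    lo = extent + 1.0
    hi = np.asarray(shape, dtype=np.float64) - 1.0 - extent - 1.0
    if np.any(hi < lo):
        raise ValueError(f"ellipsoid with semiaxes {semiaxes} cannot fit inside {shape}")
    if config.fixed_center is not None:
        center = np.asarray(config.fixed_center, dtype=np.float64)
    else:
        center = rng.uniform(lo, hi)

    coords = _voxel_grid(shape)
    rel = coords - center.reshape(3, 1, 1, 1)
    # body-frame coordinates: R^T (p - c)
    body = np.tensordot(rot.T, rel, axes=(1, 0))
    q = sum((body[i] / semiaxes[i]) ** 2 for i in range(3))
    mask = q <= 1.0

    template = np.where(mask, _BRAIN_MEAN, 0.0)
    template = template + _surround_blobs(config, mask, center, semiaxes, rot, rng)

    bias = _bias_field(shape, config.bias_amplitude, rng)
    noise = rng.normal(0.0, config.noise_sigma * _BRAIN_MEAN, size=shape)
    volume = (template * bias + noise).astype(np.float32)

    vol_id = f"phantom-{seed:08d}"
    return (
        Volume3D(volume, config.voxel_spacing, vol_id),
        BinaryMask(mask, vol_id),
    )


def cohort_item_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-item phantom seeds derived from a master seed."""
    rng = np.random.default_rng((int(seed) + 1) * 7919)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def generate_cohort(
    config: PhantomConfig,
    n: int,
    seed: int,
    duplicate_subject_rate: float = 0.0,
) -> TrainingSet:
    """Generate n phantoms with deterministic per-item seeds.

    With duplicate_subject_rate > 0 some consecutive scans share a subject id,
    emulating cohorts where a few fetuses are scanned twice; this exercises
    group-aware cross-validation splits.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    item_seeds = cohort_item_seeds(seed, n)
    dup_draws = np.random.default_rng(seed).uniform(size=n)

    items = []
    subject_counter = 0
    prev_subject: str | None = None
    for k in range(n):
        vol, mask = generate_phantom(config, int(item_seeds[k]))
        if k > 0 and dup_draws[k] < duplicate_subject_rate:
            sid = prev_subject  # repeat scan of the previous fetus
        else:
            sid = f"sub-{subject_counter:04d}"
            subject_counter += 1
        vol.id = f"{sid}_scan-{k:03d}"
        mask.id = vol.id
        items.append((vol, mask, sid))
        prev_subject = sid
    return TrainingSet(items)


def write_cohort(cohort: TrainingSet, out_dir: str | Path, seeds=None) -> Path:
    """Write phantom pairs as NIfTI plus a CSV manifest (id, subject_id, seed)."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (vol, mask, sid) in enumerate(cohort.items):
        write_volume(vol, out_dir / f"{vol.id}_epi.nii.gz")
        write_volume(mask, out_dir / f"{vol.id}_mask.nii.gz")
        rows.append({"id": vol.id, "subject_id": sid, "seed": seeds[k] if seeds else -1})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
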