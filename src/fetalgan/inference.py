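"""Whole-volume prediction, binarization and morphological post-processing.

A volume is swept by overlapping patches, each patch is pushed through the
trained network, and the per-patch probability maps are averaged back into a
whole-volume map.  The map is thresholded and then cleaned up: only the
largest connected component is kept (the brain is a single object) and
fully enclosed background cavities are filled.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .patching import PatchSpec, extract_patches, reassemble
from .volume_io import BinaryMask, ProbabilityMap, Volume3D

__all__ = ["predict_volume", "binarize", "postprocess"]


def predict_volume(model, v: Volume3D, spec: PatchSpec | None = None,
                   batch_size: int = 8) -> ProbabilityMap:
    """Patch-averaged probability map for one (already normalized) volume.

    ``model`` is anything with a ``predict(batch)`` method mapping a
    (batch, 1, d, h, w) array to same-shape probabilities — a trained
    generator, the baseline U-Net, or a stub in tests.
    """
    spec = spec or PatchSpec()
    pset = extract_patches(v, spec)
    probs = np.empty_like(pset.patches, dtype=np.float32)
    for start in range(0, len(pset), batch_size):
        batch = pset.patches[start : start + batch_size].astype(np.float32)
        out = model.predict(batch[:, None])  # add channel axis
        probs[start : start + batch_size] = np.asarray(out)[:, 0]
    pm = reassemble(probs, pset.origins, pset.source_shape)
    if pm.shape != v.shape:  # undo padding of undersized axes
        pm = ProbabilityMap(pm.values[: v.shape[0], : v.shape[1], : v.shape[2]], v.id)
    else:
        pm.id = v.id
    return pm


def binarize(p: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map; ties (p == threshold) count as foreground."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie strictly inside (0, 1), got {threshold}")
    values = p.values if isinstance(p, ProbabilityMap) else np.asarray(p)
    return BinaryMask(values >= threshold, getattr(p, "id", ""))


def postprocess(m: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep the largest connected component and fill internal cavities.

    Components use 26-connectivity by default; cavity filling treats the
    background as 6-connected (a cavity is background not reachable from the
    volume border).  The result is a single cavity-free component that is a
    superset of the largest component of the input.
    """
    values = m.values if isinstance(m, BinaryMask) else np.asarray(m, dtype=bool)
    if not values.any():
        raise ValueError("cannot post-process an empty mask")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(values, structure=structure)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = int(sizes.argmax())
        values = labels == keep
    filled = ndimage.binary_fill_holes(values)  # 6-connected background
    return BinaryMask(filled, getattr(m, "id", ""))
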