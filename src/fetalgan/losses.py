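"""Training losses: multi-scale L1 adversarial loss and binary cross-entropy.

The adversarial objective compares the critic's hierarchical features of the
image masked by the predicted probability map against features of the image
masked by the ground truth:

    min_G max_D  L = (1/N) sum_n  l_mae( f_D(x_n * G(x_n)), f_D(x_n * y_n) )

where l_mae averages, over critic layers, the mean absolute difference
between the two feature grids.  The critic is trained to maximize L (making
its features discriminative at every scale) while the generator minimizes it.
The baseline U-Net instead minimizes plain voxel-wise binary cross-entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["multiscale_mae_loss", "multiscale_mae_grads", "bce_loss", "bce_grad"]

_EPS = 1e-7


def multiscale_mae_loss(f_pred, f_true) -> float:
    """Mean over critic layers of the per-layer mean absolute feature difference.

    Symmetric in its arguments, non-negative, and zero iff all feature pairs
    are identical.
    """
    _check_feature_lists(f_pred, f_true)
    per_layer = [float(np.mean(np.abs(np.asarray(a, dtype=np.float64) - b)))
                 for a, b in zip(f_pred, f_true)]
    return float(np.mean(per_layer))


def multiscale_mae_grads(f_pred, f_true):
    """Loss value plus its gradients with respect to each feature list.

    d/da mean|a - b| = sign(a - b) / numel, averaged over layers.
    """
    _check_feature_lists(f_pred, f_true)
    n_layers = len(f_pred)
    loss = 0.0
    d_pred, d_true = [], []
    for a, b in zip(f_pred, f_true):
        diff = np.asarray(a, dtype=np.float32) - np.asarray(b, dtype=np.float32)
        loss += float(np.mean(np.abs(diff))) / n_layers
        g = np.sign(diff) / (diff.size * n_layers)
        d_pred.append(g.astype(np.float32))
        d_true.append((-g).astype(np.float32))
    return loss, d_pred, d_true


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, probabilities clamped to [1e-7, 1 - 1e-7]."""
    p, y = _check_pair(p, y)
    pc = np.clip(p, _EPS, 1.0 - _EPS).astype(np.float64)
    return float(np.mean(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))))


def bce_grad(p: np.ndarray, y: np.ndarray):
    """BCE value and its gradient with respect to p."""
    p, y = _check_pair(p, y)
    pc = np.clip(p, _EPS, 1.0 - _EPS).astype(np.float64)
    loss = float(np.mean(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))))
    grad = ((pc - y) / (pc * (1.0 - pc))) / p.size
    # clamped voxels are at the boundary of the admissible range; their
    # gradient is taken at the clamped value (finite by construction)
    return loss, grad.astype(np.float32)


def _check_feature_lists(f_pred, f_true) -> None:
    if len(f_pred) == 0 or len(f_true) == 0:
        raise ValueError("feature lists must be non-empty")
    if len(f_pred) != len(f_true):
        raise ValueError(f"feature list length mismatch: {len(f_pred)} vs {len(f_true)}")
    for i, (a, b) in enumerate(zip(f_pred, f_true)):
        if np.shape(a) != np.shape(b):
            raise ValueError(
                f"layer {i} feature shape mismatch: {np.shape(a)} vs {np.shape(b)}"
            )


def _check_pair(p, y):
    p = np.asarray(p, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {y.shape}")
    return p, y
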