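"""Finite-difference validation of every layer's backward pass.

Backpropagation is implemented by hand, so each layer's analytic gradient is
compared against central differences in double precision on small tensors.
"""

import numpy as np
import pytest

from fetalgan import nn
from fetalgan.models import (
    BaselineUNet,
    BaselineUNetSpec,
    CriticModel,
    CriticSpec,
    GeneratorModel,
    GeneratorSpec,
)

RNG = np.random.default_rng(1)


def _to_float64(layer):
    for p in layer.params():
        p.data = p.data.astype(np.float64)
        p.grad = p.grad.astype(np.float64)
    for bn in _walk_batchnorms(layer):
        bn.running_mean = bn.running_mean.astype(np.float64)
        bn.running_var = bn.running_var.astype(np.float64)
    return layer


def _walk_batchnorms(obj, seen=None):
    seen = seen if seen is not None else set()
    if id(obj) in seen:
        return
    seen.add(id(obj))
    if isinstance(obj, nn.BatchNorm3d):
        yield obj
        return
    for attr in vars(obj).values():
        items = attr if isinstance(attr, list) else [attr]
        for item in items:
            if isinstance(item, nn.Layer):
                yield from _walk_batchnorms(item, seen)


def _loss_of(layer, x, train):
    y, _ = layer.forward(x, train=train, rng=np.random.default_rng(5))
    if isinstance(y, list):
        return sum(float((np.asarray(t) ** 2).sum()) for t in y)
    return float((y ** 2).sum())


def assert_gradients_match(layer, x, train=True, tol=1e-4, rel=None, n_probe=5,
                           probe_seed=823):
    layer = _to_float64(layer)
    rel = rel if rel is not None else tol
    probe_rng = np.random.default_rng(probe_seed)
    y, cache = layer.forward(x, train=train, rng=np.random.default_rng(5))
    dy = [2 * t for t in y] if isinstance(y, list) else 2 * y
    for p in layer.params():
        p.zero_grad()
    dx = layer.backward(dy, cache)

    eps = 1e-5
    for _ in range(n_probe):
        idx = tuple(probe_rng.integers(0, s) for s in x.shape)
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = (_loss_of(layer, xp, train) - _loss_of(layer, xm, train)) / (2 * eps)
        assert dx[idx] == pytest.approx(num, abs=tol, rel=rel)

    for p in layer.params():
        flat = p.data.ravel()
        for _ in range(3):
            j = int(probe_rng.integers(0, flat.size))
            orig = flat[j]
            flat[j] = orig + eps
            lp = _loss_of(layer, x, train)
            flat[j] = orig - eps
            lm = _loss_of(layer, x, train)
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            assert p.grad.ravel()[j] == pytest.approx(num, abs=tol, rel=rel)


X = RNG.normal(size=(2, 3, 8, 8, 8))


@pytest.mark.parametrize("layer", [
    nn.Conv3d(3, 4, k=3, rng=np.random.default_rng(2)),
    nn.Conv3d(3, 4, k=3, stride=2, rng=np.random.default_rng(3)),
    nn.Conv3d(3, 2, k=1, pad=0, rng=np.random.default_rng(4)),
    nn.ConvTranspose3d(3, 2, rng=np.random.default_rng(5)),
    nn.MaxPool3d(),
    nn.BatchNorm3d(3),
    nn.LeakyReLU(0.2),
    nn.PReLU(3),
    nn.Sigmoid(),
], ids=["conv3", "conv3s2", "conv1", "convT", "maxpool", "bn", "lrelu",
        "prelu", "sigmoid"])
def test_layer_gradients(layer):
    assert_gradients_match(layer, X.copy())


def test_batchnorm_eval_gradient():
    bn = nn.BatchNorm3d(3)
    bn.running_mean = bn.running_mean.astype(np.float64) + 0.3
    bn.running_var = bn.running_var.astype(np.float64) * 1.7
    assert_gradients_match(bn, X.copy(), train=False)


@pytest.mark.parametrize("model_factory", [
    lambda: GeneratorModel(GeneratorSpec(base_channels=2, seed=1)),
    lambda: CriticModel(CriticSpec(base_channels=2, seed=1)),
    lambda: BaselineUNet(BaselineUNetSpec(base_channels=2, dropout_rate=0.0, seed=1)),
], ids=["generator", "critic", "unet"])
def test_full_model_gradients(model_factory):
    # eval mode: batch-norm statistics are constants, so the check isolates
    # the chain-rule wiring; train-mode math is covered per-layer above
    x = RNG.normal(size=(2, 1, 16, 16, 16))
    model = _to_float64(model_factory())
    for bn in _walk_batchnorms(model):
        bn.running_mean = bn.running_mean + 0.1
        bn.running_var = bn.running_var * 1.3
    # 1% slack: finite differences can cross max-pool / rectifier kinks
    assert_gradients_match(model, x, train=False, tol=1e-3, rel=1e-2, n_probe=4)


def test_adam_descends_a_quadratic():
    p = nn.Param(np.array([5.0, -3.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        p.zero_grad()
        p.grad += 2 * p.data  # d/dx of |x|^2
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_adam_maximize_ascends():
    p = nn.Param(np.array([0.1], dtype=np.float32))
    opt = nn.Adam([p], lr=0.05, maximize=True)
    for _ in range(50):
        p.zero_grad()
        p.grad += -2 * p.data + 2  # gradient of -(x-1)^2
        opt.step()
    assert abs(float(p.data[0]) - 1.0) < 0.05
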