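"""Network architectures: SegAN-style generator, critic, and 3D U-Net baseline.

The generator (segmenter) is a residual encoder-decoder: four encoder and
four decoder residual blocks with leaky-ReLU activations and batch
normalization.  Downsampling uses 3x3x3 convolutions with stride 2;
upsampling uses 2x2x2 transpose convolutions with resize factor 2; encoder
features are concatenated into the decoder at matching scales, and a sigmoid
head emits a per-voxel brain probability.  Generator channel widths are
capped at four times the base width, which keeps its trainable parameter
count strictly below the baseline U-Net built at the same base width — the
property behind its faster per-volume inference.

The critic is a fully convolutional feature extractor over image-masked-by-
label inputs; the output of every layer is exposed so the adversarial loss
can compare prediction-masked and truth-masked features at all scales.

The baseline U-Net has four two-convolution blocks per path with batch
normalization and PReLU, feature doubling per block, max-pooling downsamples,
transpose-convolution upsamples, skip concatenation, and 15% dropout at the
bottleneck.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Dropout,
    Layer,
    LeakyReLU,
    MaxPool3d,
    Param,
    PReLU,
    Sequential,
    Sigmoid,
)

__all__ = [
    "GeneratorSpec",
    "CriticSpec",
    "BaselineUNetSpec",
    "GeneratorModel",
    "CriticModel",
    "BaselineUNet",
    "build_generator",
    "build_critic",
    "build_unet",
    "masked_input",
    "count_params",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# specs


@dataclass
class GeneratorSpec:
    """Residual encoder-decoder segmenter configuration.

    n_blocks counts residual blocks (encoder + decoder); base_channels sets
    the width of the first block, with deeper levels at 2x and 4x (capped).
    """

    n_blocks: int = 8
    base_channels: int = 8
    leaky_alpha: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks % 2 != 0 or self.n_blocks < 2:
            raise ValueError(f"n_blocks must be a positive even number, got {self.n_blocks}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {self.base_channels}")

    @property
    def depth(self) -> int:
        return self.n_blocks // 2

    @property
    def channels(self) -> list[int]:
        w = self.base_channels
        # double per level, capped at 4w (parameter economy vs the baseline)
        return [min(w * 2**i, 4 * w) for i in range(self.depth)]


@dataclass
class CriticSpec:
    """Critic configuration: n_layers stride-2 convolutions, all features exposed."""

    n_layers: int = 3
    base_channels: int = 8
    leaky_alpha: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.n_layers)]


@dataclass
class BaselineUNetSpec:
    """3D U-Net baseline: 4 blocks per path, 2 convs per block, doubling widths.

    The clinical-scale configuration uses 96 initial feature maps; the desk
    default is much narrower so the model trains in minutes on a CPU.
    """

    n_levels: int = 4
    base_channels: int = 8
    dropout_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.n_levels)]


# ---------------------------------------------------------------------------
# building blocks


class _ResBlock(Layer):
    """conv-BN-lrelu-conv-BN with a projection shortcut, then lrelu."""

    def __init__(self, cin: int, cout: int, alpha: float, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, k=3, rng=rng)
        self.bn1 = BatchNorm3d(cout)
        self.act1 = LeakyReLU(alpha)
        self.conv2 = Conv3d(cout, cout, k=3, rng=rng)
        self.bn2 = BatchNorm3d(cout)
        self.proj = Conv3d(cin, cout, k=1, pad=0, rng=rng) if cin != cout else None
        self.act_out = LeakyReLU(alpha)

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train=False, rng=None):
        h, c1 = self.conv1.forward(x, train, rng)
        h, cb1 = self.bn1.forward(h, train, rng)
        h, ca1 = self.act1.forward(h, train, rng)
        h, c2 = self.conv2.forward(h, train, rng)
        h, cb2 = self.bn2.forward(h, train, rng)
        if self.proj is not None:
            sc, cp = self.proj.forward(x, train, rng)
        else:
            sc, cp = x, None
        y, cao = self.act_out.forward(h + sc, train, rng)
        return y, (c1, cb1, ca1, c2, cb2, cp, cao)

    def backward(self, dy, cache):
        c1, cb1, ca1, c2, cb2, cp, cao = cache
        dh = self.act_out.backward(dy, cao)
        dsc = dh
        d = self.bn2.backward(dh, cb2)
        d = self.conv2.backward(d, c2)
        d = self.act1.backward(d, ca1)
        d = self.bn1.backward(d, cb1)
        dx = self.conv1.backward(d, c1)
        if self.proj is not None:
            dx = dx + self.proj.backward(dsc, cp)
        else:
            dx = dx + dsc
        return dx


class _ConvBlock(Layer):
    """U-Net block: two (conv-BN-PReLU) stages."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.seq = Sequential(
            Conv3d(cin, cout, k=3, rng=rng), BatchNorm3d(cout), PReLU(cout),
            Conv3d(cout, cout, k=3, rng=rng), BatchNorm3d(cout), PReLU(cout),
        )

    def params(self):
        return self.seq.params()

    def forward(self, x, train=False, rng=None):
        return self.seq.forward(x, train, rng)

    def backward(self, dy, cache):
        return self.seq.backward(dy, cache)


def _check_divisible(shape, depth: int, name: str) -> None:
    f = 2**depth
    if any(s % f != 0 or s < f for s in shape):
        raise ValueError(
            f"{name} input spatial shape {tuple(shape)} must be divisible by "
            f"2^{depth} = {f}"
        )


# ---------------------------------------------------------------------------
# generator


class GeneratorModel(Layer):
    """SegAN segmenter: maps a 1-channel patch to a same-shape probability patch."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.channels
        alpha = spec.leaky_alpha
        self.enc_blocks, self.downs = [], []
        cin = 1
        for c in ch:
            self.enc_blocks.append(_ResBlock(cin, c, alpha, rng))
            self.downs.append(Sequential(
                Conv3d(c, c, k=3, stride=2, rng=rng), BatchNorm3d(c), LeakyReLU(alpha),
            ))
            cin = c
        self.ups, self.dec_blocks = [], []
        dec_out = ch[:-1][::-1] + [ch[0]]  # e.g. [4w, 2w, w, w] for depth 4
        prev = ch[-1]
        for skip_c, out_c in zip(ch[::-1], dec_out):
            self.ups.append(ConvTranspose3d(prev, prev, rng=rng))
            self.dec_blocks.append(_ResBlock(prev + skip_c, out_c, alpha, rng))
            prev = out_c
        self.head = Conv3d(prev, 1, k=1, pad=0, rng=rng)
        self.out_act = Sigmoid()

    def params(self):
        out = []
        for blk in self.enc_blocks + self.downs + self.ups + self.dec_blocks:
            out += blk.params()
        return out + self.head.params()

    def forward(self, x, train=False, rng=None):
        _check_divisible(x.shape[2:], self.spec.depth, "generator")
        skips, caches_e, caches_d = [], [], []
        h = x
        for blk, down in zip(self.enc_blocks, self.downs):
            h, cb = blk.forward(h, train, rng)
            skips.append(h)
            h, cd = down.forward(h, train, rng)
            caches_e.append((cb, cd))
        skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h, cu = up.forward(h, train, rng)
            h = np.concatenate([h, skip], axis=1)
            skip_channels.append(skip.shape[1])
            h, cdec = dec.forward(h, train, rng)
            caches_d.append((cu, cdec))
        y, ch_ = self.head.forward(h, train, rng)
        y, ca = self.out_act.forward(y, train, rng)
        return y, (caches_e, caches_d, skip_channels, ch_, ca)

    def backward(self, dy, cache):
        caches_e, caches_d, skip_channels, ch_, ca = cache
        d = self.out_act.backward(dy, ca)
        d = self.head.backward(d, ch_)
        dskips = []
        for up, dec, (cu, cdec), skc in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(caches_d),
            reversed(skip_channels),
        ):
            d = dec.backward(d, cdec)
            dskips.append(d[:, -skc:])
            d = up.backward(np.ascontiguousarray(d[:, :-skc]), cu)
        # dskips currently ordered bottom-up (deepest skip last in reversed walk)
        dskips = dskips[::-1]  # now dskips[i] pairs with encoder level i... reversed below
        for blk, down, (cb, cd), dskip in zip(
            reversed(self.enc_blocks), reversed(self.downs), reversed(caches_e), dskips
        ):
            d = down.backward(d, cd)
            d = blk.backward(d + dskip, cb)
        return d

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass on a (batch, 1, D, H, W) array."""
        y, _ = self.forward(np.asarray(x, dtype=np.float32), train=False)
        return y


# ---------------------------------------------------------------------------
# critic


class CriticModel(Layer):
    """Feature extractor over masked patches; exposes every layer's output."""

    def __init__(self, spec: CriticSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.stages = []
        cin = 1
        for c in spec.channels:
            self.stages.append(Sequential(
                Conv3d(cin, c, k=3, stride=2, rng=rng),
                BatchNorm3d(c),
                LeakyReLU(spec.leaky_alpha),
            ))
            cin = c

    def params(self):
        return [p for st in self.stages for p in st.params()]

    def forward(self, x, train=False, rng=None):
        """Return the ordered list of per-layer feature grids."""
        if min(x.shape[2:]) < 2**self.spec.n_layers:
            raise ValueError(
                f"critic input spatial {x.shape[2:]} smaller than total "
                f"downsampling factor {2**self.spec.n_layers}"
            )
        feats, caches = [], []
        h = x
        for st in self.stages:
            h, c = st.forward(h, train, rng)
            feats.append(h)
            caches.append(c)
        return feats, caches

    def backward(self, dfeats, caches):
        """Backpropagate per-layer feature gradients to the input."""
        d = None
        for st, c, df in zip(reversed(self.stages), reversed(caches), reversed(dfeats)):
            d = df if d is None else d + df
            d = st.backward(d, c)
        return d

    def features(self, x: np.ndarray, train: bool = False):
        feats, _ = self.forward(np.asarray(x, dtype=np.float32), train=train)
        return feats


# ---------------------------------------------------------------------------
# baseline U-Net


class BaselineUNet(Layer):
    """Patch-based 3D U-Net with sigmoid probability output."""

    def __init__(self, spec: BaselineUNetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.channels
        self.enc_blocks = []
        cin = 1
        for c in ch:
            self.enc_blocks.append(_ConvBlock(cin, c, rng))
            cin = c
        self.pool = MaxPool3d()
        bott = ch[-1] * 2
        self.bottleneck = _ConvBlock(ch[-1], bott, rng)
        self.dropout = Dropout(spec.dropout_rate)
        self.ups, self.dec_blocks = [], []
        prev = bott
        for c in reversed(ch):
            self.ups.append(ConvTranspose3d(prev, c, rng=rng))
            self.dec_blocks.append(_ConvBlock(2 * c, c, rng))
            prev = c
        self.head = Conv3d(prev, 1, k=1, pad=0, rng=rng)
        self.out_act = Sigmoid()

    def params(self):
        out = []
        for blk in self.enc_blocks:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.ups + self.dec_blocks:
            out += blk.params()
        return out + self.head.params()

    def forward(self, x, train=False, rng=None):
        _check_divisible(x.shape[2:], self.spec.n_levels, "unet")
        skips, caches_e = [], []
        h = x
        for blk in self.enc_blocks:
            h, cb = blk.forward(h, train, rng)
            skips.append(h)
            h, cp = self.pool.forward(h, train, rng)
            caches_e.append((cb, cp))
        h, cbott = self.bottleneck.forward(h, train, rng)
        h, cdrop = self.dropout.forward(h, train, rng)
        caches_d = []
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h, cu = up.forward(h, train, rng)
            h = np.concatenate([h, skip], axis=1)
            h, cdec = dec.forward(h, train, rng)
            caches_d.append((cu, cdec, skip.shape[1]))
        y, ch_ = self.head.forward(h, train, rng)
        y, ca = self.out_act.forward(y, train, rng)
        return y, (caches_e, cbott, cdrop, caches_d, ch_, ca)

    def backward(self, dy, cache):
        caches_e, cbott, cdrop, caches_d, ch_, ca = cache
        d = self.out_act.backward(dy, ca)
        d = self.head.backward(d, ch_)
        dskips = []
        for up, dec, (cu, cdec, skc) in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(caches_d)
        ):
            d = dec.backward(d, cdec)
            dskips.append(d[:, -skc:])
            d = up.backward(np.ascontiguousarray(d[:, :-skc]), cu)
        d = self.dropout.backward(d, cdrop)
        d = self.bottleneck.backward(d, cbott)
        dskips = dskips[::-1]
        for blk, (cb, cp), dskip in zip(
            reversed(self.enc_blocks), reversed(caches_e), dskips
        ):
            d = self.pool.backward(d, cp)
            d = blk.backward(d + dskip, cb)
        return d

    def predict(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(np.asarray(x, dtype=np.float32), train=False)
        return y


# ---------------------------------------------------------------------------
# helpers


def build_generator(spec: GeneratorSpec) -> GeneratorModel:
    return GeneratorModel(spec)


def build_critic(spec: CriticSpec) -> CriticModel:
    return CriticModel(spec)


def build_unet(spec: BaselineUNetSpec) -> BaselineUNet:
    return BaselineUNet(spec)


def masked_input(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Element-wise product of an image patch with a label/probability patch.

    The critic never sees raw labels: it compares hierarchical features of
    the image masked by the prediction against the image masked by the
    ground truth.
    """
    x = np.asarray(x, dtype=np.float32)
    m = np.asarray(m, dtype=np.float32)
    if x.shape != m.shape:
        raise ValueError(f"shape mismatch: image {x.shape} vs mask {m.shape}")
    return x * m


def count_params(model: Layer) -> int:
    return int(sum(p.size for p in model.params()))


_SPEC_TYPES = {
    "generator": (GeneratorSpec, GeneratorModel),
    "critic": (CriticSpec, CriticModel),
    "unet": (BaselineUNetSpec, BaselineUNet),
}


def _model_kind(model: Layer) -> str:
    for kind, (_, cls) in _SPEC_TYPES.items():
        if isinstance(model, cls):
            return kind
    raise TypeError(f"unknown model type {type(model)!r}")


def save_model(model, path: str | Path) -> Path:
    """Save parameters (npz) with a JSON sidecar recording the spec."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz") if path.suffix else path.with_suffix(".npz")
    kind = _model_kind(model)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    # batchnorm running statistics travel with the checkpoint
    stats = {}
    for i, bn in enumerate(_iter_batchnorms(model)):
        stats[f"rm{i}"] = bn.running_mean
        stats[f"rv{i}"] = bn.running_var
    np.savez(str(path), **arrays, **stats)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"kind": kind, "spec": asdict(model.spec)}, indent=2))
    return path


def load_model(path: str | Path):
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz") if path.suffix else path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_cls, model_cls = _SPEC_TYPES[meta["kind"]]
    model = model_cls(spec_cls(**meta["spec"]))
    with np.load(str(path)) as data:
        for i, p in enumerate(model.params()):
            p.data[...] = data[f"p{i}"]
        for i, bn in enumerate(_iter_batchnorms(model)):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
    return model


def _iter_batchnorms(layer: Layer):
    """Deterministic walk over all BatchNorm3d sub-layers."""
    if isinstance(layer, BatchNorm3d):
        yield layer
        return
    for attr in vars(layer).values():
        items = attr if isinstance(attr, list) else [attr]
        for item in items:
            if isinstance(item, BatchNorm3d):
                yield item
            elif isinstance(item, (Sequential, _ResBlock, _ConvBlock)):
                yield from _iter_batchnorms(item)
            elif isinstance(item, Layer) and not isinstance(
                item, (Conv3d, ConvTranspose3d, MaxPool3d, LeakyReLU, PReLU, Sigmoid, Dropout)
            ):
                yield from _iter_batchnorms(item)
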