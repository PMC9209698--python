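"""Whole-volume prediction, thresholding and morphological cleanup."""

import numpy as np
import pytest
from scipy import ndimage

from fetalgan import (
    PatchSpec,
    ProbabilityMap,
    Volume3D,
    binarize,
    postprocess,
    predict_volume,
)


class ConstantModel:
    """Stub: always emits the same probability."""

    def __init__(self, value):
        self.value = value

    def predict(self, x):
        return np.full_like(x, self.value, dtype=np.float32)


class OriginTaggedModel:
    """Stub: emits a per-call constant drawn from a queue, to probe averaging."""

    def __init__(self, values):
        self.values = list(values)

    def predict(self, x):
        out = np.empty_like(x, dtype=np.float32)
        for i in range(len(x)):
            out[i] = self.values.pop(0)
        return out


class IdentityModel:
    def predict(self, x):
        return np.clip(x, 0.0, 1.0)


def test_constant_model_gives_constant_map(rng):
    v = Volume3D(rng.uniform(size=(48, 48, 48)).astype(np.float32))
    pm = predict_volume(ConstantModel(0.7), v, PatchSpec(size=32, stride=16))
    assert pm.shape == v.shape
    assert np.allclose(pm.values, 0.7, atol=1e-6)


def test_single_whole_volume_patch_equals_direct_output(rng):
    v = Volume3D(rng.uniform(size=(32, 32, 32)).astype(np.float32))
    pm = predict_volume(IdentityModel(), v, PatchSpec(size=32, stride=32))
    assert np.array_equal(pm.values, v.values)


def test_overlap_averaging_matches_bruteforce_accumulator(rng):
    """Patch-constant outputs let us predict the averaged map exactly."""
    v = Volume3D(rng.uniform(size=(48, 48, 48)).astype(np.float32))
    spec = PatchSpec(size=32, stride=16)
    from fetalgan.patching import extract_patches

    pset = extract_patches(v, spec)
    values = [0.1 + 0.05 * k for k in range(len(pset))]
    pm = predict_volume(OriginTaggedModel(values), v, spec, batch_size=3)

    acc = np.zeros(v.shape)
    cnt = np.zeros(v.shape)
    for val, (a, b, c) in zip(values, pset.origins):
        acc[a:a + 32, b:b + 32, c:c + 32] += val
        cnt[a:a + 32, b:b + 32, c:c + 32] += 1
    assert np.allclose(pm.values, acc / cnt, atol=1e-6)


def test_binarize_threshold_and_tie_rule():
    pm = ProbabilityMap(np.full((3, 3, 3), 0.6, dtype=np.float32))
    assert binarize(pm, 0.5).values.all()
    tie = ProbabilityMap(np.full((3, 3, 3), 0.5, dtype=np.float32))
    assert binarize(tie, 0.5).values.all()  # p == t counts as foreground
    below = ProbabilityMap(np.full((3, 3, 3), 0.49, dtype=np.float32))
    assert not binarize(below, 0.5).values.any()


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
def test_binarize_rejects_degenerate_threshold(bad):
    pm = ProbabilityMap(np.zeros((2, 2, 2), dtype=np.float32))
    with pytest.raises(ValueError):
        binarize(pm, bad)


def _ball(shape=(20, 20, 20), center=(10, 10, 10), r=6):
    g = np.indices(shape)
    d2 = sum((g[i] - center[i]) ** 2 for i in range(3))
    return d2 <= r * r


def test_postprocess_fills_interior_hole():
    mask = _ball()
    mask[10, 10, 10] = False
    out = postprocess(__wrap(mask))
    assert out.values[10, 10, 10]
    assert out.values.sum() == _ball().sum()


def test_postprocess_removes_isolated_voxel():
    mask = _ball()
    mask[1, 1, 1] = True
    out = postprocess(__wrap(mask))
    assert not out.values[1, 1, 1]
    assert np.array_equal(out.values, _ball())


def test_postprocess_output_single_component_no_cavities(rng):
    """Flood-fill oracle: exactly one 26-connected component, zero cavities."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        mask = r.uniform(size=(16, 16, 16)) > 0.7
        mask[6:10, 6:10, 6:10] = True  # guarantee a dominant blob
        out = postprocess(__wrap(mask)).values
        labels, n = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=bool))
        assert n == 1
        # cavity scan: background unreachable from the border must be empty
        bg_labels, _ = ndimage.label(~out)
        border = set()
        for ax in range(3):
            for side in (0, -1):
                sl = [slice(None)] * 3
                sl[ax] = side
                border.update(np.unique(bg_labels[tuple(sl)]))
        cavity = np.isin(bg_labels, sorted(set(np.unique(bg_labels)) - border - {0}))
        assert cavity.sum() == 0


def test_postprocess_superset_of_largest_component():
    mask = _ball()
    mask[0:2, 0:2, 0:2] = True  # small separate blob
    out = postprocess(__wrap(mask)).values
    assert np.all(out[_ball()])


def test_postprocess_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        postprocess(__wrap(np.zeros((4, 4, 4), dtype=bool)))


def test_postprocess_never_decreases_dice_on_constructed_errors(rng):
    """Hole/isolated-voxel errors are exactly what the cleanup removes."""
    from fetalgan import compute_metrics

    truth = _ball()
    noisy = truth.copy()
    noisy[10, 10, 10] = False  # interior hole
    noisy[2, 2, 2] = True      # isolated speck
    before = compute_metrics(noisy, truth).dice
    after = compute_metrics(postprocess(__wrap(noisy)).values, truth).dice
    assert after >= before
    assert after == 1.0


def __wrap(arr):
    from fetalgan import BinaryMask

    return BinaryMask(arr)
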