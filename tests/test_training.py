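"""Fold plans, patch sampling, adversarial step directions, training smoke."""

import numpy as np
import pandas as pd
import pytest

from fetalgan import (
    BaselineUNetSpec,
    CriticSpec,
    GeneratorSpec,
    TrainConfig,
    TrainingSet,
    build_critic,
    build_generator,
    generate_cohort,
    kfold_split,
    train_baseline_unet,
    train_segan,
)
from fetalgan.nn import Adam
from fetalgan.training import (
    FoldPlan,
    sample_patch_batch,
    segan_critic_step,
    segan_generator_step,
)
from fetalgan.losses import multiscale_mae_loss
from fetalgan.models import masked_input


def _items(subject_ids):
    """Minimal items list carrying only subject ids (for fold-plan tests)."""
    return [(None, None, sid) for sid in subject_ids]


def test_ten_subjects_five_folds_of_two():
    plan = kfold_split(_items([f"s{i}" for i in range(10)]), k=5, seed=1)
    assert plan.k == 5
    assert sorted(len(f) for f in plan.folds) == [2] * 5


def test_repeat_scans_travel_together():
    sids = ["a", "b", "c", "d", "e", "a", "c"]
    plan = kfold_split(_items(sids), k=3, seed=2)
    for fold in plan.folds:
        fold_sids = {sids[i] for i in fold}
        for sid in fold_sids:
            everywhere = [i for i, s in enumerate(sids) if s == sid]
            assert set(everywhere) <= set(fold)


def test_folds_partition_all_indices():
    plan = kfold_split(_items([f"s{i}" for i in range(13)]), k=4, seed=3)
    all_idx = sorted(i for f in plan.folds for i in f)
    assert all_idx == list(range(13))


def test_fewer_subjects_than_k_rejected():
    with pytest.raises(ValueError, match="subjects"):
        kfold_split(_items(["a", "b", "a"]), k=3, seed=0)


def test_fold_plan_deterministic_by_seed():
    items = _items([f"s{i}" for i in range(9)])
    p1 = kfold_split(items, 3, seed=4)
    p2 = kfold_split(items, 3, seed=4)
    p3 = kfold_split(items, 3, seed=5)
    assert p1.folds == p2.folds
    assert p1.folds != p3.folds


def test_fold_plan_validates_leakage():
    with pytest.raises(ValueError, match="more than one fold"):
        FoldPlan(folds=[[0], [1]], subject_ids=["a", "a"])


@pytest.fixture(scope="module")
def tiny_cohort(small_phantom_config_module):
    return generate_cohort(small_phantom_config_module, 3, seed=99)


@pytest.fixture(scope="module")
def small_phantom_config_module():
    from fetalgan import PhantomConfig

    return PhantomConfig(
        grid_shape=(24, 24, 24),
        brain_semiaxes_range=(6.0, 8.0),
        contrast=1.5,
        noise_sigma=0.02,
        bias_amplitude=0.1,
        n_surround_blobs=3,
    )


def _tiny_cfg(**kw):
    base = dict(epochs=1, patches_per_volume=2, batch_size=2, patch_size=16,
                infer_stride=16, learning_rate=1e-3, seed=5)
    base.update(kw)
    return TrainConfig(**base)


def test_sampled_patches_have_matching_masks(tiny_cohort):
    from fetalgan.training import _prepare

    vols, masks = _prepare(tiny_cohort)
    cfg = _tiny_cfg(patches_per_volume=4)
    x, y = sample_patch_batch(vols, masks, cfg, np.random.default_rng(0))
    assert x.shape == y.shape == (12, 1, 16, 16, 16)
    assert set(np.unique(y)) <= {0.0, 1.0}
    # balanced sampling: at least half of all patches touch the brain
    frac_touching = np.mean([yy.any() for yy in y])
    assert frac_touching >= 0.5


def test_adversarial_step_directions(tiny_cohort):
    """On a fixed batch: a critic step must not decrease the multi-scale loss,
    a generator step must not increase it (small-step, full-batch check)."""
    from fetalgan.training import _prepare

    vols, masks = _prepare(tiny_cohort)
    cfg = _tiny_cfg(patches_per_volume=2, batch_size=6)
    for seed in (0, 1, 2):
        x, y = sample_patch_batch(vols, masks, cfg, np.random.default_rng(seed))
        gen = build_generator(GeneratorSpec(base_channels=2, seed=seed))
        critic = build_critic(CriticSpec(base_channels=2, seed=seed + 10))

        def current_loss(gen_train):
            # evaluate in the same batch-statistics mode the step optimizes:
            # on a fixed batch, train-mode batch norm is a deterministic
            # function of the parameters alone
            gx, _ = gen.forward(x, train=gen_train)
            b = len(x)
            feats, _ = critic.forward(
                np.concatenate([masked_input(x, gx), masked_input(x, y)]), train=True
            )
            f_p = [masked_input(x, gx)] + [f[:b] for f in feats]
            f_t = [masked_input(x, y)] + [f[b:] for f in feats]
            return multiscale_mae_loss(f_p, f_t)

        opt_c = Adam(critic.params(), lr=1e-4, maximize=True)
        before = current_loss(gen_train=False)
        segan_critic_step(gen, critic, opt_c, x, y)
        after_critic = current_loss(gen_train=False)
        assert after_critic >= before - 1e-6

        opt_g = Adam(gen.params(), lr=1e-4)
        before_g = current_loss(gen_train=True)
        segan_generator_step(gen, critic, opt_g, x, y)
        after_g = current_loss(gen_train=True)
        assert after_g <= before_g + 1e-6


def test_train_segan_smoke_contract(tiny_cohort):
    gen, history = train_segan(
        tiny_cohort,
        GeneratorSpec(base_channels=2, seed=1),
        CriticSpec(base_channels=2, seed=2),
        _tiny_cfg(),
    )
    assert len(history) == 1
    assert np.isfinite(history.gen_loss.iloc[0])
    assert np.isfinite(history.critic_loss.iloc[0])
    out = gen.predict(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_train_segan_seed_reproducibility(tiny_cohort):
    args = (GeneratorSpec(base_channels=2, seed=1), CriticSpec(base_channels=2, seed=2))
    _, h1 = train_segan(tiny_cohort, *args, _tiny_cfg())
    _, h2 = train_segan(tiny_cohort, *args, _tiny_cfg())
    pd.testing.assert_frame_equal(h1, h2)


def test_train_unet_smoke_and_loss_trend(tiny_cohort):
    """On easy low-noise phantoms the BCE loss should trend downward."""
    unet, history = train_baseline_unet(
        tiny_cohort,
        BaselineUNetSpec(base_channels=2, seed=3),
        _tiny_cfg(epochs=5, learning_rate=3e-3, patches_per_volume=4),
    )
    losses = history.loss.to_numpy()
    assert np.all(np.isfinite(losses))
    assert losses[-2:].mean() < losses[:2].mean()
    out = unet.predict(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_train_unet_seed_reproducibility(tiny_cohort):
    spec = BaselineUNetSpec(base_channels=2, seed=3)
    _, h1 = train_baseline_unet(tiny_cohort, spec, _tiny_cfg())
    _, h2 = train_baseline_unet(tiny_cohort, spec, _tiny_cfg())
    pd.testing.assert_frame_equal(h1, h2)


def test_training_set_validates_shapes(small_phantom):
    vol, mask = small_phantom
    import numpy as np

    from fetalgan import BinaryMask

    bad_mask = BinaryMask(np.zeros((4, 4, 4), dtype=bool))
    with pytest.raises(ValueError, match="mismatch"):
        TrainingSet([(vol, bad_mask, "s0")])


def test_invalid_train_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(k_folds=1)
    with pytest.raises(ValueError):
        TrainConfig(threshold=0.0)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
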