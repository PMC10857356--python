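"""Network contracts, Dice-loss closed forms, and the training loop."""

import numpy as np
import pytest
from dataclasses import replace

from crescentseg.phantom import HUParams, desk_spec, generate_cohort
from crescentseg.unet_core import (
    ModelConfig,
    TrainConfig,
    UNet,
    _dice_loss_and_grad,
    build_unet,
    dice_loss,
    load_checkpoint,
    save_checkpoint,
    train,
)


class TestModel:
    def test_softmax_channels_sum_to_one(self, rng):
        net = build_unet(ModelConfig(in_channels=1, depth=2, base_filters=8), seed=0)
        out = net.forward(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        assert out.shape == (1, 2, 64, 64)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert out.min() >= 0

    def test_five_channel_input(self, rng):
        net = build_unet(ModelConfig(in_channels=5, depth=2, base_filters=4), seed=0)
        out = net(rng.standard_normal((5, 16, 16)))
        assert out.shape == (16, 16)

    def test_seeded_init_is_reproducible(self):
        cfg = ModelConfig(in_channels=3, depth=2, base_filters=4)
        assert build_unet(cfg, seed=5).checksum() == build_unet(cfg, seed=5).checksum()
        assert build_unet(cfg, seed=5).checksum() != build_unet(cfg, seed=6).checksum()

    def test_indivisible_input_side_rejected(self, rng):
        net = build_unet(ModelConfig(in_channels=1, depth=3, base_filters=4), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(rng.standard_normal((1, 1, 20, 20)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(in_channels=2).validate()
        with pytest.raises(ValueError):
            ModelConfig(depth=1).validate()
        with pytest.raises(NotImplementedError):
            ModelConfig(encoder="efficientnet-b4").validate()


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        t = (rng.random((10, 10)) < 0.4).astype(float)
        for smooth in (0.5, 1.0, 10.0):
            assert dice_loss(t, t, smooth) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_prediction_closed_form(self):
        t = np.zeros((20, 20))
        t.ravel()[:100] = 1.0
        assert dice_loss(np.zeros_like(t), t, smooth=1.0) == pytest.approx(1 - 1 / 101)

    def test_half_probability_closed_form(self):
        # uniform 0.5 on an all-ones 4x4 target: 1 - (2*8+1)/(8+16+1)
        pred = np.full((4, 4), 0.5)
        target = np.ones((4, 4))
        assert dice_loss(pred, target, smooth=1.0) == pytest.approx(1 - 17 / 25)

    def test_monotone_in_true_positive_mass(self, rng):
        target = np.zeros((8, 8))
        target[2:6, 2:6] = 1
        base = np.full((8, 8), 0.3)
        better = base.copy()
        better[3, 3] = 0.9  # raise a true-positive pixel only
        # keep totals comparable: loss must not increase
        assert dice_loss(better, target) <= dice_loss(base, target)

    def test_bounds_and_errors(self, rng):
        p = rng.random((6, 6))
        t = (rng.random((6, 6)) < 0.5).astype(float)
        assert 0.0 <= dice_loss(p, t) < 1.0
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="smooth"):
            dice_loss(p, t, smooth=0.0)

    def test_training_gradient_matches_finite_differences(self, rng):
        probs = rng.random((2, 2, 5, 5))
        probs = probs / probs.sum(axis=1, keepdims=True)
        t = (rng.random((2, 5, 5)) < 0.3).astype(float)
        loss, grad = _dice_loss_and_grad(probs, t, smooth=1.0)
        eps = 1e-6
        for idx in [(0, 1, 2, 2), (1, 1, 0, 4)]:
            probs[idx] += eps
            lp, _ = _dice_loss_and_grad(probs, t, smooth=1.0)
            probs[idx] -= eps
            assert (lp - loss) / eps == pytest.approx(grad[idx], rel=1e-3, abs=1e-9)


@pytest.fixture(scope="module")
def micro_cohort():
    spec = desk_spec(
        32, 4, hu_params=HUParams(brain_sd=0, skull_sd=0, collection_sd=0), noise_sd=0.0
    )
    return generate_cohort(3, None, base_spec=spec, seed=21)


class TestTrain:
    def test_lr_follows_exponential_schedule(self, micro_cohort):
        tcfg = TrainConfig(epochs=3, batch_size=4, seed=0, crop_fraction=1.0)
        net = build_unet(ModelConfig(in_channels=1, depth=2, base_filters=4), seed=0)
        _, hist = train(net, micro_cohort, tcfg)
        for e, rec in enumerate(hist):
            assert rec["lr"] == pytest.approx(tcfg.learning_rate * 0.96**e)

    def test_loss_decreases_on_noiseless_phantoms(self, micro_cohort):
        tcfg = TrainConfig(
            learning_rate=1e-3, lr_gamma=0.9, epochs=5, batch_size=4, seed=1,
            crop_fraction=1.0, augment_p=0.0, window=(0.0, 100.0),
            empty_slice_fraction=0.25,
        )
        net = build_unet(ModelConfig(in_channels=3, depth=2, base_filters=4), seed=1)
        _, hist = train(net, micro_cohort, tcfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_identical_seeds_give_identical_history(self, micro_cohort):
        tcfg = TrainConfig(epochs=2, batch_size=4, seed=12, crop_fraction=1.0)
        runs = []
        for _ in range(2):
            net = build_unet(ModelConfig(in_channels=1, depth=2, base_filters=4), seed=12)
            _, hist = train(net, micro_cohort, tcfg)
            runs.append([rec["train_loss"] for rec in hist])
        assert runs[0] == runs[1]

    def test_preconditions(self, micro_cohort):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0).validate()
        net = build_unet(ModelConfig(in_channels=1, depth=2, base_filters=4), seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            train(net, [], TrainConfig(epochs=1))
        with pytest.raises(ValueError, match="does not match"):
            train(net, micro_cohort, TrainConfig(epochs=1), k=3)


def test_checkpoint_round_trip(tmp_path, micro_cohort, rng):
    net = build_unet(ModelConfig(in_channels=3, depth=2, base_filters=4), seed=4)
    path = tmp_path / "model.npz"
    save_checkpoint(net, path, seed=4)
    back, meta = load_checkpoint(path)
    assert meta["seed"] == 4
    x = rng.standard_normal((3, 32, 32))
    np.testing.assert_array_equal(back(x), net(x))
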