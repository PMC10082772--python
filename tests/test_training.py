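"""Training loop: augmentations, masked loss, scheduler, determinism."""

import numpy as np
import pytest

from octdenoise.network import NetSpec, build_unet
from octdenoise.training import (PlateauScheduler, TrainConfig, augment,
                                 desk_profile, masked_mse, sample_patch,
                                 train_model, validate)


@pytest.fixture
def tiny_config():
    return desk_profile(epochs=2, steps_per_epoch=3, batch_size=2,
                        patch_size=(32, 32), seed=0)


class TestAugment:
    def test_unchanged_fraction_is_one_quarter(self):
        """Each range bound moves only inward, so the whole image survives
        untouched in ~25% of draws."""
        rng = np.random.default_rng(0)
        cfg = desk_profile(flip_prob=0.0)
        patch = np.linspace(0, 1, 64).reshape(8, 8)
        unchanged = sum(
            np.array_equal(augment(patch, rng, cfg), patch)
            for _ in range(10_000))
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert unchanged / 10_000 == pytest.approx(0.25, abs=3 * se)

    def test_linear_remap_arithmetic(self, monkeypatch):
        """delta_lo = 0.2, delta_hi = -0.1 remaps [0,1] to [0.2, 0.9]."""
        cfg = desk_profile(flip_prob=0.0)

        class FakeRng:
            def __init__(self):
                self.draws = iter([0.2, -0.1])

            def random(self):
                return 1.0

            def normal(self, mu, sigma):
                return next(self.draws)

        patch = np.array([[0.0, 0.5, 1.0]])
        out = augment(patch, FakeRng(), cfg)
        np.testing.assert_allclose(out, [[0.2, 0.55, 0.9]])

    def test_forced_flip_is_an_involution(self):
        cfg = desk_profile(flip_prob=1.0, jitter_sigma=0.0)
        rng = np.random.default_rng(1)
        patch = np.random.default_rng(2).random((16, 16))
        twice = augment(augment(patch, rng, cfg), rng, cfg)
        np.testing.assert_allclose(twice, patch)

    def test_flip_reverses_lateral_axis(self):
        cfg = desk_profile(flip_prob=1.0, jitter_sigma=0.0)
        patch = np.arange(12.0).reshape(3, 4) / 12.0
        out = augment(patch, np.random.default_rng(0), cfg)
        np.testing.assert_allclose(out, patch[:, ::-1])


class TestMaskedMSE:
    def test_identity_gives_zero(self, rng):
        x = rng.random((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = True
        assert masked_mse(x, x, mask) == 0.0

    def test_hand_case(self):
        pred = np.zeros((2, 2))
        target = np.array([[1.0, 0.0], [3.0, 0.0]])
        mask = np.array([[True, False], [True, False]])
        assert masked_mse(pred, target, mask) == pytest.approx(5.0)

    def test_matches_bruteforce_loop(self, rng):
        pred, target = rng.random((16, 16)), rng.random((16, 16))
        mask = rng.random((16, 16)) < 0.2
        mask[0, 0] = True
        acc = [(pred[r, c] - target[r, c]) ** 2
               for r in range(16) for c in range(16) if mask[r, c]]
        assert masked_mse(pred, target, mask) == pytest.approx(np.mean(acc))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            masked_mse(rng.random((4, 4)), rng.random((4, 4)),
                       np.zeros((4, 4), dtype=bool))


class TestScheduler:
    def test_flat_sequence_triggers_exactly_one_halving(self):
        """A scripted flat validation loss halves the rate exactly once after
        the tenth plateau epoch."""
        sched = PlateauScheduler(1e-3, patience=10, factor=0.5)
        lrs = [sched.step(1.0)]           # sets the best
        lrs += [sched.step(1.0) for _ in range(10)]
        assert lrs[:-1] == [1e-3] * 10
        assert lrs[-1] == pytest.approx(5e-4)

    def test_improvement_resets_the_counter(self):
        sched = PlateauScheduler(1e-3, patience=3)
        for loss in [1.0, 1.0, 1.0, 0.9, 1.0, 1.0]:
            lr = sched.step(loss)
        assert lr == 1e-3
        assert sched.step(1.0) == pytest.approx(5e-4)

    def test_lr_never_below_floor(self):
        sched = PlateauScheduler(1e-3, patience=1, factor=0.5, floor=1e-4)
        for _ in range(40):
            lr = sched.step(1.0)
        assert lr == pytest.approx(1e-4)

    def test_lr_sequence_nonincreasing_with_fixed_ratio(self):
        sched = PlateauScheduler(8e-4, patience=2, factor=0.5)
        lrs = [sched.step(1.0) for _ in range(12)]
        distinct = sorted(set(lrs), reverse=True)
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        for a, b in zip(distinct, distinct[1:]):
            assert b / a == pytest.approx(0.5)


class TestTrainLoop:
    def test_zero_epochs_returns_initial_weights(self, rng):
        model = build_unet(NetSpec(n=2, seed=3))
        before = model.head.params["W"].copy()
        cfg = desk_profile(epochs=0, seed=0)
        trained = train_model(model, [rng.random((64, 64))], [], cfg)
        assert len(trained.history) == 0
        np.testing.assert_array_equal(trained.model.head.params["W"], before)

    def test_training_is_deterministic(self, rng):
        imgs = [rng.random((48, 48)) for _ in range(3)]
        cfg = desk_profile(epochs=2, steps_per_epoch=3, batch_size=2,
                          patch_size=(32, 32), seed=5)
        runs = []
        for _ in range(2):
            model = build_unet(NetSpec(n=2, seed=5))
            runs.append(train_model(model, imgs[:2], imgs[2:], cfg))
        assert runs[0].history.equals(runs[1].history)
        np.testing.assert_array_equal(runs[0].model.head.params["W"],
                                      runs[1].model.head.params["W"])

    def test_patch_larger_than_image_rejected(self, rng, tiny_config):
        model = build_unet(NetSpec(n=2))
        with pytest.raises(ValueError):
            train_model(model, [rng.random((16, 16))], [rng.random((16, 16))],
                        tiny_config)

    def test_history_records_losses_and_lr(self, rng, tiny_config):
        model = build_unet(NetSpec(n=2, seed=1))
        imgs = [rng.random((48, 48)) for _ in range(3)]
        trained = train_model(model, imgs[:2], imgs[2:], tiny_config)
        assert list(trained.history.columns) == ["epoch", "train_loss",
                                                 "val_loss", "lr"]
        assert len(trained.history) == 2
        assert (trained.history["lr"] > 0).all()
        assert trained.best_epoch in (1, 2)


class TestValidate:
    def test_validation_is_deterministic(self, rng):
        model = build_unet(NetSpec(n=2, seed=2))
        cfg = desk_profile(patch_size=(32, 32))
        imgs = [rng.random((64, 64))]
        a = validate(model, imgs, cfg, fixed_seed=9)
        b = validate(model, imgs, cfg, fixed_seed=9)
        assert a == b

    def test_identity_model_loss_equals_replacement_discrepancy(self, rng):
        """A model that returns its input scores the mean squared difference
        between replaced and original center values, computable by brute force
        from the plans."""
        from octdenoise.masking import apply_mask, build_mask_plan

        class Identity:
            def forward(self, x, train=False):
                return x

        cfg = desk_profile(patch_size=(32, 32))
        img = rng.random((64, 64))
        mask_rng = np.random.default_rng(9)
        sq, cnt = 0.0, 0
        for r in range(0, 33, 32):
            for c in range(0, 33, 32):
                patch = img[r:r + 32, c:c + 32]
                plan = build_mask_plan((32, 32), cfg.mask, mask_rng)
                if len(plan.centers) == 0:
                    continue
                masked = apply_mask(patch, plan)
                d = masked[plan.loss_mask] - patch[plan.loss_mask]
                sq += float((d * d).sum())
                cnt += d.size
        expected = sq / cnt
        got = validate(Identity(), [img], cfg, fixed_seed=9)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_empty_validation_set_rejected(self):
        with pytest.raises(ValueError):
            validate(build_unet(NetSpec(n=2)), [], desk_profile(), 0)
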