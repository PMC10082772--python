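"""Layer-level checks of the CPU network engine against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octdenoise.nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d,
                           MaxPool2d, ReLU)


def numeric_grad(fn, x, g, eps=1e-3):
    """Central finite differences of sum(fn(x) * g) w.r.t. a few entries."""
    rng = np.random.default_rng(0)
    out = {}
    for _ in range(6):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        out[idx] = float(((fn(xp) - fn(xm)) * g).sum()) / (2 * eps)
    return out


class TestConv2d:
    def test_forward_matches_scipy_correlate(self, rng):
        from scipy.ndimage import correlate
        conv = Conv2d(2, 3, 3, rng=rng)
        x = rng.standard_normal((1, 2, 9, 11)).astype(np.float32)
        y = conv.forward(x)
        for o in range(3):
            ref = sum(correlate(x[0, c].astype(float),
                                conv.params["W"][o, c].astype(float),
                                mode="constant") for c in range(2))
            np.testing.assert_allclose(y[0, o], ref + conv.params["b"][o],
                                       atol=1e-5)

    def test_input_gradient_matches_bruteforce(self, rng):
        conv = Conv2d(2, 2, 3, rng=rng)
        x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        g = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        conv.forward(x, train=True)
        dx = conv.backward(g)
        W = conv.params["W"]
        for n, ci, h, w in [(0, 0, 2, 3), (0, 1, 0, 0), (0, 1, 5, 5)]:
            s = sum(g[n, o, h - (i - 1), w - (j - 1)] * W[o, ci, i, j]
                    for o in range(2) for i in range(3) for j in range(3)
                    if 0 <= h - (i - 1) < 6 and 0 <= w - (j - 1) < 6)
            assert dx[n, ci, h, w] == pytest.approx(s, abs=1e-5)

    def test_weight_gradient_matches_bruteforce(self, rng):
        conv = Conv2d(1, 2, 3, rng=rng)
        x = rng.standard_normal((2, 1, 5, 5)).astype(np.float32)
        g = rng.standard_normal((2, 2, 5, 5)).astype(np.float32)
        conv.zero_grad()
        conv.forward(x, train=True)
        conv.backward(g)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for o in range(2):
            for i in range(3):
                for j in range(3):
                    ref = float((g[:, o] * xp[:, 0, i:i + 5, j:j + 5]).sum())
                    assert conv.grads["W"][o, 0, i, j] == pytest.approx(
                        ref, abs=1e-4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            Conv2d(1, 1, 2)


class TestConvTranspose2d:
    def test_forward_places_blocks(self, rng):
        up = ConvTranspose2d(1, 1, rng=rng)
        x = np.zeros((1, 1, 2, 2), dtype=np.float32)
        x[0, 0, 0, 1] = 1.0
        y = up.forward(x)
        expected = np.zeros((1, 1, 4, 4), dtype=np.float32)
        expected[0, 0, 0:2, 2:4] = up.params["W"][0, 0]
        np.testing.assert_allclose(y, expected, atol=1e-7)

    def test_gradients_match_finite_difference(self, rng):
        up = ConvTranspose2d(2, 3, rng=rng)
        x = rng.standard_normal((1, 2, 3, 3)).astype(np.float32)
        g = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        up.zero_grad()
        up.forward(x, train=True)
        dx = up.backward(g)
        for idx, num in numeric_grad(
                lambda xx: up._apply(xx.astype(np.float32), up.params["W"],
                                     up.params["b"]), x, g).items():
            assert dx[idx] == pytest.approx(num, rel=2e-2, abs=2e-3)


class TestPoolAndReLU:
    def test_maxpool_selects_window_maxima(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        y = MaxPool2d().forward(x)
        np.testing.assert_array_equal(y[0, 0], [[5, 7], [13, 15]])

    def test_maxpool_routes_gradient_to_argmax(self):
        pool = MaxPool2d()
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        pool.forward(x, train=True)
        g = np.ones((1, 1, 2, 2), dtype=np.float32)
        dx = pool.backward(g)
        expected = np.zeros((4, 4))
        for r, c in [(1, 1), (1, 3), (3, 1), (3, 3)]:
            expected[r, c] = 1.0
        np.testing.assert_array_equal(dx[0, 0], expected)

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            MaxPool2d().forward(np.zeros((1, 1, 5, 4), dtype=np.float32))

    def test_relu_gradient_gates_negatives(self, rng):
        relu = ReLU()
        x = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        relu.forward(x, train=True)
        dx = relu.backward(np.ones_like(x))
        np.testing.assert_array_equal(dx, (x > 0).astype(np.float32))


class TestBatchNorm:
    def test_train_forward_normalizes(self, rng):
        bn = BatchNorm2d(3)
        x = (rng.standard_normal((4, 3, 8, 8)) * 5 + 2).astype(np.float32)
        y = bn.forward(x, train=True)
        assert y.mean(axis=(0, 2, 3)) == pytest.approx(np.zeros(3), abs=1e-5)
        assert y.std(axis=(0, 2, 3)) == pytest.approx(np.ones(3), abs=1e-3)

    def test_eval_uses_running_statistics(self, rng):
        bn = BatchNorm2d(2)
        x = (rng.standard_normal((8, 2, 4, 4)) + 1).astype(np.float32)
        for _ in range(200):
            bn.forward(x, train=True)
        y = bn.forward(x, train=False)
        z = bn.forward(x, train=True)
        np.testing.assert_allclose(y, z, atol=1e-2)

    def test_fold_reproduces_eval_forward(self, rng):
        bn = BatchNorm2d(2)
        bn.buffers["running_mean"][:] = [0.3, -0.2]
        bn.buffers["running_var"][:] = [1.5, 0.7]
        bn.params["gamma"][:] = [2.0, 0.5]
        bn.params["beta"][:] = [0.1, -0.4]
        x = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        scale, shift = bn.fold()
        expected = x * scale[None, :, None, None] + shift[None, :, None, None]
        np.testing.assert_allclose(bn.forward(x, train=False), expected,
                                   atol=1e-6)

    def test_train_gradient_matches_finite_difference(self, rng):
        bn = BatchNorm2d(2)
        x = rng.standard_normal((3, 2, 4, 4)).astype(np.float64)
        g = rng.standard_normal((3, 2, 4, 4)).astype(np.float32)
        bn.forward(x.astype(np.float32), train=True)
        dx = bn.backward(g)
        for idx, num in numeric_grad(
                lambda xx: bn.forward(xx.astype(np.float32), train=True),
                x, g, eps=1e-3).items():
            assert dx[idx] == pytest.approx(num, rel=5e-2, abs=5e-3)


class TestAdam:
    def test_single_step_matches_reference_formula(self):
        conv = Conv2d(1, 1, 1, rng=np.random.default_rng(0))
        conv.params["W"][...] = 1.0
        conv.grads["W"][...] = 0.5
        conv.grads["b"][...] = 0.0
        opt = Adam([conv], lr=0.1)
        opt.step()
        # first step: m_hat = g, v_hat = g^2 -> update = lr * g/(|g|+eps)
        assert conv.params["W"][0, 0, 0, 0] == pytest.approx(0.9, abs=1e-6)

    def test_descends_a_quadratic(self, rng):
        conv = Conv2d(1, 1, 1, rng=rng)
        target = 3.0
        opt = Adam([conv], lr=0.05)
        x = np.ones((1, 1, 2, 2), dtype=np.float32)
        for _ in range(400):
            y = conv.forward(x, train=True)
            opt.zero_grad()
            conv.backward(2 * (y - target) / y.size)
            opt.step()
        assert float(conv.forward(x).mean()) == pytest.approx(3.0, abs=1e-2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_masking_complement_untouched_property(seed):
    """For any seed, pixels outside the replaced strips are bit-identical."""
    from octdenoise.masking import MaskConfig, apply_mask, build_mask_plan
    rng = np.random.default_rng(seed)
    patch = rng.random((48, 48))
    plan = build_mask_plan((48, 48), MaskConfig(center_fraction=0.02), rng)
    out = apply_mask(patch, plan)
    touched = np.zeros((48, 48), dtype=bool)
    for strip in plan.strips():
        touched[strip[:, 0], strip[:, 1]] = True
    assert np.array_equal(out[~touched], patch[~touched])
    assert plan.loss_mask.sum() == len(plan.centers)
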