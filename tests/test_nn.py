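"""Engine-level checks: gradients against finite differences, the partial
convolution against a dense-convolution oracle, pooling and Adam."""

import numpy as np
import pytest

from scattergap.nn import Adam, Conv2d, Tensor
from scattergap.nn import functional as F
from scattergap.nn.tensor import _conv_raw


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def dense_conv_oracle(x, W, b, dilation=1):
    """Direct nested-loop 'same' zero-padded convolution."""
    N, C, H, Wd = x.shape
    O, _, kh, kw = W.shape
    y = np.zeros((N, O, H, Wd))
    for n in range(N):
        for o in range(O):
            for h in range(H):
                for w in range(Wd):
                    acc = b[o]
                    for c in range(C):
                        for i in range(kh):
                            for j in range(kw):
                                hh = h + (i - kh // 2) * dilation
                                ww = w + (j - kw // 2) * dilation
                                if 0 <= hh < H and 0 <= ww < Wd:
                                    acc += W[o, c, i, j] * x[n, c, hh, ww]
                    y[n, o, h, w] = acc
    return y


class TestConvolution:
    @pytest.mark.parametrize("dilation", [1, 2, 3])
    def test_forward_matches_dense_oracle(self, rng, dilation):
        x = rng.normal(size=(2, 3, 7, 6))
        W = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        got = _conv_raw(x, W, b, dilation)
        np.testing.assert_allclose(got, dense_conv_oracle(x, W, b, dilation), atol=1e-12)

    @pytest.mark.parametrize("op_name", ["x", "W", "b"])
    def test_gradients_match_finite_differences(self, rng, op_name):
        x = rng.normal(size=(2, 2, 5, 4))
        W = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        tgt = rng.normal(size=(2, 3, 5, 4))

        def run():
            return F.l1_loss(F.conv2d(Tensor(x), Tensor(W), Tensor(b), 2), tgt).data

        tx, tw, tb = Tensor(x, True), Tensor(W, True), Tensor(b, True)
        F.l1_loss(F.conv2d(tx, tw, tb, 2), tgt).backward()
        grads = {"x": (tx.grad, x), "W": (tw.grad, W), "b": (tb.grad, b)}
        got, arr = grads[op_name]
        np.testing.assert_allclose(got, numerical_grad(run, arr), atol=1e-7)


class TestPartialConv:
    def test_full_mask_reduces_to_standard_convolution(self, rng):
        for _ in range(100):
            x = rng.normal(size=(1, 2, 6, 5))
            m = np.ones((1, 1, 6, 5))
            W = rng.normal(size=(3, 2, 3, 3))
            b = rng.normal(size=3)
            y, m2 = F.partial_conv2d(Tensor(x), m, Tensor(W), Tensor(b))
            np.testing.assert_allclose(y.data, dense_conv_oracle(x, W, b), atol=1e-10)
            assert np.all(m2 == 1)

    def test_empty_window_outputs_zero_and_stays_invalid(self, rng):
        x = rng.normal(size=(1, 1, 8, 8))
        m = np.zeros((1, 1, 8, 8))
        m[0, 0, :2, :2] = 1
        W = rng.normal(size=(1, 1, 3, 3))
        b = Tensor(np.zeros(1))
        y, m2 = F.partial_conv2d(Tensor(x), m, Tensor(W), b)
        assert np.all(y.data[0, 0, 5:, 5:] == 0)
        assert np.all(m2[0, 0, 5:, 5:] == 0)
        assert np.all(m2[0, 0, :3, :3] == 1)

    def test_three_valid_cells_renormalization(self):
        # 3x3 patch, kernel all 1/9, x all 1, 3 valid cells:
        # y = (3/9) * (9/3) = 1 at the center
        x = np.ones((1, 1, 3, 3))
        m = np.zeros((1, 1, 3, 3))
        m[0, 0, 0, :] = 1  # three valid cells in the top row
        W = np.full((1, 1, 3, 3), 1 / 9)
        y, m2 = F.partial_conv2d(Tensor(x), m, Tensor(W), Tensor(np.zeros(1)))
        assert y.data[0, 0, 1, 1] == pytest.approx(1.0)
        assert m2[0, 0, 1, 1] == 1

    def test_valid_region_grows_monotonically(self, rng):
        x = rng.normal(size=(1, 1, 16, 16))
        m = np.zeros((1, 1, 16, 16))
        m[0, 0, :, :3] = 1
        W = Tensor(rng.normal(size=(1, 1, 3, 3)))
        b = Tensor(np.zeros(1))
        t = Tensor(x)
        prev = m
        for _ in range(6):
            t, new = F.partial_conv2d(t, prev, W, b)
            assert np.all(new >= prev)
            prev = new
        assert prev.sum() > m.sum()

    def test_non_binary_mask_rejected(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 4, 4)))
        with pytest.raises(ValueError, match="binary"):
            F.partial_conv2d(x, np.full((1, 1, 4, 4), 0.5), Tensor(rng.normal(size=(1, 1, 3, 3))), Tensor(np.zeros(1)))

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.normal(size=(1, 2, 5, 4))
        m = (rng.random((1, 1, 5, 4)) > 0.4).astype(float)
        W = rng.normal(size=(2, 2, 3, 3))
        b = rng.normal(size=2)
        tgt = rng.normal(size=(1, 2, 5, 4))

        def run():
            y, _ = F.partial_conv2d(Tensor(x), m, Tensor(W), Tensor(b))
            return F.l1_loss(y, tgt).data

        tx, tw = Tensor(x, True), Tensor(W, True)
        y, _ = F.partial_conv2d(tx, m, tw, Tensor(b, True))
        F.l1_loss(y, tgt).backward()
        np.testing.assert_allclose(tx.grad, numerical_grad(run, x), atol=1e-7)
        np.testing.assert_allclose(tw.grad, numerical_grad(run, W), atol=1e-7)


class TestPoolingAndUpsampling:
    def test_maxpool_forward_and_backward(self, rng):
        x = rng.normal(size=(1, 1, 4, 4))
        tx = Tensor(x, True)
        y = F.maxpool2x2(tx)
        assert y.data.shape == (1, 1, 2, 2)
        assert y.data[0, 0, 0, 0] == x[0, 0, :2, :2].max()
        y.backward(np.ones_like(y.data))
        # gradient lands only on the argmax cells, one per block
        assert tx.grad.sum() == 4
        assert np.count_nonzero(tx.grad) == 4

    def test_maxpool_gradcheck(self, rng):
        x = rng.normal(size=(2, 2, 4, 6))
        tgt = rng.normal(size=(2, 2, 2, 3))

        def run():
            return F.l1_loss(F.maxpool2x2(Tensor(x)), tgt).data

        tx = Tensor(x, True)
        F.l1_loss(F.maxpool2x2(tx), tgt).backward()
        np.testing.assert_allclose(tx.grad, numerical_grad(run, x), atol=1e-7)

    def test_transposed_conv_doubles_and_gradchecks(self, rng):
        x = rng.normal(size=(1, 2, 3, 4))
        W = rng.normal(size=(2, 3, 2, 2))
        b = rng.normal(size=3)
        tgt = rng.normal(size=(1, 3, 6, 8))
        y = F.conv_transpose2x2(Tensor(x), Tensor(W), Tensor(b))
        assert y.data.shape == (1, 3, 6, 8)

        def run():
            return F.l1_loss(F.conv_transpose2x2(Tensor(x), Tensor(W), Tensor(b)), tgt).data

        tx, tw = Tensor(x, True), Tensor(W, True)
        F.l1_loss(F.conv_transpose2x2(tx, tw, Tensor(b, True)), tgt).backward()
        np.testing.assert_allclose(tx.grad, numerical_grad(run, x), atol=1e-7)
        np.testing.assert_allclose(tw.grad, numerical_grad(run, W), atol=1e-7)


class TestDenseAndLoss:
    def test_linear_and_global_pool_gradcheck(self, rng):
        x = rng.normal(size=(3, 2, 4, 4))
        W = rng.normal(size=(5, 2))
        b = rng.normal(size=5)
        tgt = rng.normal(size=(3, 5))

        def run():
            h = F.global_mean_pool(Tensor(x))
            return F.l1_loss(F.linear(h, Tensor(W), Tensor(b)), tgt).data

        tx, tw = Tensor(x, True), Tensor(W, True)
        F.l1_loss(F.linear(F.global_mean_pool(tx), tw, Tensor(b, True)), tgt).backward()
        np.testing.assert_allclose(tx.grad, numerical_grad(run, x), atol=1e-7)
        np.testing.assert_allclose(tw.grad, numerical_grad(run, W), atol=1e-7)

    def test_weighted_l1_restricts_support(self, rng):
        p = rng.normal(size=(1, 1, 4, 4))
        t = rng.normal(size=(1, 1, 4, 4))
        w = np.zeros((1, 1, 4, 4))
        w[0, 0, 1, 1] = 1.0
        loss = F.l1_loss(Tensor(p), t, w)
        assert loss.data == pytest.approx(abs(p[0, 0, 1, 1] - t[0, 0, 1, 1]))

    def test_concat_routes_gradients(self, rng):
        a = Tensor(rng.normal(size=(1, 2, 3, 3)), True)
        b = Tensor(rng.normal(size=(1, 3, 3, 3)), True)
        y = F.concat([a, b])
        g = rng.normal(size=(1, 5, 3, 3))
        y.backward(g)
        np.testing.assert_array_equal(a.grad, g[:, :2])
        np.testing.assert_array_equal(b.grad, g[:, 2:])


class TestAdam:
    def test_converges_on_a_quadratic(self):
        rng = np.random.default_rng(0)
        p = Tensor(rng.normal(size=(5,)), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            p.zero_grad()
            p.grad = 2 * (p.data - 3.0)
            opt.step()
        np.testing.assert_allclose(p.data, 3.0, atol=1e-3)

    def test_first_step_magnitude_is_lr(self):
        p = Tensor(np.array([10.0]), requires_grad=True)
        opt = Adam([p], lr=0.01)
        p.grad = np.array([42.0])
        opt.step()
        assert p.data[0] == pytest.approx(10.0 - 0.01, rel=1e-6)
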