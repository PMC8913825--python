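"""Autodiff engine checks against independent numerical oracles."""

import numpy as np
import pytest
from scipy import ndimage

from lesionseg.nn import Adam, BatchNorm2d
from lesionseg.nn.tensor import (
    Tensor, conv2d, conv_transpose2d_2x2, maxpool2d_2x2,
    upsample_nearest_2x, global_avg_pool, channel_resize, concat,
)


@pytest.fixture()
def arrs(rng):
    x = rng.random((2, 3, 12, 12)).astype(np.float32)
    return x


class TestConv2d:
    def test_forward_matches_scipy_correlate(self, rng):
        """Replicate-padded conv equals per-channel scipy correlation."""
        x = rng.random((1, 2, 10, 10)).astype(np.float32)
        w = rng.random((3, 2, 3, 3)).astype(np.float32)
        out = conv2d(Tensor(x), Tensor(w)).data
        for f in range(3):
            ref = sum(ndimage.correlate(x[0, c].astype(np.float64),
                                        w[f, c].astype(np.float64),
                                        mode="nearest")
                      for c in range(2))
            np.testing.assert_allclose(out[0, f], ref, rtol=1e-4, atol=1e-4)

    @pytest.mark.parametrize("kernel,dilation", [(3, 1), (1, 1), (3, 2), (3, 6)])
    def test_backward_matches_scatter_reference(self, rng, kernel, dilation):
        """Fast input-gradient (flipped-kernel correlation) equals the
        explicit col2im scatter computed independently."""
        from lesionseg.nn.tensor import _edge_pad_backward
        x = Tensor(rng.random((2, 3, 12, 12)).astype(np.float32),
                   requires_grad=True)
        w = Tensor((rng.random((4, 3, kernel, kernel)) * 0.3).astype(np.float32),
                   requires_grad=True)
        out = conv2d(x, w, dilation=dilation)
        gout = rng.random(out.shape).astype(np.float32)
        out.backward(gout)

        n, c, h, wdt = x.data.shape
        f = 4
        p = dilation * (kernel - 1) // 2
        xp = (np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
              if p else x.data)
        gmat = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(-1, f)
        dcols = (gmat @ w.data.reshape(f, -1)).reshape(n, h, wdt, c, kernel, kernel)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        gp = np.zeros_like(xp)
        for i in range(kernel):
            for j in range(kernel):
                gp[:, :, i * dilation:i * dilation + h,
                   j * dilation:j * dilation + wdt] += dcols[:, :, :, :, i, j]
        ref = _edge_pad_backward(gp, p, p, h, wdt) if p else gp
        np.testing.assert_allclose(x.grad, ref, atol=1e-5)

    def test_weight_gradient_finite_difference(self, rng):
        x = Tensor(rng.random((1, 2, 6, 6)).astype(np.float32))
        w = Tensor(rng.random((1, 2, 3, 3)).astype(np.float32),
                   requires_grad=True)
        out = conv2d(x, w)
        out.backward(np.ones(out.shape, dtype=np.float32))
        eps = 1e-2
        for idx in [(0, 0, 0, 0), (0, 1, 2, 2), (0, 0, 1, 2)]:
            wp, wm = w.data.copy(), w.data.copy()
            wp[idx] += eps
            wm[idx] -= eps
            fd = (conv2d(x, Tensor(wp)).data.sum()
                  - conv2d(x, Tensor(wm)).data.sum()) / (2 * eps)
            assert abs(fd - w.grad[idx]) < 5e-2 * max(1.0, abs(fd))


def test_transposed_conv_doubles_and_inverts_gradient(rng):
    x = Tensor(rng.random((1, 2, 4, 4)).astype(np.float32), requires_grad=True)
    w = Tensor(rng.random((2, 3, 2, 2)).astype(np.float32), requires_grad=True)
    out = conv_transpose2d_2x2(x, w)
    assert out.shape == (1, 3, 8, 8)
    # forward oracle: explicit loop
    ref = np.zeros((1, 3, 8, 8))
    for i in range(2):
        for j in range(2):
            for f in range(3):
                ref[0, f, i::2, j::2] = np.tensordot(
                    x.data[0], w.data[:, f, i, j], axes=(0, 0))
    np.testing.assert_allclose(out.data, ref, rtol=1e-5, atol=1e-6)
    out.backward(np.ones(out.shape, dtype=np.float32))
    # each input pixel feeds 4 output pixels: grad = sum of all taps
    np.testing.assert_allclose(
        x.grad, w.data.sum(axis=(1, 2, 3))[None, :, None, None]
        * np.ones((1, 2, 4, 4)), rtol=1e-5)


def test_maxpool_forward_and_gradient_routing(rng):
    x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
    t = Tensor(x, requires_grad=True)
    out = maxpool2d_2x2(t)
    np.testing.assert_array_equal(out.data[0, 0], [[5, 7], [13, 15]])
    out.backward(np.ones(out.shape, dtype=np.float32))
    expected = np.zeros((4, 4), dtype=np.float32)
    expected[[1, 1, 3, 3], [1, 3, 1, 3]] = 1.0
    np.testing.assert_array_equal(t.grad[0, 0], expected)


def test_upsample_nearest_and_adjoint(rng):
    x = Tensor(rng.random((1, 2, 3, 3)).astype(np.float32), requires_grad=True)
    out = upsample_nearest_2x(x)
    assert out.shape == (1, 2, 6, 6)
    np.testing.assert_array_equal(out.data[0, 0, :2, :2],
                                  np.full((2, 2), x.data[0, 0, 0, 0]))
    out.backward(np.ones(out.shape, dtype=np.float32))
    np.testing.assert_array_equal(x.grad, np.full((1, 2, 3, 3), 4.0))


def test_channel_resize_pad_and_truncate(rng):
    x = Tensor(rng.random((1, 3, 2, 2)).astype(np.float32), requires_grad=True)
    up = channel_resize(x, 5)
    assert up.shape == (1, 5, 2, 2)
    np.testing.assert_array_equal(up.data[:, 3:], 0)
    down = channel_resize(x, 2)
    np.testing.assert_array_equal(down.data, x.data[:, :2])
    down.backward(np.ones(down.shape, dtype=np.float32))
    np.testing.assert_array_equal(x.grad[:, 2], 0)
    np.testing.assert_array_equal(x.grad[:, :2], 1)


def test_batchnorm_normalizes_and_tracks_running_stats(rng):
    bn = BatchNorm2d(3)
    x = Tensor((rng.random((4, 3, 5, 5)) * 7 + 2).astype(np.float32))
    out = bn(x)
    assert abs(out.data.mean()) < 1e-4
    assert abs(out.data.std() - 1.0) < 1e-2
    bn.eval()
    out_eval = bn(x)
    assert out_eval.shape == x.shape


def test_adam_converges_on_quadratic():
    p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([p], lr=0.2)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_concat_splits_gradient(rng):
    a = Tensor(rng.random((1, 2, 3, 3)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.random((1, 4, 3, 3)).astype(np.float32), requires_grad=True)
    out = concat([a, b], axis=1)
    g = rng.random(out.shape).astype(np.float32)
    out.backward(g)
    np.testing.assert_array_equal(a.grad, g[:, :2])
    np.testing.assert_array_equal(b.grad, g[:, 2:])


def test_global_avg_pool_gradient(rng):
    x = Tensor(rng.random((2, 3, 4, 4)).astype(np.float32), requires_grad=True)
    out = global_avg_pool(x)
    np.testing.assert_allclose(out.data, x.data.mean(axis=(2, 3)), rtol=1e-6)
    out.backward(np.ones(out.shape, dtype=np.float32))
    np.testing.assert_allclose(x.grad, np.full(x.shape, 1 / 16), rtol=1e-6)
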