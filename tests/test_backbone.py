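"""Truncated-AlexNet backbone: tap shapes, parameter counts, determinism,
and agreement of the convolution stack with an independent scipy oracle."""

import numpy as np
import pytest
from scipy import signal

from mnattnet.backbone import (TruncatedAlexNet, alexnet_total_params,
                               build_truncated_alexnet)

FULL_ALEXNET_PARAMS = 61_100_840
BACKBONE_PARAMS = 2_469_696


def test_tap_shapes_for_224_input(tiny_model):
    x = np.random.default_rng(0).standard_normal((2, 3, 224, 224)).astype(np.float32)
    m5, m6, last = tiny_model.backbone.forward_features(x)
    assert m5.shape == (2, 256, 13, 13) and m5.tap == "layer5"
    assert m6.shape == (2, 256, 13, 13) and m6.tap == "layer6"
    assert last.shape == (2, 256, 6, 6) and last.tap == "last"


def test_batch_leading_dimension(tiny_model):
    for n in (1, 3):
        x = np.zeros((n, 3, 224, 224), dtype=np.float32)
        taps = tiny_model.backbone.forward_features(x)
        assert all(t.shape[0] == n for t in taps)


def test_wrong_spatial_size_raises_naming_expected_shape(tiny_model):
    with pytest.raises(ValueError, match="224"):
        tiny_model.backbone.forward_features(np.zeros((1, 3, 128, 128),
                                                      dtype=np.float32))


def test_parameter_counts():
    """Closed-form sums: conv stack ~2.47 M vs ~61 M for full AlexNet."""
    net = build_truncated_alexnet(init_seed=0)
    assert net.num_params() == BACKBONE_PARAMS
    assert alexnet_total_params() == FULL_ALEXNET_PARAMS
    assert net.num_params() < alexnet_total_params()


def test_random_init_is_deterministic_given_seed():
    a = build_truncated_alexnet(init_seed=42)
    b = build_truncated_alexnet(init_seed=42)
    x = np.random.default_rng(1).standard_normal((1, 3, 224, 224)).astype(np.float32)
    ta = a.forward_features(x)
    tb = b.forward_features(x)
    for u, v in zip(ta, tb):
        assert np.array_equal(u.values, v.values)


def test_zero_input_zero_bias_gives_zero_features():
    net = build_truncated_alexnet(init_seed=0)
    for conv in net.convs:
        conv.b[...] = 0.0
    _, _, last = net.forward_features(np.zeros((1, 3, 224, 224), dtype=np.float32))
    assert np.all(last.values == 0)


def test_pretrained_without_checkpoint_is_an_explicit_error():
    with pytest.raises(FileNotFoundError, match="checkpoint"):
        build_truncated_alexnet(pretrained=True)


def _scipy_conv(x, W, b, stride, pad):
    """Independent direct-convolution oracle (per channel-pair correlate2d)."""
    n, c_in, h, w = x.shape
    c_out = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    k = W.shape[2]
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    out = np.zeros((n, c_out, ho, wo))
    for ni in range(n):
        for o in range(c_out):
            acc = np.zeros((h + 2 * pad - k + 1, w + 2 * pad - k + 1))
            for i in range(c_in):
                acc += signal.correlate2d(xp[ni, i], W[o, i], mode="valid")
            out[ni, o] = acc[::stride, ::stride][:ho, :wo] + b[o]
    return out


def _scipy_pool(x, k=3, s=2):
    n, c, h, w = x.shape
    ho, wo = (h - k) // s + 1, (w - k) // s + 1
    out = np.zeros((n, c, ho, wo))
    for i in range(ho):
        for j in range(wo):
            out[:, :, i, j] = x[:, :, i * s:i * s + k, j * s:j * s + k].max(axis=(2, 3))
    return out


def test_conv_prefix_matches_direct_convolution_oracle():
    """conv1 -> relu -> pool -> conv2 on one fixed image, checked against a
    naive scipy correlate2d implementation."""
    rng = np.random.default_rng(3)
    net = build_truncated_alexnet(init_seed=3)
    x = rng.standard_normal((1, 3, 63, 63)).astype(np.float32)

    c1, c2 = net.convs[0], net.convs[1]
    ref = _scipy_conv(x.astype(np.float64), c1.W.astype(np.float64),
                      c1.b.astype(np.float64), stride=4, pad=2)
    got = c1.forward(x)
    np.testing.assert_allclose(got, ref, rtol=1e-4, atol=1e-4)

    ref = np.maximum(ref, 0)
    got = net.relus[0].forward(got)
    ref_p = _scipy_pool(ref)
    got_p = net.pool1.forward(got)
    np.testing.assert_allclose(got_p, ref_p, rtol=1e-4, atol=1e-4)

    ref2 = _scipy_conv(ref_p, c2.W.astype(np.float64),
                       c2.b.astype(np.float64), stride=1, pad=2)
    got2 = c2.forward(got_p.astype(np.float32))
    np.testing.assert_allclose(got2, ref2, rtol=1e-3, atol=1e-3)


class TestGradients:
    """Finite-difference checks of the hand-written backward passes."""

    @staticmethod
    def _numeric_grad(f, x, eps=1e-3):
        g = np.zeros_like(x, dtype=np.float64)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = x[idx]
            x[idx] = orig + eps
            fp = f()
            x[idx] = orig - eps
            fm = f()
            x[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
        return g

    def test_conv2d_backward(self):
        from mnattnet.nn import Conv2d
        rng = np.random.default_rng(0)
        conv = Conv2d(2, 3, 3, stride=2, pad=1, rng=rng)
        x = rng.standard_normal((2, 2, 7, 7)).astype(np.float32)
        gy = rng.standard_normal((2, 3, 4, 4)).astype(np.float32)

        def loss():
            return float((conv.forward(x.copy()) * gy).sum())

        loss()
        conv.zero_grad()
        gx = conv.backward(gy)
        np.testing.assert_allclose(gx, self._numeric_grad(loss, x),
                                   rtol=1e-2, atol=1e-3)
        np.testing.assert_allclose(conv.gW, self._numeric_grad(loss, conv.W),
                                   rtol=1e-2, atol=1e-3)

    def test_maxpool_backward(self):
        from mnattnet.nn import MaxPool2d
        rng = np.random.default_rng(1)
        pool = MaxPool2d(3, 2)
        x = rng.standard_normal((1, 2, 7, 7)).astype(np.float32)
        gy = rng.standard_normal((1, 2, 3, 3)).astype(np.float32)

        def loss():
            return float((pool.forward(x.copy()) * gy).sum())

        loss()
        gx = pool.backward(gy)
        np.testing.assert_allclose(gx, self._numeric_grad(loss, x),
                                   rtol=1e-2, atol=1e-3)

    def test_bilinear_backward_is_exact_transpose(self):
        from mnattnet.nn import BilinearUpsample
        up = BilinearUpsample((6, 6), (13, 13))
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 1, 6, 6)).astype(np.float32)
        gy = rng.standard_normal((1, 1, 13, 13)).astype(np.float32)
        up.forward(x)
        gx = up.backward(gy)
        # the map is linear: <up(x), gy> == <x, up^T(gy)> identically
        lhs = float((up.forward(x) * gy).sum())
        rhs = float((x * gx).sum())
        assert abs(lhs - rhs) < 1e-3
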