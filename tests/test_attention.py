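"""Attention-fusion operations against hand-computed and naive-loop oracles."""

import numpy as np
import pytest

from mnattnet.attention import AttentionResult, build_model
from mnattnet.losses import focal_dlogits
from mnattnet.nn import interp_matrix, softmax


@pytest.fixture()
def model():
    return build_model(init_seed=1)


class TestProjectLast:
    def test_identity_kernel_constant_input_stays_constant(self, model):
        model.proj_l.W[...] = np.eye(256, dtype=np.float32)
        model.proj_l.b[...] = 0.0
        L = np.full((1, 256, 6, 6), 3.25, dtype=np.float32)
        F_l = model.project_last(L)
        assert F_l.shape == (1, 256, 13, 13)
        np.testing.assert_allclose(F_l, 3.25, rtol=1e-6)

    def test_zero_kernel_gives_zero(self, model):
        model.proj_l.W[...] = 0.0
        model.proj_l.b[...] = 0.0
        F_l = model.project_last(np.ones((1, 256, 6, 6), dtype=np.float32))
        assert np.all(F_l == 0)

    def test_wrong_shape_raises(self, model):
        with pytest.raises(ValueError, match="256, 6, 6"):
            model.project_last(np.zeros((1, 256, 13, 13), dtype=np.float32))

    def test_bilinear_2x2_to_4x4_matches_hand_computed_weights(self):
        """Half-pixel-centers convention: source coords for a 2->4 upsample
        are (-0.25, 0.25, 0.75, 1.25), clamped; weights computed by hand."""
        m = interp_matrix(2, 4)
        expected = np.array([[1.0, 0.0],
                             [0.75, 0.25],
                             [0.25, 0.75],
                             [0.0, 1.0]], dtype=np.float32)
        np.testing.assert_allclose(m, expected, atol=1e-7)
        x = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)
        up = m @ x @ m.T
        # corners reproduce the source corners under clamping
        assert up[0, 0] == 1.0 and up[3, 3] == 4.0
        # center is the average of the 4 source pixels
        np.testing.assert_allclose(up[1:3, 1:3].mean(), 2.5, atol=1e-6)


class TestProjectMid:
    def test_zero_and_identity_kernels(self, model):
        M = np.random.default_rng(0).standard_normal(
            (1, 256, 13, 13)).astype(np.float32)
        model.branch6.proj_m.W[...] = 0.0
        model.branch6.proj_m.b[...] = 0.0
        assert np.all(model.project_mid(M) == 0)
        model.branch6.proj_m.W[...] = np.eye(256, dtype=np.float32)
        np.testing.assert_allclose(model.project_mid(M), M, rtol=1e-5)

    def test_random_kernel_matches_per_pixel_matrix_product(self):
        """1x1 convolution == independent matrix product at every pixel."""
        from mnattnet.nn import Conv1x1
        rng = np.random.default_rng(5)
        conv = Conv1x1(2, 3, rng)
        x = rng.standard_normal((2, 2, 4, 4)).astype(np.float32)
        got = conv.forward(x)
        for n in range(2):
            for i in range(4):
                for j in range(4):
                    ref = conv.W @ x[n, :, i, j] + conv.b
                    np.testing.assert_allclose(got[n, :, i, j], ref, rtol=1e-5)


class TestAttentionWeights:
    def test_zero_gate_gives_half_everywhere(self, model):
        model.branch6.gate.W[...] = 0.0
        model.branch6.gate.b[...] = 0.0
        F = np.random.default_rng(0).standard_normal(
            (1, 256, 13, 13)).astype(np.float32)
        A = model.attention_weights(F, F)
        assert A.shape == (1, 1, 13, 13)
        np.testing.assert_allclose(A, 0.5, atol=1e-7)

    def test_output_strictly_inside_unit_interval(self, model):
        rng = np.random.default_rng(1)
        A = model.attention_weights(
            rng.standard_normal((2, 256, 13, 13)).astype(np.float32),
            rng.standard_normal((2, 256, 13, 13)).astype(np.float32))
        assert np.all(A > 0) and np.all(A < 1)

    def test_scalar_toy_case_relu_then_sigmoid(self):
        """sum = [[1,-1],[0,2]], identity gate: ReLU zeroes -1, then sigmoid
        gives [[0.7311, 0.5], [0.5, 0.8808]]."""
        from mnattnet.attention import MNAttentionNet
        from mnattnet.nn import Conv1x1, ReLU, Sigmoid
        gate = Conv1x1(1, 1, np.random.default_rng(0))
        gate.W[...] = 1.0
        gate.b[...] = 0.0
        s = np.array([[[[1.0, -1.0], [0.0, 2.0]]]], dtype=np.float32)
        A = Sigmoid().forward(gate.forward(ReLU().forward(s)))
        np.testing.assert_allclose(
            A[0, 0], [[0.73106, 0.5], [0.5, 0.88080]], atol=1e-4)

    def test_shape_mismatch_raises(self, model):
        with pytest.raises(ValueError, match="mismatch"):
            model.attention_weights(np.zeros((1, 256, 13, 13), np.float32),
                                    np.zeros((1, 256, 6, 6), np.float32))


class TestApplyAttention:
    def test_identity_and_zero_weighting(self, model):
        F = np.random.default_rng(2).standard_normal(
            (1, 256, 13, 13)).astype(np.float32)
        np.testing.assert_array_equal(
            model.apply_attention(np.ones((1, 1, 13, 13), np.float32), F), F)
        assert np.all(model.apply_attention(
            np.zeros((1, 1, 13, 13), np.float32), F) == 0)

    def test_checkerboard_zeroes_exactly_the_zero_cells(self, model):
        F = np.random.default_rng(3).standard_normal(
            (1, 4, 4, 4)).astype(np.float32) + 10.0
        board = np.indices((4, 4)).sum(axis=0) % 2
        A = board[None, None].astype(np.float32)
        out = model.apply_attention(A, F)
        for i in range(4):
            for j in range(4):
                if board[i, j] == 0:
                    assert np.all(out[0, :, i, j] == 0)
                else:
                    np.testing.assert_array_equal(out[0, :, i, j], F[0, :, i, j])

    def test_attention_result_checks_spatial_agreement(self):
        with pytest.raises(ValueError, match="spatial"):
            AttentionResult(np.zeros((1, 1, 13, 13)), np.zeros((1, 256, 6, 6)))


class TestGlobalFeature:
    def test_constant_inputs_give_constant_768_vector(self, model):
        c = 1.5
        F_g = model.global_feature(np.full((2, 256, 13, 13), c, np.float32),
                                   np.full((2, 256, 13, 13), c, np.float32),
                                   np.full((2, 256, 6, 6), c, np.float32))
        assert F_g.shape == (2, 768)
        np.testing.assert_allclose(F_g, c, rtol=1e-6)

    def test_concatenation_order(self, model):
        F_g = model.global_feature(np.zeros((1, 256, 13, 13), np.float32),
                                   np.ones((1, 256, 13, 13), np.float32),
                                   np.full((1, 256, 6, 6), 2.0, np.float32))
        assert np.all(F_g[0, :256] == 0)
        np.testing.assert_allclose(F_g[0, 256:512], 1.0)
        np.testing.assert_allclose(F_g[0, 512:], 2.0)

    def test_blocks_equal_loop_based_spatial_mean(self, model):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((1, 256, 13, 13)).astype(np.float32)
        b = rng.standard_normal((1, 256, 13, 13)).astype(np.float32)
        l = rng.standard_normal((1, 256, 6, 6)).astype(np.float32)
        F_g = model.global_feature(a, b, l)
        for c in range(0, 256, 37):
            assert abs(F_g[0, c] - sum(a[0, c, i, j] for i in range(13)
                                       for j in range(13)) / 169) < 1e-4
            assert abs(F_g[0, 512 + c] - sum(l[0, c, i, j] for i in range(6)
                                             for j in range(6)) / 36) < 1e-4

    def test_channel_mismatch_raises(self, model):
        with pytest.raises(ValueError, match="256 channels"):
            model.global_feature(np.zeros((1, 128, 13, 13), np.float32),
                                 np.zeros((1, 256, 13, 13), np.float32),
                                 np.zeros((1, 256, 6, 6), np.float32))


class TestClassify:
    def test_probabilities_sum_to_one(self, model):
        p = model.classify(np.random.default_rng(0)
                           .standard_normal((5, 768)).astype(np.float32))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-6)

    def test_zero_weights_give_uniform(self, model):
        model.fc.W[...] = 0.0
        model.fc.b[...] = 0.0
        np.testing.assert_allclose(
            model.classify(np.ones((1, 768), np.float32)), 0.5, atol=1e-7)

    def test_softmax_arithmetic(self):
        np.testing.assert_allclose(softmax(np.array([[2.0, 0.0]]))[0],
                                   [0.88080, 0.11920], atol=1e-4)


class TestEndToEnd:
    def test_forward_is_deterministic(self, tiny_model, small_batch):
        x = tiny_model.preprocess(small_batch[0])
        a = tiny_model.forward(x)
        b = tiny_model.forward(x)
        np.testing.assert_array_equal(a["logits"], b["logits"])
        assert a["F_g"].shape == (4, 768)
        assert a["A5"].shape == (4, 1, 13, 13)
        assert np.all(a["A5"] > 0) and np.all(a["A5"] < 1)

    def test_gradient_reaches_every_parameter(self, small_batch):
        """No layer is frozen: a generic batch sends nonzero gradient to
        every weight tensor in backbone and head."""
        model = build_model(init_seed=3)
        x = model.preprocess(small_batch[0])
        out = model.forward(x)
        model.zero_grad()
        model.backward(focal_dlogits(out["probs"], small_batch[1]), out)
        for name, _, g in model.parameters():
            assert np.abs(g).max() > 0, f"no gradient reached {name}"

    def test_model_has_fewer_parameters_than_alexnet(self, tiny_model):
        from mnattnet.backbone import alexnet_total_params
        assert tiny_model.num_params() < alexnet_total_params()

    def test_whole_model_gradient_matches_finite_differences(self):
        """Directional finite-difference check through the entire network."""
        from mnattnet.losses import focal_loss
        model = build_model(init_seed=9)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3, 224, 224)).astype(np.float32)
        y = np.array([1, 0])

        def loss_value():
            return focal_loss(model.forward(x)["probs"][:, 1], y)

        out = model.forward(x)
        model.zero_grad()
        model.backward(focal_dlogits(out["probs"], y), out)
        # probe a handful of parameters spread across the network
        rng2 = np.random.default_rng(1)
        checked = 0
        for name, v, g in model.parameters():
            if "b" in name.split(".")[-1]:
                continue
            idx = tuple(rng2.integers(0, s) for s in v.shape)
            eps = 1e-2
            orig = v[idx]
            v[idx] = orig + eps
            fp = loss_value()
            v[idx] = orig - eps
            fm = loss_value()
            v[idx] = orig
            num = (fp - fm) / (2 * eps)
            assert abs(num - g[idx]) < max(5e-3, 0.15 * abs(num) + 1e-4), \
                f"gradient mismatch at {name}{idx}: {num} vs {g[idx]}"
            checked += 1
        assert checked >= 8


def test_checkpoint_round_trip(tmp_path, small_batch):
    from mnattnet.attention import load_checkpoint, save_checkpoint
    model = build_model(init_seed=5)
    x = model.preprocess(small_batch[0])
    before = model.forward(x)["probs"]
    save_checkpoint(tmp_path / "ckpt.npz", model, config={"init_seed": 5})
    loaded, config = load_checkpoint(tmp_path / "ckpt.npz")
    assert config == {"init_seed": 5}
    after = loaded.forward(x)["probs"]
    np.testing.assert_array_equal(before, after)
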