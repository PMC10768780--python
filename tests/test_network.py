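"""Forward primitives against loop oracles, shape arithmetic, and the
analytic-vs-numerical gradient check on a tiny hybrid model."""

import numpy as np
import pytest

import oracles
from nmsite.config import NetworkConfig
from nmsite.network import (
    HybridModel,
    attention,
    bce_loss,
    bce_loss_t,
    bigru_forward,
    cnn_block_forward,
    conv1d_forward,
    conv1d_out_length,
    fuse_and_predict,
    gru_att_block_forward,
    gru_step,
    init_params,
    maxpool1d,
    relu,
)

TINY = NetworkConfig(
    conv_channels=(2, 3, 4), cnn_fc_dim=3, gru_hidden=3, attention_dim=3,
    gru_fc_dim=3, fusion_hidden=4, dropout=0.0,
)


def zero_gru_params(d, H):
    p = {}
    for gate in ("u", "r", "n"):
        p[f"W_i{gate}"] = np.zeros((d, H))
        p[f"U_h{gate}"] = np.zeros((H, H))
        p[f"b_i{gate}"] = np.zeros(H)
        p[f"b_h{gate}"] = np.zeros(H)
    return p


def random_gru_params(rng, d, H):
    p = zero_gru_params(d, H)
    return {k: rng.standard_normal(v.shape) * 0.5 for k, v in p.items()}


class TestShapeArithmetic:
    @pytest.mark.parametrize(
        "args,expected",
        [((41, 0, 1, 3, 1), 39), ((41, 1, 1, 3, 1), 41), ((17, 0, 1, 1, 1), 17),
         ((10, 0, 1, 2, 2), 5), ((41, 2, 2, 3, 1), 41)],
    )
    def test_out_length(self, args, expected):
        assert conv1d_out_length(*args) == expected

    def test_underflow_is_error(self):
        with pytest.raises(ValueError):
            conv1d_out_length(2, 0, 1, 5, 1)


class TestConv:
    def test_hand_example(self):
        out = conv1d_forward(np.array([[1.0, 2, 3]]),
                             np.array([[[1.0, 0]]]), np.zeros(1))
        np.testing.assert_allclose(out, [[1.0, 2.0]])

    def test_zero_weights_constant_bias(self):
        x = np.random.default_rng(0).standard_normal((2, 9))
        out = conv1d_forward(x, np.zeros((3, 2, 3)), np.array([1.0, -2.0, 0.5]))
        np.testing.assert_allclose(out, np.array([1.0, -2.0, 0.5])[:, None]
                                   * np.ones((3, 7)))

    @pytest.mark.parametrize("stride,pad,dilation", [(1, 0, 1), (2, 1, 1), (1, 2, 2)])
    def test_matches_loop_oracle(self, stride, pad, dilation):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((2, 15))
        w = rng.standard_normal((3, 2, 3))
        b = rng.standard_normal(3)
        ours = conv1d_forward(x, w, b, stride=stride, pad=pad, dilation=dilation)
        ref = oracles.conv1d_loop(x, w, b, stride=stride, pad=pad,
                                  dilation=dilation)
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestPoolAndRelu:
    def test_pool_hand_example(self):
        np.testing.assert_allclose(
            maxpool1d(np.array([[1.0, 3, 2, 5]]), 2, 2), [[3.0, 5.0]]
        )

    def test_pool_identity_and_length_formula(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 11))
        np.testing.assert_allclose(maxpool1d(x, 1, 1), x)
        out = maxpool1d(x, 3, 2)
        assert out.shape[1] == conv1d_out_length(11, 0, 1, 3, 2)
        np.testing.assert_allclose(out, oracles.maxpool_loop(x, 3, 2))

    def test_relu(self):
        x = np.array([-2.0, 0.0, 3.0])
        np.testing.assert_allclose(relu(x), [0.0, 0.0, 3.0])
        np.testing.assert_allclose(relu(relu(x)), relu(x))


class TestGru:
    def test_zero_params_halves_hidden_state(self):
        p = zero_gru_params(2, 3)
        h = gru_step(np.zeros(2), np.array([1.0, 2.0, 3.0]), p)
        np.testing.assert_allclose(h, [0.5, 1.0, 1.5])
        h0 = gru_step(np.zeros(2), np.zeros(3), p)
        np.testing.assert_allclose(h0, np.zeros(3))

    def test_matches_loop_oracle_and_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_gru_params(rng, 4, 3)
            x = rng.standard_normal(4)
            h_prev = rng.standard_normal(3)
            ours = gru_step(x, h_prev, p)
            ref = oracles.gru_step_loop(x, h_prev, p)
            np.testing.assert_allclose(ours, ref, atol=1e-10)
            bound = np.maximum(np.abs(h_prev), 1.0)
            assert (np.abs(ours) <= bound + 1e-12).all()


class TestBiGru:
    def test_matches_stepwise_oracle(self):
        rng = np.random.default_rng(4)
        params = {"forward": random_gru_params(rng, 5, 3),
                  "backward": random_gru_params(rng, 5, 3)}
        E = rng.standard_normal((7, 5))
        np.testing.assert_allclose(
            bigru_forward(E, params), oracles.bigru_loop(E, params), atol=1e-6
        )

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        pf = random_gru_params(rng, 5, 3)
        pb = random_gru_params(rng, 5, 3)
        E = rng.standard_normal((7, 5))
        H1 = bigru_forward(E, {"forward": pf, "backward": pb})
        H2 = bigru_forward(E[::-1].copy(), {"forward": pb, "backward": pf})
        swapped = np.concatenate([H2[::-1, 3:], H2[::-1, :3]], axis=1)
        np.testing.assert_allclose(H1, swapped, atol=1e-10)

    def test_zero_params_zero_output_t_preserved(self):
        params = {"forward": zero_gru_params(4, 2),
                  "backward": zero_gru_params(4, 2)}
        E = np.random.default_rng(0).standard_normal((41, 4))
        H = bigru_forward(E, params)
        assert H.shape == (41, 4) and not H.any()


class TestAttention:
    def make_params(self, rng, H2, A):
        return {"W_a": rng.standard_normal((H2, A)),
                "b_a": rng.standard_normal(A),
                "x_a": rng.standard_normal((A, 1))}

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        p = self.make_params(rng, 4, 3)
        H = rng.standard_normal((9, 4))
        c, alpha = attention(H, p)
        c_ref, a_ref = oracles.attention_loop(H, {"W_a": p["W_a"],
                                                  "b_a": p["b_a"],
                                                  "x_a": p["x_a"]})
        np.testing.assert_allclose(alpha, a_ref, atol=1e-10)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)

    def test_singleton_and_uniform(self):
        rng = np.random.default_rng(7)
        p = self.make_params(rng, 4, 3)
        H1 = rng.standard_normal((1, 4))
        c, alpha = attention(H1, p)
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(c, H1[0])
        row = rng.standard_normal(4)
        Hsame = np.tile(row, (6, 1))
        c2, alpha2 = attention(Hsame, p)
        np.testing.assert_allclose(alpha2, np.full(6, 1 / 6), atol=1e-12)
        np.testing.assert_allclose(c2, row, atol=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        p = self.make_params(rng, 6, 4)
        for _ in range(5):
            _, alpha = attention(rng.standard_normal((12, 6)), p)
            assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
            assert (alpha >= 0).all()


class TestBlocksAndFusion:
    def test_cnn_block_zero_weights_yields_fc_bias(self):
        params = init_params({"d": 20}, {}, TINY, seed=0)
        p = params.cnn["d"]
        for key in p:
            if key != "fc_b":
                p[key] = np.zeros_like(p[key])
        p["fc_b"] = np.array([1.0, -1.0, 2.0])
        out = cnn_block_forward(np.random.default_rng(0).standard_normal(20),
                                p, TINY)
        np.testing.assert_allclose(out, [1.0, -1.0, 2.0])

    def test_cnn_block_output_dims(self):
        params = init_params({"BPF": 164, "Kmer": 64}, {}, TINY, seed=0)
        rng = np.random.default_rng(1)
        for name, dim in (("BPF", 164), ("Kmer", 64)):
            out = cnn_block_forward(rng.standard_normal(dim),
                                    params.cnn[name], TINY)
            assert out.shape == (TINY.cnn_fc_dim,)

    def test_gru_att_block_contract(self):
        params = init_params({}, {"e": 5}, TINY, seed=0)
        E = np.random.default_rng(2).standard_normal((41, 5))
        out1, alpha1 = gru_att_block_forward(E, params.gru["e"], TINY)
        out2, alpha2 = gru_att_block_forward(E, params.gru["e"], TINY)
        assert out1.shape == (TINY.gru_fc_dim,)
        np.testing.assert_array_equal(out1, out2)
        assert alpha1.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fusion_sigmoid_properties(self):
        rng = np.random.default_rng(3)
        fused_dim = 2 * 3 + 1 * 3
        params = {
            "hidden_w": np.zeros((fused_dim, 4)), "hidden_b": np.zeros(4),
            "out_w": np.zeros((4, 1)), "out_b": np.array([0.3]),
        }
        reps_c = [rng.standard_normal(3) for _ in range(2)]
        reps_g = [rng.standard_normal(3)]
        p0 = fuse_and_predict(reps_c, reps_g, params)
        np.testing.assert_allclose(p0, 1 / (1 + np.exp(-0.3)))
        probs = []
        for bias in (-2.0, 0.0, 2.0):
            params["out_b"] = np.array([bias])
            probs.append(float(fuse_and_predict(reps_c, reps_g, params)[0]))
        assert probs == sorted(probs)
        assert all(0 < p < 1 for p in probs)


class TestLoss:
    def test_worked_values(self):
        assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2), abs=1e-9)
        assert bce_loss([1.0], [1.0 - 1e-12]) == pytest.approx(0.0, abs=1e-5)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 20).astype(float)
        p = rng.random(20)
        assert bce_loss(y, p) == pytest.approx(bce_loss(1 - y, 1 - p))


class TestInitAndModel:
    def test_init_reproducible_and_shapes(self):
        a = init_params({"d": 30}, {"e": 4}, TINY, seed=11)
        b = init_params({"d": 30}, {"e": 4}, TINY, seed=11)
        c = init_params({"d": 30}, {"e": 4}, TINY, seed=12)
        fa, fb, fc = a.flat(), b.flat(), c.flat()
        assert set(fa) == set(fb) == set(fc)
        for k in fa:
            np.testing.assert_array_equal(fa[k], fb[k])
        assert any(not np.array_equal(fa[k], fc[k]) for k in fa)

    def test_inference_deterministic(self):
        m = HybridModel({"d1": 20, "d2": 16}, {"e1": 5}, TINY, seed=1)
        rng = np.random.default_rng(0)
        d = {"d1": rng.standard_normal((3, 20)), "d2": rng.standard_normal((3, 16))}
        e = {"e1": rng.standard_normal((3, 7, 5))}
        p1 = m.predict_proba(d, e)
        p2 = m.predict_proba(d, e)
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 > 0) & (p1 < 1)).all()

    def test_checkpoint_roundtrip(self, tmp_path):
        m = HybridModel({"d1": 20}, {"e1": 5}, TINY, seed=1, site_type="A")
        path = tmp_path / "ckpt.npz"
        m.save(path)
        back = HybridModel.load(path)
        assert back.site_type == "A"
        fa, fb = m.params.flat(), back.params.flat()
        for k in fa:
            np.testing.assert_array_equal(fa[k], fb[k])
        rng = np.random.default_rng(0)
        d = {"d1": rng.standard_normal((2, 20))}
        e = {"e1": rng.standard_normal((2, 7, 5))}
        np.testing.assert_array_equal(m.predict_proba(d, e),
                                      back.predict_proba(d, e))


def test_gradient_check_tiny_model():
    """Analytic gradients of BCE(forward) agree with central differences to
    1e-4 relative error on a tiny two-descriptor, one-embedding model."""
    from nmsite.network import bce_loss as loss_np

    m = HybridModel({"d1": 18, "d2": 12}, {"e1": 4}, TINY, seed=2)
    rng = np.random.default_rng(0)
    d = {"d1": rng.standard_normal((4, 18)), "d2": rng.standard_normal((4, 12))}
    e = {"e1": rng.standard_normal((4, 6, 4))}
    y = np.array([1.0, 0.0, 1.0, 0.0])
    prob, leaves, _ = m.forward_t(d, e, train=True, rng=None)
    bce_loss_t(y, prob).backward()
    flat = m.params.flat()
    rng2 = np.random.default_rng(1)
    checked = 0
    for name, leaf in leaves.items():
        if leaf.grad is None:
            continue
        arr = flat[name]
        idx = tuple(rng2.integers(0, s) for s in arr.shape) if arr.ndim else ()
        eps = 1e-6
        orig = arr[idx]
        arr[idx] = orig + eps
        p1, _, _ = m.forward_t(d, e)
        l1 = loss_np(y, p1.data)
        arr[idx] = orig - eps
        p2, _, _ = m.forward_t(d, e)
        l2 = loss_np(y, p2.data)
        arr[idx] = orig
        numeric = (l1 - l2) / (2 * eps)
        analytic = leaf.grad[idx]
        denom = max(1e-8, abs(numeric) + abs(analytic))
        assert abs(numeric - analytic) / denom < 1e-4, name
        checked += 1
    assert checked > 50
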