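"""Stage-level oracles, gradient checks, and the estimator contract."""

import numpy as np
import pytest

from bsjnet._nn import softmax_cross_entropy
from bsjnet.model import (
    JunctionClassifier,
    ModelConfig,
    adaptive_max_pool,
    build_network,
    conv_forward,
    cross_entropy,
    fc_forward,
    self_attention,
    softmax_probs,
)
from bsjnet.synthetic_data import generate_separable_embeddings


def literal_self_attention(x, w_q, w_k, w_v):
    """From-scratch per-element expansion of single-head attention:
    Q = X W_Q, K = X W_K, V = X W_V, A_ij = softmax_j(Q_i . K_j / sqrt(Dk)),
    out_i = sum_j A_ij V_j.  Pure loops, independent of the implementation."""
    L, F = x.shape
    d_k = w_q.shape[1]
    Q = np.array([[sum(x[i][a] * w_q[a][b] for a in range(F)) for b in range(d_k)]
                  for i in range(L)])
    K = np.array([[sum(x[i][a] * w_k[a][b] for a in range(F)) for b in range(d_k)]
                  for i in range(L)])
    V = np.array([[sum(x[i][a] * w_v[a][b] for a in range(F)) for b in range(d_k)]
                  for i in range(L)])
    out = np.zeros((L, d_k))
    A = np.zeros((L, L))
    for i in range(L):
        scores = [sum(Q[i][d] * K[j][d] for d in range(d_k)) / np.sqrt(d_k) for j in range(L)]
        e = np.exp(np.array(scores) - max(scores))
        A[i] = e / e.sum()
        for d in range(d_k):
            out[i][d] = sum(A[i][j] * V[j][d] for j in range(L))
    return out, A


class TestSelfAttention:
    def test_single_position_identity_weights_passthrough(self):
        x = np.array([[1.5, -2.0]])
        eye = np.eye(2)
        out, weights = self_attention(x, eye, eye, eye)
        np.testing.assert_allclose(out, x)
        np.testing.assert_allclose(weights, [[1.0]])

    @pytest.mark.parametrize("L", [2, 3, 4])
    def test_matches_literal_oracle(self, L):
        rng = np.random.default_rng(L)
        x = rng.standard_normal((L, 3))
        w_q, w_k, w_v = (rng.standard_normal((3, 3)) for _ in range(3))
        out, weights = self_attention(x, w_q, w_k, w_v)
        oracle_out, oracle_A = literal_self_attention(x, w_q, w_k, w_v)
        np.testing.assert_allclose(out, oracle_out, atol=1e-8)
        np.testing.assert_allclose(weights, oracle_A, atol=1e-8)

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 8))
        w = [rng.standard_normal((8, 8)) for _ in range(3)]
        _, weights = self_attention(x, *w, heads=4)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_multi_head_preserves_shape(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 8))
        w = [rng.standard_normal((8, 8)) for _ in range(3)]
        out, _ = self_attention(x, *w, heads=2)
        assert out.shape == (5, 8)


class TestPoolingAndHead:
    def test_column_maxima_by_hand(self):
        np.testing.assert_array_equal(adaptive_max_pool(np.array([[1, 5], [3, 2]])), [3, 5])

    def test_constant_matrix(self):
        np.testing.assert_array_equal(adaptive_max_pool(np.full((7, 3), 2.5)), [2.5] * 3)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 4))
        np.testing.assert_array_equal(
            adaptive_max_pool(x), adaptive_max_pool(x[rng.permutation(10)])
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adaptive_max_pool(np.empty((0, 3)))

    def test_fc_zero_weights_pass_bias(self):
        z = fc_forward(np.zeros(4), np.zeros((2, 4)), np.array([1.0, -1.0]))
        np.testing.assert_array_equal(z, [1.0, -1.0])

    def test_fc_matches_hand_arithmetic(self):
        w = np.array([[1.0, 2.0], [3.0, -1.0]])
        b = np.array([0.5, -0.5])
        y = np.array([2.0, 1.0])
        np.testing.assert_allclose(fc_forward(y, w, b), [2 + 2 + 0.5, 6 - 1 - 0.5])


class TestSoftmaxAndLoss:
    def test_symmetric_logits(self):
        np.testing.assert_allclose(softmax_probs(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_closed_form_ln3(self):
        np.testing.assert_allclose(
            softmax_probs(np.array([np.log(3), 0.0])), [0.75, 0.25], atol=1e-12
        )

    def test_probabilities_sum_to_one_and_survive_large_logits(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((20, 2)) * 500
        p = softmax_probs(z)
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_one_hot_probability_gives_zero_loss(self):
        assert cross_entropy(np.array([0.0, 1.0]), 1) == 0.0

    def test_uniform_probability_gives_ln2(self):
        np.testing.assert_allclose(cross_entropy(np.array([0.5, 0.5]), 0), np.log(2))

    def test_matches_negative_log_of_true_class(self):
        rng = np.random.default_rng(4)
        p1 = rng.uniform(0.01, 0.99, size=50)
        probs = np.column_stack([1 - p1, p1])
        y = rng.integers(0, 2, size=50)
        expected = float(np.mean([-np.log(probs[i, y[i]]) for i in range(50)]))
        np.testing.assert_allclose(cross_entropy(probs, y), expected, atol=1e-12)

    def test_zero_probability_is_clamped(self):
        loss = cross_entropy(np.array([1.0, 0.0]), 1)
        assert np.isfinite(loss) and loss > 20


class TestConvModule:
    def test_position_count_preserved(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((202, 4))
        out = conv_forward(x, ModelConfig(conv_channels=(8, 8, 8)))
        assert out.shape[0] == 202

    def test_identity_kernel_without_norm_reproduces_input(self):
        cfg = ModelConfig(conv_channels=(3,), kernel_size=3, norm=None, attention_heads=1)
        net = build_network(cfg, 3, np.random.default_rng(0))
        conv = net.layers[0]
        W = np.zeros((9, 3))
        W[3:6] = np.eye(3)  # centre tap = identity, other taps = 0
        conv.params["W"] = W
        conv.params["b"] = np.zeros(3)
        x = np.abs(np.random.default_rng(1).standard_normal((1, 10, 3)))
        out = conv_forward(x, cfg, network=net)
        np.testing.assert_allclose(out, x, atol=1e-12)  # LeakyReLU is identity on x>0

    def test_leaky_relu_slope(self):
        from bsjnet._nn import LeakyReLU

        np.testing.assert_allclose(LeakyReLU(0.01).forward(np.array([-1.0])), [-0.01])


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = ModelConfig(
            conv_channels=(6, 4), attention_heads=2, linear_layers=2, fc_hidden=5
        )
        rng = np.random.default_rng(0)
        net = build_network(cfg, 3, rng)
        X = rng.standard_normal((4, 7, 3))
        y = np.array([0, 1, 1, 0])

        logits = net.forward(X, train=True)
        _, dlogits = softmax_cross_entropy(logits, y)
        net.backward(dlogits)

        def loss_at():
            return softmax_cross_entropy(net.forward(X, train=True), y)[0]

        named = list(net.named_params())
        check_rng = np.random.default_rng(42)
        checked = 0
        for i in check_rng.choice(len(named), size=8, replace=False):
            name, owner = named[i]
            key = name.rsplit(".", 1)[-1]
            p = owner.params[key]
            idx = tuple(int(check_rng.integers(0, s)) for s in p.shape)
            analytic = owner.grads[key][idx]
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss_at()
            p[idx] = orig - eps
            lm = loss_at()
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert np.isfinite(analytic)
            if abs(fd) + abs(analytic) > 1e-12:
                assert abs(fd - analytic) / (abs(fd) + abs(analytic)) < 1e-4
            checked += 1
        assert checked >= 5


class TestEstimator:
    @staticmethod
    def _small_clf(**kw):
        defaults = dict(
            conv_channels=(8, 8), attention_heads=2, epochs=12, batch_size=32,
            random_state=0,
        )
        defaults.update(kw)
        return JunctionClassifier(**defaults)

    def test_learns_separable_embeddings(self):
        X, y = generate_separable_embeddings(60, dim=6, margin=10, seed=0)
        clf = self._small_clf().fit(X, y)
        assert clf.score(X, y) >= 0.99

    def test_loss_decreases_on_separable_batch(self):
        X, y = generate_separable_embeddings(40, dim=6, margin=10, seed=1)
        clf = self._small_clf(epochs=10).fit(X, y)
        losses = clf.history_["train_loss"]
        assert losses[9] < losses[0]

    def test_same_seed_identical_history_and_probs(self):
        X, y = generate_separable_embeddings(30, dim=4, margin=5, seed=2)
        runs = [self._small_clf(epochs=4).fit(X, y) for _ in range(2)]
        assert runs[0].history_ == runs[1].history_
        np.testing.assert_array_equal(
            runs[0].predict_proba(X), runs[1].predict_proba(X)
        )

    def test_probabilities_valid(self):
        X, y = generate_separable_embeddings(20, dim=4, margin=5, seed=3)
        p = self._small_clf(epochs=2).fit(X, y).predict_proba(X)
        assert p.shape == (40, 2)
        assert ((p > 0) & (p < 1)).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_no_attention_ablation_runs_end_to_end(self):
        X, y = generate_separable_embeddings(20, dim=4, margin=5, seed=4)
        clf = self._small_clf(use_attention=False, epochs=3).fit(X, y)
        assert clf.predict(X).shape == (40,)

    def test_three_linear_layers_still_emit_two_logits(self):
        X, y = generate_separable_embeddings(15, dim=4, margin=5, seed=5)
        clf = self._small_clf(linear_layers=3, epochs=2).fit(X, y)
        assert clf.predict_proba(X).shape == (30, 2)

    def test_sklearn_params_roundtrip(self):
        clf = JunctionClassifier(learning_rate=0.001)
        params = clf.get_params()
        assert params["learning_rate"] == 0.001
        clone = JunctionClassifier(**params)
        assert clone.get_params() == params

    def test_default_learning_rate_is_0_005(self):
        assert JunctionClassifier().get_params()["learning_rate"] == 0.005

    def test_checkpoint_roundtrip(self, tmp_path):
        X, y = generate_separable_embeddings(20, dim=4, margin=5, seed=6)
        clf = self._small_clf(epochs=3).fit(X, y)
        clf.save(tmp_path / "ckpt.npz", embedder_id="one_hot")
        restored, embedder_id = JunctionClassifier.load(tmp_path / "ckpt.npz")
        assert embedder_id == "one_hot"
        np.testing.assert_array_equal(restored.predict_proba(X), clf.predict_proba(X))

    def test_invalid_labels_rejected(self):
        X, _ = generate_separable_embeddings(5, dim=4, margin=1, seed=7)
        with pytest.raises(ValueError, match="binary"):
            self._small_clf().fit(X, np.full(10, 2))

    def test_2d_input_rejected(self):
        with pytest.raises(ValueError, match="positions"):
            self._small_clf().fit(np.zeros((4, 8)), np.array([0, 1, 0, 1]))
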