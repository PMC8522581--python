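import numpy as np
import pytest

from cgatnet import (
    AttentionResult,
    ModelConfig,
    PointPattern,
    TrainConfig,
    attention_percentile_mask,
    build_knn_adjacency,
    embed_labels,
    forward,
    gcn_layer,
    init_params,
    load_model,
    save_model,
    self_attention,
    train_pairwise,
)
from conftest import random_pattern


def brute_force_gcn(X, A_tilde, W, activation):
    """Per-node oracle: weighted neighbour sum, then weights, then sigma."""
    n, d = X.shape
    out = np.zeros((n, d))
    for i in range(n):
        agg = np.zeros(d)
        for j in range(n):
            agg += A_tilde[i, j] * X[j]
        z = agg @ W
        out[i] = np.maximum(z, 0) if activation == "relu" else np.tanh(z)
    return out


@pytest.fixture
def config():
    return ModelConfig(d=6, layers=2, k=3, seed=0)


@pytest.fixture
def params(config, rng):
    return init_params(config, rng)


class TestEmbedLabels:
    def test_lookup_matches_table_rows(self, params):
        X = embed_labels(("Epithelial", "CTL", "Epithelial"), params)
        np.testing.assert_array_equal(X[0], X[2])
        np.testing.assert_array_equal(X[1], params.embedding[1])

    def test_identical_labels_identical_rows(self, params):
        X = embed_labels(("Treg",) * 5, params)
        assert (X == X[0]).all()

    def test_zero_table_gives_zero_features(self, config, params):
        params.embedding[:] = 0.0
        X = embed_labels(("CTL", "Treg"), params)
        assert (X == 0).all()

    def test_unknown_label_raises(self, params):
        with pytest.raises(KeyError, match="Bcell"):
            embed_labels(("Bcell",), params)


class TestGcnLayer:
    def test_zero_weights_give_zero_output(self, rng):
        X = rng.normal(size=(4, 3))
        A = np.eye(4)
        for act in ("relu", "tanh"):
            assert (gcn_layer(X, A, np.zeros((3, 3)), act) == 0).all()

    def test_isolated_node_relu_clamps_negative(self):
        out = gcn_layer(np.array([[-1.0, 2.0]]), np.array([[1.0]]), np.eye(2), "relu")
        np.testing.assert_array_equal(out, [[0.0, 2.0]])

    def test_two_node_edge_averages_features(self):
        A_tilde = 0.5 * np.ones((2, 2))
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gcn_layer(X, A_tilde, np.eye(2), "relu")
        np.testing.assert_allclose(out, 0.5 * np.ones((2, 2)))

    def test_matches_per_node_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            n, d = int(rng.integers(2, 15)), int(rng.integers(1, 8))
            pat = random_pattern(rng, n)
            g = build_knn_adjacency(pat, min(3, n - 1))
            X = rng.normal(size=(n, d))
            W = rng.normal(size=(d, d))
            act = "relu" if rng.random() < 0.5 else "tanh"
            got = gcn_layer(X, g.A_tilde, W, act)
            want = brute_force_gcn(X, g.A_tilde.toarray(), W, act)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            gcn_layer(rng.normal(size=(3, 4)), np.eye(3), np.eye(5), "relu")


class TestSelfAttention:
    def test_zero_vector_gives_uniform_weights_and_mean_context(self, rng):
        X = rng.normal(size=(7, 4))
        att = self_attention(X, np.zeros(4))
        np.testing.assert_allclose(att.p, np.full(7, 1 / 7))
        np.testing.assert_allclose(att.s, X.mean(axis=0), atol=1e-12)

    def test_single_cell(self, rng):
        X = rng.normal(size=(1, 4))
        att = self_attention(X, rng.normal(size=4))
        np.testing.assert_allclose(att.p, [1.0])
        np.testing.assert_allclose(att.s, X[0])

    def test_scalar_two_cell_example(self):
        # alpha = (tanh(0), tanh(10)) ~ (0, 1); p = softmax; s = 10 * p[1]
        att = self_attention(np.array([[0.0], [10.0]]), np.array([1.0]))
        np.testing.assert_allclose(att.alpha, [0.0, np.tanh(10.0)], atol=1e-4)
        np.testing.assert_allclose(att.p, [0.2689, 0.7311], atol=1e-4)
        np.testing.assert_allclose(att.s, [7.311], atol=1e-3)

    def test_simplex_on_many_random_inputs(self, rng):
        for _ in range(1000):
            n, d = int(rng.integers(1, 30)), int(rng.integers(1, 6))
            X = rng.normal(scale=rng.uniform(0.1, 50), size=(n, d))
            att = self_attention(X, rng.normal(size=d))
            assert (att.p >= 0).all()
            assert abs(att.p.sum() - 1.0) < 1e-9
            np.testing.assert_allclose(att.s, X.T @ att.p, atol=1e-9)

    def test_extreme_scores_do_not_overflow(self):
        X = np.array([[1e3], [-1e3]])
        att = self_attention(X, np.array([1e6]))
        assert np.isfinite(att.p).all()


class TestForward:
    def test_all_zero_params_give_even_odds(self, config, tiny_pattern, rng):
        params = init_params(config, rng)
        for arr in params.arrays().values():
            arr[:] = 0.0
        probs, _ = forward(tiny_pattern, params, config)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_probabilities_sum_to_one(self, config, params, rng):
        for n in (1, 4, 40):
            pat = random_pattern(rng, n)
            probs, _ = forward(pat, params, config)
            assert abs(probs.sum() - 1.0) < 1e-9

    def test_permutation_invariance_and_equivariance(self, config, params, rng):
        for _ in range(10):
            n = int(rng.integers(3, 40))
            pat = random_pattern(rng, n)
            perm = rng.permutation(n)
            probs, att = forward(pat, params, config)
            probs_p, att_p = forward(pat.subset(perm), params, config)
            np.testing.assert_allclose(probs_p, probs, atol=1e-6)
            np.testing.assert_allclose(att_p.p, att.p[perm], atol=1e-6)

    @pytest.mark.parametrize("n", [1, 5, 50, 500])
    def test_context_vector_dimension_independent_of_n(self, config, params, rng, n):
        pat = random_pattern(rng, n)
        _, att = forward(pat, params, config)
        assert att.s.shape == (config.d,)


class TestTrainPairwise:
    @staticmethod
    def _separable_cohort(rng, n_per_class=10, n_cells=40):
        """Classes use disjoint phenotypes, separable by embedding alone."""
        cohort = []
        for cls, lab in (("A", "Epithelial"), ("B", "CTL")):
            for i in range(n_per_class):
                coords = rng.uniform(0, 100, size=(n_cells, 2))
                cohort.append(
                    PointPattern(f"{cls}{i}", coords, (lab,) * n_cells,
                                 disease_class=cls)
                )
        return cohort

    def test_separable_cohort_reaches_low_loss(self, rng):
        cohort = self._separable_cohort(rng)
        model = train_pairwise(
            cohort, ("A", "B"),
            ModelConfig(d=8, layers=2, k=5, seed=1),
            TrainConfig(epochs=100, seed=1),
        )
        assert model.final_loss < 0.1
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_seeded_determinism(self, rng):
        cohort = self._separable_cohort(rng, n_per_class=4, n_cells=20)
        kw = dict(
            model_config=ModelConfig(d=6, layers=2, k=5, seed=3),
            train_config=TrainConfig(epochs=5, seed=3),
        )
        m1 = train_pairwise(cohort, ("A", "B"), **kw)
        m2 = train_pairwise(cohort, ("A", "B"), **kw)
        assert abs(m1.final_loss - m2.final_loss) <= 1e-7
        np.testing.assert_array_equal(m1.params.embedding, m2.params.embedding)

    def test_missing_class_raises(self, rng):
        cohort = self._separable_cohort(rng, n_per_class=3)
        with pytest.raises(ValueError, match="each class"):
            train_pairwise(cohort, ("A", "C"))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        cohort = self._separable_cohort(rng, n_per_class=3, n_cells=15)
        model = train_pairwise(
            cohort, ("A", "B"),
            ModelConfig(d=5, layers=2, k=4, seed=0),
            TrainConfig(epochs=3, seed=0),
        )
        path = save_model(model, tmp_path / "ckpt.npz")
        back = load_model(path)
        assert back.class_pair == model.class_pair
        pat = cohort[0]
        np.testing.assert_allclose(
            back.predict_proba(pat), model.predict_proba(pat), atol=1e-12
        )


class TestAttentionPercentileMask:
    def test_uniform_weights_all_selected(self):
        att = AttentionResult(alpha=np.zeros(10), p=np.full(10, 0.1), s=np.zeros(2))
        assert len(attention_percentile_mask(att, 90)) == 10

    def test_q_zero_selects_all(self, rng):
        p = rng.dirichlet(np.ones(15))
        att = AttentionResult(alpha=np.zeros(15), p=p, s=np.zeros(2))
        assert len(attention_percentile_mask(att, 0)) == 15

    def test_distinct_weights_top_decile(self):
        p = np.arange(1, 11, dtype=float)
        p /= p.sum()
        att = AttentionResult(alpha=np.zeros(10), p=p, s=np.zeros(2))
        # 90th percentile of 10 distinct values (linear interpolation) lies
        # between the 9th and 10th order statistic: only the max qualifies
        sel = attention_percentile_mask(att, 90)
        assert sel.tolist() == [9]

    def test_out_of_range_percentile(self):
        att = AttentionResult(alpha=np.zeros(3), p=np.full(3, 1 / 3), s=np.zeros(2))
        with pytest.raises(ValueError):
            attention_percentile_mask(att, 101)
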