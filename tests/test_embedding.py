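import numpy as np
import pytest
from scipy.stats import chisquare
from sklearn.cluster import KMeans

from graphimg.connectivity import ConnectivityGraph
from graphimg.embedding import (SkipGramConfig, WalkConfig, generate_walks,
                                node2vec, random_walk, train_skipgram)


def _graph(weights, ids=None):
    weights = np.asarray(weights, dtype=float)
    ids = ids or [f"n{i}" for i in range(weights.shape[0])]
    return ConnectivityGraph(ids, weights)


def _triangle():
    # w(a,b)=0.8, w(a,c)=0.4, w(b,c)=0.2  (spec ratio 2:1 from a)
    return _graph([[0, 0.8, 0.4], [0.8, 0, 0.2], [0.4, 0.2, 0]])


class TestRandomWalk:
    def test_length_one_is_just_the_root(self):
        walk = random_walk(_triangle(), 2, 1, np.random.default_rng(0))
        assert walk.tolist() == [2]

    def test_single_edge_forces_alternation(self):
        g = _graph([[0, 0.7], [0.7, 0]], ids=["a", "b"])
        walk = random_walk(g, 0, 4, np.random.default_rng(1))
        assert walk.tolist() == [0, 1, 0, 1]

    def test_transition_frequency_proportional_to_weight(self):
        g = _triangle()
        rng = np.random.default_rng(2)
        steps = np.array([random_walk(g, 0, 2, rng)[1] for _ in range(10_000)])
        frac_b = np.mean(steps == 1)
        assert frac_b == pytest.approx(2 / 3, abs=0.02)

    def test_isolated_start_raises_with_node_name(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        g = _graph(w, ids=["a", "b", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            random_walk(g, 2, 5, np.random.default_rng(0))

    def test_chi_square_transition_law(self):
        # empirical successor counts from one node vs weight-normalized law
        rng = np.random.default_rng(3)
        w = rng.uniform(0.1, 1.0, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = _graph(np.round(w, 6))
        n = 10_000
        steps = np.array([random_walk(g, 0, 2, rng)[1] for _ in range(n)])
        observed = np.bincount(steps, minlength=6)[1:]
        expected = g.weights[0, 1:] / g.weights[0, 1:].sum() * n
        _, p = chisquare(observed, expected)
        assert p > 0.01

    def test_uniform_transition_ignores_weights(self):
        g = _triangle()
        rng = np.random.default_rng(4)
        steps = np.array(
            [random_walk(g, 0, 2, rng, transition="uniform")[1] for _ in range(5000)])
        assert np.mean(steps == 1) == pytest.approx(0.5, abs=0.03)


class TestGenerateWalks:
    def test_walk_count_and_roots(self, two_block_graph):
        cfg = WalkConfig(iterations=3, walk_length=10, seed=0)
        walks = generate_walks(two_block_graph, cfg)
        assert len(walks) == 3 * two_block_graph.n_nodes
        roots = np.array([w[0] for w in walks])
        counts = np.bincount(roots, minlength=two_block_graph.n_nodes)
        assert np.all(counts == 3)

    def test_every_step_is_a_positive_edge(self, two_block_graph):
        walks = generate_walks(two_block_graph, WalkConfig(iterations=2, walk_length=15, seed=1))
        w = two_block_graph.weights
        for walk in walks:
            assert np.all(w[walk[:-1], walk[1:]] > 0)

    def test_fixed_seed_reproducible(self, two_block_graph):
        cfg = WalkConfig(iterations=2, walk_length=12, seed=9)
        a = generate_walks(two_block_graph, cfg)
        b = generate_walks(two_block_graph, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_isolated_node_propagates(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.raises(ValueError, match="n2"):
            generate_walks(_graph(w), WalkConfig(iterations=1, walk_length=5, seed=0))


class TestTrainSkipgram:
    def test_model_shapes_and_softmax_normalization(self):
        rng = np.random.default_rng(0)
        walks = [rng.integers(0, 8, size=12) for _ in range(20)]
        model = train_skipgram(walks, SkipGramConfig(dim=4, epochs=2, seed=0), n_nodes=8)
        assert model.input_weights.shape == (8, 4)
        assert model.output_weights.shape == (4, 8)
        for node in range(8):
            assert model.predict_context(node).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_walk_list_rejected(self):
        with pytest.raises(ValueError):
            train_skipgram([], SkipGramConfig(dim=4), n_nodes=5)

    def test_two_cliques_cosine_separation(self):
        # two 6-node cliques joined by one weak edge
        n = 12
        w = np.zeros((n, n))
        for block in (range(6), range(6, 12)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 0.9
        w[5, 6] = w[6, 5] = 0.05
        g = _graph(w)
        walks = generate_walks(g, WalkConfig(iterations=10, walk_length=30, seed=3))
        model = train_skipgram(walks, SkipGramConfig(window=4, dim=6, epochs=5, seed=3), n)
        v = model.input_weights
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        cos = v @ v.T
        same = np.zeros((n, n), dtype=bool)
        same[:6, :6] = same[6:, 6:] = True
        np.fill_diagonal(cos, np.nan)
        within = np.nanmean(cos[same])
        between = np.nanmean(cos[~same])
        assert within > between

    def test_permutation_equivariance_given_permuted_inputs(self):
        rng = np.random.default_rng(7)
        n, d = 10, 4
        walks = [rng.integers(0, n, size=15) for _ in range(30)]
        perm = rng.permutation(n)
        init_in = rng.uniform(-0.1, 0.1, (n, d))
        init_out = rng.uniform(-0.1, 0.1, (d, n))
        cfg = SkipGramConfig(dim=d, epochs=2, seed=1)
        base = train_skipgram(walks, cfg, n, init_input=init_in, init_output=init_out)
        perm_walks = [perm[w] for w in walks]
        perm_init_in = np.empty_like(init_in)
        perm_init_in[perm] = init_in
        perm_init_out = np.empty_like(init_out)
        perm_init_out[:, perm] = init_out
        permuted = train_skipgram(perm_walks, cfg, n,
                                  init_input=perm_init_in, init_output=perm_init_out)
        assert np.allclose(permuted.input_weights[perm], base.input_weights, atol=1e-10)


class TestNode2Vec:
    def test_embedding_dim_must_be_small(self, two_block_graph):
        with pytest.raises(ValueError):
            node2vec(two_block_graph, WalkConfig(iterations=1, walk_length=5, seed=0),
                     SkipGramConfig(dim=two_block_graph.n_nodes))

    def test_deterministic_under_fixed_seeds(self, two_block_graph):
        wc = WalkConfig(iterations=2, walk_length=10, seed=4)
        sc = SkipGramConfig(dim=6, epochs=2, seed=4)
        a = node2vec(two_block_graph, wc, sc)
        b = node2vec(two_block_graph, wc, sc)
        assert np.array_equal(a.vectors, b.vectors)

    def test_two_means_recovers_planted_blocks(self, two_block_embedding):
        labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
            two_block_embedding.vectors)
        truth = np.array([0] * 15 + [1] * 15)
        agreement = max(np.mean(labels == truth), np.mean(labels != truth))
        assert agreement >= 0.9
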