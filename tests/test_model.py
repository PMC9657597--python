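"""Propagation operators, graph convolution, sort pooling, read-out head."""

import numpy as np
import pytest

import linkgnn.nn as nn
from linkgnn.data import PairSample
from linkgnn.model import (
    ABLATION_VARIANTS,
    ModelConfig,
    TrainedModel,
    build_propagators,
    conv1d_head,
    forward,
    graph_conv_layer,
    load_checkpoint,
    nll_loss,
    save_checkpoint,
    sort_pooling,
    stack_conv_layers,
)
from linkgnn.subgraph import LabelEncoding, batch_extract, extract_enclosing_subgraph

from conftest import random_bipartite


def dense_propagators(adj):
    """Independent dense-matrix oracle for all four operators."""
    A = adj.astype(float)
    n = len(A)
    At = A + np.eye(n)
    deg = At.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / deg, 0.0)
    return {
        "A": A,
        "A2": A @ A,
        "rw_norm": np.diag(dinv) @ At,
        "sym_norm": np.diag(np.sqrt(dinv)) @ At @ np.diag(np.sqrt(dinv)),
    }


def random_subgraph_adj(rng, n_max=15):
    na = int(rng.integers(1, n_max // 2))
    nb = int(rng.integers(1, n_max // 2))
    B = (rng.random((na, nb)) < 0.4).astype(float)
    adj = np.zeros((na + nb, na + nb))
    adj[:na, na:] = B
    adj[na:, :na] = B.T
    return adj, na


class TestPropagators:
    def test_match_dense_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            adj, _ = random_subgraph_adj(rng)
            stack = build_propagators(adj)
            oracle = dense_propagators(adj)
            for name in nn.ALL_PROPAGATORS:
                got = stack[name].toarray()
                assert np.allclose(got, oracle[name], atol=1e-6), name

    def test_a_squared_stays_within_sides(self):
        """[[0,B],[B^T,0]]^2 = [[BB^T,0],[0,B^TB]]: no cross-side entries,
        and within-side entries count common neighbors."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            adj, na = random_subgraph_adj(rng, n_max=14)
            A2 = build_propagators(adj, ["A2"])["A2"].toarray()
            assert np.allclose(A2[:na, na:], 0)
            assert np.allclose(A2[na:, :na], 0)
            n = len(adj)
            for i in range(n):
                for j in range(n):
                    common = int(np.sum(adj[i].astype(bool) & adj[j].astype(bool)))
                    assert A2[i, j] == common

    def test_single_edge_a_squared(self):
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        A2 = build_propagators(adj, ["A2"])["A2"].toarray()
        assert np.array_equal(A2, np.eye(2))

    def test_empty_adjacency(self):
        adj = np.zeros((3, 3))
        stack = build_propagators(adj)
        assert stack["A"].nnz == 0
        assert np.allclose(stack["rw_norm"].toarray(), np.eye(3))
        assert np.allclose(stack["sym_norm"].toarray(), np.eye(3))

    def test_rw_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        adj, _ = random_subgraph_adj(rng)
        rw = build_propagators(adj, ["rw_norm"])["rw_norm"].toarray()
        assert np.allclose(rw.sum(axis=1), 1.0)

    def test_sym_is_symmetric(self):
        rng = np.random.default_rng(3)
        adj, _ = random_subgraph_adj(rng)
        sym = build_propagators(adj, ["sym_norm"])["sym_norm"].toarray()
        assert np.allclose(sym, sym.T)


class TestGraphConv:
    def test_single_propagator_identity_weight_reduces_to_AZ(self):
        rng = np.random.default_rng(4)
        adj, _ = random_subgraph_adj(rng)
        n = len(adj)
        Z = rng.normal(size=(n, 4))
        stack = build_propagators(adj, ["A"])
        out = graph_conv_layer(Z, stack, np.eye(4), activation="identity")
        assert np.allclose(out, adj @ Z, atol=1e-9)

    def test_zero_input_gives_sigma_zero(self):
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        stack = build_propagators(adj)
        out = graph_conv_layer(np.zeros((2, 3)), stack, np.ones((12, 5)))
        assert np.allclose(out, np.tanh(0.0))

    def test_concat_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            adj, _ = random_subgraph_adj(rng)
            n = len(adj)
            Z = rng.normal(size=(n, 3))
            W = rng.normal(size=(12, 2))
            stack = build_propagators(adj)
            oracle_ops = dense_propagators(adj)
            H = np.concatenate([oracle_ops[p] @ Z for p in nn.ALL_PROPAGATORS], axis=1)
            expected = np.tanh(H @ W)
            got = graph_conv_layer(Z, stack, W)
            assert np.allclose(got, expected, atol=1e-6)

    def test_shape_mismatch_errors(self):
        adj = np.zeros((2, 2))
        stack = build_propagators(adj, ["A"])
        with pytest.raises(ValueError):
            graph_conv_layer(np.zeros((2, 3)), stack, np.zeros((5, 2)))

    def test_stacked_layers_widths_and_rows(self):
        rng = np.random.default_rng(6)
        adj, _ = random_subgraph_adj(rng)
        n = len(adj)
        X = rng.normal(size=(n, 5))
        dims = [7, 3, 1]
        weights = []
        d_in = 5
        for d in dims:
            weights.append(rng.normal(size=(4 * d_in, d)))
            d_in = d
        Z = stack_conv_layers(X, build_propagators(adj), weights)
        assert Z.shape == (n, sum(dims))


class TestSortPooling:
    def test_n_equals_k_is_reordering(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(6, 4))
        out = sort_pooling(Z, 6)
        assert sorted(map(tuple, out)) == sorted(map(tuple, Z))
        assert np.all(np.diff(out[:, -1]) <= 0)

    def test_padding_when_fewer_nodes(self):
        Z = np.ones((2, 3))
        out = sort_pooling(Z, 5)
        assert out.shape == (5, 3)
        assert np.allclose(out[2:], 0)

    def test_tie_break_uses_earlier_channels(self):
        Z = np.array([[0.0, 1.0], [5.0, 1.0], [1.0, 2.0]])
        out = sort_pooling(Z, 2)
        # last channel primary: row [1,2] first; tie on 1.0 broken by
        # first channel descending: [5,1] before [0,1]
        assert out.tolist() == [[1.0, 2.0], [5.0, 1.0]]

    def test_identical_rows_tie_is_stable(self):
        Z = np.array([[2.0, 3.0], [2.0, 3.0], [0.0, 0.0]])
        out = sort_pooling(Z, 2)
        assert out.tolist() == [[2.0, 3.0], [2.0, 3.0]]


def make_tiny_model(rng, config=None, k=10, L=8):
    config = config or ModelConfig(conv_dims=(4, 1))
    params = nn.init_params(config, L, k, rng)
    return TrainedModel(config=config, parameters=params, resolved_k=k, feature_width=L)


class TestHeadAndForward:
    def test_log_probs_normalize(self):
        rng = np.random.default_rng(8)
        model = make_tiny_model(rng)
        pooled = rng.normal(size=(model.resolved_k, model.config.embed_dim))
        logp = conv1d_head(pooled, model)
        assert np.isclose(np.exp(logp).sum(), 1.0, atol=1e-6)

    def test_zero_input_finite(self):
        rng = np.random.default_rng(9)
        model = make_tiny_model(rng)
        logp = conv1d_head(np.zeros((model.resolved_k, model.config.embed_dim)), model)
        assert np.isfinite(logp).all()

    def test_first_conv_covers_k_positions(self):
        # kernel = stride = embed width D over a flattened k x D tensor
        k, D = 12, 5
        assert (k * D - D) // D + 1 == k

    def test_too_small_k_raises_at_build(self):
        rng = np.random.default_rng(10)
        config = ModelConfig()
        with pytest.raises(ValueError):
            nn.init_params(config, 8, k=4, rng=rng)

    def test_forward_probability_range_and_determinism(self, small_sbm):
        rng = np.random.default_rng(11)
        enc = LabelEncoding()
        model = make_tiny_model(rng, ModelConfig(conv_dims=(4, 1)), k=10, L=enc.L)
        g = extract_enclosing_subgraph(small_sbm, PairSample(0, 0, 0), 2, enc)
        p1 = forward(g, model)
        p2 = forward(g, model)
        assert 0.0 <= p1 <= 1.0
        assert p1 == p2

    def test_forward_invariant_to_noncenter_permutation(self, small_sbm):
        rng = np.random.default_rng(12)
        enc = LabelEncoding()
        model = make_tiny_model(rng, ModelConfig(), k=12, L=enc.L)
        g = extract_enclosing_subgraph(small_sbm, PairSample(1, 2, 0), 2, enc)
        n = g.n_nodes
        if n <= 3:
            pytest.skip("subgraph too small to permute")
        base = forward(g, model)
        for trial in range(3):
            perm = np.concatenate([[0, 1], 2 + rng.permutation(n - 2)])
            import copy

            gp = copy.deepcopy(g)
            gp.adj = g.adj[np.ix_(perm, perm)]
            gp.sides = g.sides[perm]
            gp.global_indices = g.global_indices[perm]
            gp.labels = g.labels[perm]
            gp.features = g.features[perm]
            assert abs(forward(gp, model) - base) < 1e-5

    def test_width_mismatch_errors(self, small_sbm):
        rng = np.random.default_rng(13)
        model = make_tiny_model(rng, L=5)
        g = extract_enclosing_subgraph(small_sbm, PairSample(0, 0, 0), 2)
        with pytest.raises(ValueError):
            forward(g, model)


class TestNLL:
    def test_perfect_prediction_zero_loss(self):
        logp = np.log(np.array([[1e-12, 1.0], [1.0, 1e-12]]))
        assert nll_loss(logp, [1, 0]) < 1e-9

    def test_uniform_predictor_ln2(self):
        logp = np.full((10, 2), np.log(0.5))
        assert abs(nll_loss(logp, [0, 1] * 5) - np.log(2)) < 1e-9

    def test_batch_permutation_invariant(self):
        rng = np.random.default_rng(14)
        logits = rng.normal(size=(20, 2))
        logp = logits - np.logaddexp(logits[:, :1], logits[:, 1:])
        y = rng.integers(0, 2, size=20)
        perm = rng.permutation(20)
        assert np.isclose(nll_loss(logp, y), nll_loss(logp[perm], y[perm]))


class TestGradients:
    def test_backprop_matches_finite_differences(self, small_subgraphs):
        """Analytic gradients of the NLL agree with central differences."""
        config = ModelConfig()
        subs = small_subgraphs[:5] + small_subgraphs[-5:]
        batch = nn.make_batches(subs, 10)[0]
        k = 10
        rng = np.random.default_rng(15)
        params = nn.init_params(config, subs[0].features.shape[1], k, rng)
        logp, cache = nn.net_forward(params, config, batch, k)
        _, dlogp = nn.nll_from_logp(logp, batch.y)
        grads = nn.net_backward(params, config, batch, cache, dlogp)
        eps = 1e-6
        for key in sorted(params):
            W = params[key]
            idx = tuple(int(rng.integers(s)) for s in W.shape)
            W[idx] += eps
            lp, _ = nn.net_forward(params, config, batch, k)
            up, _ = nn.nll_from_logp(lp, batch.y)
            W[idx] -= 2 * eps
            lm, _ = nn.net_forward(params, config, batch, k)
            dn, _ = nn.nll_from_logp(lm, batch.y)
            W[idx] += eps
            num = (up - dn) / (2 * eps)
            ana = grads[key][idx]
            denom = max(abs(num) + abs(ana), 1e-8)
            assert abs(num - ana) / denom < 1e-3, key


class TestConfigAndCheckpoint:
    def test_ablation_variants_cover_published_subsets(self):
        assert set(ABLATION_VARIANTS) == {"full", "a", "b", "c", "d", "baseline"}
        assert "A" not in ABLATION_VARIANTS["a"]
        assert "A2" not in ABLATION_VARIANTS["b"]
        assert "rw_norm" not in ABLATION_VARIANTS["c"]
        assert "sym_norm" not in ABLATION_VARIANTS["d"]
        assert ABLATION_VARIANTS["baseline"] == ("sym_norm",)
        for props in ABLATION_VARIANTS.values():
            ModelConfig(propagators=props)  # all build

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(propagators=())
        with pytest.raises(ValueError):
            ModelConfig(conv_dims=(32, 32))  # last dim must be 1
        with pytest.raises(ValueError):
            ModelConfig(propagators=("bogus",))

    def test_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig(propagators=("A", "A2"), conv_dims=(8, 1), pooling_k=17)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = ModelConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_checkpoint_round_trip(self, tmp_path, small_sbm):
        rng = np.random.default_rng(16)
        model = make_tiny_model(rng)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == model.config
        assert back.resolved_k == model.resolved_k
        for key, v in model.parameters.items():
            assert np.array_equal(back.parameters[key], v)
        g = extract_enclosing_subgraph(
            small_sbm, PairSample(0, 0, 0), 2, LabelEncoding(cap=6)
        )
        assert forward(g, back) == forward(g, model)
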