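import numpy as np
import pytest

from mdalink import (AttributedGraph, EmbeddingSet, GateConfig, build_graph,
                     attention_weights, decode, encode, gate_loss,
                     make_pair_features, train_gate)
from mdalink.gate import _loss_and_grads, init_model

from conftest import random_similarity


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def layer_oracle(Hin, W, vs, vr, neighbor_sets):
    """Nested-loop evaluation of one attention layer from its definition."""
    n = Hin.shape[0]
    Z = np.array([np.tanh(W @ Hin[j]) for j in range(n)])
    Hout = np.zeros((n, W.shape[0]))
    alpha = {}
    for i in range(n):
        cs = {j: sigmoid(float(vs @ Z[i]) + float(vr @ Z[j]))
              for j in neighbor_sets[i]}
        denom = sum(np.exp(c) for c in cs.values())
        for j, c in cs.items():
            alpha[(i, j)] = np.exp(c) / denom
            Hout[i] += alpha[(i, j)] * Z[j]
    return Hout, alpha


def loss_oracle(X, Xhat, H, neighbor_sets, lam):
    recon = sum(float((X[i] - Xhat[i]) @ (X[i] - Xhat[i]))
                for i in range(len(X)))
    structure = 0.0
    for i in range(len(X)):
        for j in neighbor_sets[i]:
            structure -= np.log(1.0 / (1.0 + np.exp(-float(H[i] @ H[j]))))
    return recon + lam * structure


class TestBuildGraph:
    def test_self_always_included(self, small_graph):
        for i, nbrs in enumerate(small_graph.neighbor_sets):
            assert i in nbrs

    def test_top_neighbor_chosen(self):
        S = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        sim = random_similarity(3, 0)
        sim.S = S
        g = build_graph(sim, np.zeros((3, 2)), k_neighbors=1)
        assert set(g.neighbor_sets[0]) == {0, 1}

    def test_tie_breaks_to_lower_index(self):
        S = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.1], [0.5, 0.1, 1.0]])
        sim = random_similarity(3, 0)
        sim.S = S
        g = build_graph(sim, np.zeros((3, 2)), k_neighbors=1)
        assert set(g.neighbor_sets[0]) == {0, 1}

    def test_full_neighborhood_at_k_max(self):
        sim = random_similarity(4, 3)
        g = build_graph(sim, np.zeros((4, 2)), k_neighbors=3)
        for nbrs in g.neighbor_sets:
            assert len(nbrs) == 4

    def test_k_too_large_errors(self):
        sim = random_similarity(4, 3)
        with pytest.raises(ValueError, match="k_neighbors"):
            build_graph(sim, np.zeros((4, 2)), k_neighbors=4)


class TestAttention:
    @pytest.mark.parametrize("direction", ["encode", "decode"])
    def test_rows_sum_to_one(self, small_graph, direction):
        model = init_model(4, GateConfig(embedding_dim=4, seed=0))
        H = small_graph.X
        A = attention_weights(model, 0, small_graph, H, direction)
        assert np.abs(A.sum(axis=1) - 1.0).max() < 1e-10
        assert (A[small_graph.mask] > 0).all()

    def test_singleton_neighborhood_gives_unit_weight(self):
        mask = np.eye(3, dtype=bool)
        graph = AttributedGraph(["a", "b", "c"],
                                [np.array([i]) for i in range(3)],
                                np.ones((3, 2)), mask)
        model = init_model(2, GateConfig(embedding_dim=2, seed=0))
        A = attention_weights(model, 0, graph, graph.X)
        assert np.allclose(np.diag(A), 1.0)

    def test_equal_logits_give_uniform_weights(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, seed=0))
        for p in model.enc:  # zero weights -> all logits sigmoid(0)
            p["W"][:] = 0.0
            p["vs"][:] = 0.0
            p["vr"][:] = 0.0
        A = attention_weights(model, 0, small_graph, small_graph.X)
        for i, nbrs in enumerate(small_graph.neighbor_sets):
            assert np.allclose(A[i, nbrs], 1.0 / len(nbrs))

    def test_matches_loop_oracle(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, seed=2))
        p = model.enc[0]
        A = attention_weights(model, 0, small_graph, small_graph.X)
        _, alpha = layer_oracle(small_graph.X, p["W"], p["vs"], p["vr"],
                                small_graph.neighbor_sets)
        for (i, j), a in alpha.items():
            assert A[i, j] == pytest.approx(a, abs=1e-12)


class TestEncodeDecodeLoss:
    def test_encode_matches_loop_oracle(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, seed=5))
        p = model.enc[0]
        _, emb = encode(model, small_graph)
        Href, _ = layer_oracle(small_graph.X, p["W"], p["vs"], p["vr"],
                               small_graph.neighbor_sets)
        assert np.abs(emb.H - Href).max() < 1e-10

    def test_decode_matches_loop_oracle(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, seed=5))
        _, emb = encode(model, small_graph)
        Xhat = decode(model, emb, small_graph)
        p = model.dec[0]
        Xref, _ = layer_oracle(emb.H, p["W"], p["vs"], p["vr"],
                               small_graph.neighbor_sets)
        assert np.abs(Xhat - Xref).max() < 1e-10

    def test_singleton_graph_closed_form(self):
        mask = np.eye(2, dtype=bool)
        X = np.array([[0.3, -0.2], [0.1, 0.4]])
        graph = AttributedGraph(["a", "b"],
                                [np.array([0]), np.array([1])], X, mask)
        model = init_model(2, GateConfig(embedding_dim=3, seed=1))
        _, emb = encode(model, graph)
        W = model.enc[0]["W"]
        assert np.allclose(emb.H, np.tanh(X @ W.T))  # alpha = 1

    def test_zero_attributes_zero_weights_fixed_point(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, seed=0))
        for p in model.enc + model.dec:
            p["W"][:] = 0.0
        graph = AttributedGraph(small_graph.names, small_graph.neighbor_sets,
                                np.zeros_like(small_graph.X),
                                small_graph.mask)
        _, emb = encode(model, graph)
        assert np.allclose(emb.H, 0.0)
        assert np.allclose(decode(model, emb, graph), 0.0)

    def test_loss_perfect_reconstruction_lambda_zero(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, lam=0.0, seed=0))
        emb = EmbeddingSet(small_graph.names, np.ones((5, 3)))
        assert gate_loss(model, small_graph, emb, small_graph.X.copy()) == 0.0

    def test_loss_structure_closed_form(self, small_graph):
        # zero embeddings: every edge term is log 2
        model = init_model(4, GateConfig(embedding_dim=3, lam=1.0, seed=0))
        emb = EmbeddingSet(small_graph.names, np.zeros((5, 3)))
        expected = sum(len(nb) for nb in small_graph.neighbor_sets) * np.log(2)
        got = gate_loss(model, small_graph, emb, small_graph.X.copy())
        assert got == pytest.approx(expected, abs=1e-10)

    def test_loss_matches_loop_oracle(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, lam=0.7, seed=8))
        _, emb = encode(model, small_graph)
        Xhat = decode(model, emb, small_graph)
        ref = loss_oracle(small_graph.X, Xhat, emb.H,
                          small_graph.neighbor_sets, 0.7)
        assert gate_loss(model, small_graph, emb, Xhat) == pytest.approx(
            ref, abs=1e-10)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            GateConfig(lam=-0.5)


class TestGradientsAndTraining:
    def test_gradients_match_finite_differences(self, small_graph):
        model = init_model(4, GateConfig(embedding_dim=3, lam=0.7, seed=1))
        _, genc, gdec = _loss_and_grads(model, small_graph)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for layers, grads in ((model.enc, genc), (model.dec, gdec)):
            for layer, grad in zip(layers, grads):
                for key in ("W", "vs", "vr"):
                    arr = layer[key]
                    flat = rng.choice(arr.size, size=min(6, arr.size),
                                      replace=False)
                    for f in flat:
                        idx = np.unravel_index(f, arr.shape)
                        orig = arr[idx]
                        arr[idx] = orig + eps
                        lp, *_ = _loss_and_grads(model, small_graph)
                        arr[idx] = orig - eps
                        lm, *_ = _loss_and_grads(model, small_graph)
                        arr[idx] = orig
                        num = (lp - lm) / (2 * eps)
                        assert grad[key][idx] == pytest.approx(num, abs=1e-6)

    def test_training_is_deterministic(self, small_graph):
        cfg = GateConfig(embedding_dim=3, epochs=30, seed=9)
        _, emb1, losses1 = train_gate(small_graph, cfg)
        _, emb2, losses2 = train_gate(small_graph, cfg)
        assert np.array_equal(losses1, losses2)
        assert np.array_equal(emb1.H, emb2.H)

    def test_training_reduces_loss(self, small_graph):
        _, _, losses = train_gate(
            small_graph, GateConfig(embedding_dim=3, epochs=100, seed=0))
        assert losses[-1] < losses[0]

    def test_default_embedding_width_is_64(self):
        sim = random_similarity(70, seed=1)
        rng = np.random.default_rng(2)
        graph = build_graph(sim, rng.random((70, 12)), 5)
        _, emb, _ = train_gate(graph, GateConfig(epochs=2, seed=0))
        assert emb.dim == 64

    def test_identical_nodes_get_identical_embeddings(self):
        # nodes 0 and 1: same attributes, same neighbor set {0,1,2}
        nbrs = [np.array([0, 1, 2]), np.array([0, 1, 2]),
                np.array([0, 1, 2]), np.array([2, 3])]
        mask = np.zeros((4, 4), dtype=bool)
        for i, nb in enumerate(nbrs):
            mask[i, nb] = True
        X = np.array([[0.5, 0.1], [0.5, 0.1], [0.2, 0.9], [0.8, 0.3]])
        graph = AttributedGraph(list("abcd"), nbrs, X, mask)
        _, emb, _ = train_gate(graph, GateConfig(embedding_dim=3, epochs=20,
                                                 seed=4))
        assert np.allclose(emb.H[0], emb.H[1], atol=1e-12)

    def test_stacked_layers_supported(self, small_graph):
        cfg = GateConfig(embedding_dim=3, hidden_dims=(6,), epochs=5, seed=0)
        model, emb, losses = train_gate(small_graph, cfg)
        assert len(model.enc) == len(model.dec) == 2
        assert emb.dim == 3
        assert np.isfinite(losses).all()


class TestPairFeatures:
    def _embs(self):
        rng = np.random.default_rng(0)
        emb_m = EmbeddingSet([f"m{j}" for j in range(4)], rng.random((4, 3)))
        emb_d = EmbeddingSet([f"d{i}" for i in range(3)], rng.random((3, 2)))
        return emb_m, emb_d

    def test_width_is_sum_of_dims(self):
        emb_m, emb_d = self._embs()
        ds = make_pair_features(emb_m, emb_d, [[0, 0], [2, 3]])
        assert ds.feature_width == 5

    def test_row_is_microbe_then_disease(self):
        emb_m, emb_d = self._embs()
        ds = make_pair_features(emb_m, emb_d, [[1, 2]])
        expected = np.concatenate([emb_m.H[2], emb_d.H[1]])
        assert np.array_equal(ds.X[0], expected)

    def test_default_dims_give_128(self):
        rng = np.random.default_rng(1)
        emb_m = EmbeddingSet([f"m{j}" for j in range(3)], rng.random((3, 64)))
        emb_d = EmbeddingSet([f"d{i}" for i in range(3)], rng.random((3, 64)))
        ds = make_pair_features(emb_m, emb_d, [[0, 0]])
        assert ds.feature_width == 128

    def test_unknown_index_errors(self):
        emb_m, emb_d = self._embs()
        with pytest.raises(IndexError, match="microbe"):
            make_pair_features(emb_m, emb_d, [[0, 9]])
        with pytest.raises(IndexError, match="disease"):
            make_pair_features(emb_m, emb_d, [[7, 0]])
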