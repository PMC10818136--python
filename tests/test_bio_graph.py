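"""Heterogeneous network construction and masked graph attention."""

import numpy as np
import pytest

from sagdti.autodiff import Tensor
from sagdti.bio_graph import (
    GATLayer,
    GATStack,
    HeteroGraph,
    build_hetero_graph,
    gat_layer,
    mask_test_edges,
    pool_pair,
)


def _toy_graph(n_d=2, n_t=2, interactions=(("d0", "t0"),), dsim=None, tsim=None, thr=0.5):
    drugs = [f"d{i}" for i in range(n_d)]
    targets = [f"t{i}" for i in range(n_t)]
    return build_hetero_graph(list(interactions), drugs, targets,
                              drug_sim=dsim, target_sim=tsim, sim_threshold=thr)


class TestBuildHeteroGraph:
    def test_interaction_edge_symmetric(self):
        g = _toy_graph()
        i, j = g.node_of("d0"), g.node_of("t0")
        assert g.interaction[i, j] and g.interaction[j, i]
        assert g.n_nodes == 4

    def test_vacuous_similarity_threshold_removes_all(self):
        dsim = np.array([[0.0, 0.9], [0.9, 0.0]])
        g = _toy_graph(dsim=dsim, thr=1.1)
        assert not (g.similarity > 0).any()

    def test_edge_count_matches_set_dedup_oracle(self, rng):
        drugs = [f"d{i}" for i in range(12)]
        targets = [f"t{i}" for i in range(8)]
        raw = [(drugs[rng.integers(12)], targets[rng.integers(8)]) for _ in range(40)]
        g = build_hetero_graph(raw, drugs, targets)
        assert g.interaction.sum() // 2 == len(set(raw))

    def test_dangling_id_listed_in_error(self):
        with pytest.raises(ValueError, match="dX"):
            _toy_graph(interactions=[("dX", "t0")])

    def test_asymmetric_similarity_symmetrized_with_warning(self):
        dsim = np.array([[0.0, 0.9], [0.7, 0.0]])
        with pytest.warns(UserWarning, match="symmetrized"):
            g = _toy_graph(dsim=dsim)
        i, j = g.node_of("d0"), g.node_of("d1")
        assert g.similarity[i, j] == pytest.approx(0.8)

    def test_node_features_schema(self):
        dsim = np.array([[0.0, 0.8], [0.8, 0.0]])
        g = _toy_graph(dsim=dsim)
        assert g.features.shape == (4, 2 + 1 + 16)
        assert g.features[g.node_of("d0"), 0] == 1.0  # drug type one-hot
        assert g.features[g.node_of("t0"), 1] == 1.0


class TestGATLayer:
    def test_single_neighbor_gets_weight_one(self, rng):
        g = _toy_graph()  # d0-t0 only interaction
        layer = GATLayer(g.features.shape[1], 4, heads=1, rng=rng)
        adj = g.adjacency(self_loops=False)
        a, _ = layer.attention(Tensor(g.features), adj, 0)
        i, j = g.node_of("d0"), g.node_of("t0")
        assert a.data[i, j] == pytest.approx(1.0)

    def test_zero_attention_vector_gives_uniform_weights(self, rng):
        dsim = np.array([[0, 0.9, 0.9], [0.9, 0, 0.9], [0.9, 0.9, 0]], dtype=float)
        g = _toy_graph(n_d=3, n_t=1, interactions=[], dsim=dsim)
        layer = GATLayer(g.features.shape[1], 4, heads=1, rng=rng)
        layer.a_src[0].data[:] = 0.0
        layer.a_dst[0].data[:] = 0.0
        adj = g.adjacency(self_loops=True)
        a = layer.attention(Tensor(g.features), adj, 0)[0].data
        deg = adj.sum(1)
        for i in range(g.n_nodes):
            nz = a[i][adj[i]]
            assert np.allclose(nz, 1.0 / deg[i], atol=1e-12)

    def test_matches_per_node_loop_oracle(self, rng):
        dsim = (rng.random((4, 4)) > 0.4).astype(float) * 0.9
        dsim = np.triu(dsim, 1) + np.triu(dsim, 1).T
        g = _toy_graph(n_d=4, n_t=1, interactions=[("d0", "t0")], dsim=dsim)
        layer = GATLayer(g.features.shape[1], 3, heads=2, rng=rng)
        got = gat_layer(g, layer)
        adj = g.adjacency(self_loops=True)
        h = g.features
        heads_out = []
        for k in range(2):
            w, asrc, adst = layer.W[k].data, layer.a_src[k].data, layer.a_dst[k].data
            hw = h @ w
            out = np.zeros((g.n_nodes, 3))
            for i in range(g.n_nodes):
                nbrs = np.flatnonzero(adj[i])
                e = np.array([asrc @ hw[i] + adst @ hw[j] for j in nbrs])
                e = np.where(e > 0, e, 0.2 * e)
                a = np.exp(e - e.max())
                a /= a.sum()
                agg = sum(a[t] * hw[j] for t, j in enumerate(nbrs))
                out[i] = np.where(agg > 0, agg, 0.2 * agg)
            heads_out.append(out)
        want = np.concatenate(heads_out, axis=1)
        assert np.abs(got - want).max() < 1e-6

    def test_non_neighbors_weight_exactly_zero(self, rng):
        g = _toy_graph()
        layer = GATLayer(g.features.shape[1], 4, heads=1, rng=rng)
        adj = g.adjacency(self_loops=True)
        a = layer.attention(Tensor(g.features), adj, 0)[0].data
        assert np.all(a[~adj] == 0.0)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-9)

    def test_isolated_node_defined_via_self_loop(self, rng):
        g = _toy_graph(n_d=2, n_t=2, interactions=[])
        stack = GATStack(g.features.shape[1], 4, heads=2, layers=2, rng=rng)
        out = stack.forward(g).data
        assert np.all(np.isfinite(out))


class TestPoolPair:
    def test_identical_embeddings_idempotent(self):
        g = _toy_graph()
        emb = np.tile(np.arange(4.0), (4, 1))
        assert np.allclose(pool_pair(emb, g, "d0", "t0"), emb[0])

    def test_max_dominance(self):
        g = _toy_graph()
        emb = np.full((4, 3), -1e12)
        i = g.node_of("d0")
        emb[i] = [1.0, 2.0, 3.0]
        assert np.allclose(pool_pair(emb, g, "d0", "t0"), [1.0, 2.0, 3.0])

    def test_coordinatewise_max(self, rng):
        g = _toy_graph()
        emb = rng.standard_normal((4, 6))
        got = pool_pair(emb, g, "d1", "t1")
        i, j = g.node_of("d1"), g.node_of("t1")
        for c in range(6):
            assert got[c] == max(emb[i, c], emb[j, c])

    def test_missing_node_errors(self):
        g = _toy_graph()
        with pytest.raises(KeyError, match="d9"):
            pool_pair(np.zeros((4, 2)), g, "d9", "t0")


class TestMaskTestEdges:
    def test_masking_only_interaction_edge_empties_interactions(self):
        g = _toy_graph()
        m = mask_test_edges(g, [("d0", "t0")])
        assert not m.interaction.any()
        assert np.array_equal(m.similarity, g.similarity)

    def test_empty_mask_is_identity(self):
        g = _toy_graph()
        m = mask_test_edges(g, [])
        assert np.array_equal(m.interaction, g.interaction)

    def test_masked_count_matches_set_difference(self, rng):
        drugs = [f"d{i}" for i in range(10)]
        targets = [f"t{i}" for i in range(5)]
        all_pairs = [(d, t) for d in drugs for t in targets]
        idx = rng.choice(len(all_pairs), size=50, replace=False)
        edges = [all_pairs[i] for i in idx]
        g = build_hetero_graph(edges, drugs, targets)
        masked = [edges[i] for i in rng.choice(50, size=10, replace=False)]
        m = mask_test_edges(g, masked)
        assert m.interaction.sum() // 2 == len(set(edges) - set(masked))


def test_locality_perturbation_beyond_receptive_field(rng):
    """A node >= L+1 hops from both endpoints cannot change their pooled
    embedding after L GAT layers."""
    # path: d0 - t0 - d1 - t1 - d2 ; pair (d0, t0); perturb d2 (3 hops from t0)
    drugs, targets = ["d0", "d1", "d2"], ["t0", "t1"]
    inter = [("d0", "t0"), ("d1", "t0"), ("d1", "t1"), ("d2", "t1")]
    g = build_hetero_graph(inter, drugs, targets)
    stack = GATStack(g.features.shape[1], 4, heads=2, layers=2, rng=rng)
    base = pool_pair(stack.forward(g).data, g, "d0", "t0")
    g2 = HeteroGraph(node_ids=g.node_ids, node_type=g.node_type, features=g.features.copy(),
                     interaction=g.interaction, similarity=g.similarity, index=dict(g.index))
    g2.features[g2.node_of("d2")] += 10.0
    pert = pool_pair(stack.forward(g2).data, g2, "d0", "t0")
    assert np.allclose(base, pert, atol=1e-12)


def test_gat_deterministic_given_seed():
    g = _toy_graph()
    outs = []
    for _ in range(2):
        stack = GATStack(g.features.shape[1], 4, heads=2, layers=2,
                         rng=np.random.default_rng(99))
        outs.append(stack.forward(g).data)
    assert np.array_equal(outs[0], outs[1])
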