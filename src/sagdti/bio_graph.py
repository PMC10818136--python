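"""Heterogeneous drug/target network and graph-attention aggregation.

Drugs and targets are nodes of one undirected graph whose edges mix three
kinds of biological evidence: known drug-target interactions, drug-drug
similarities and target-target similarities (similarity edges carry a weight
in [0, 1] and survive only above a threshold). Node features are
self-contained: a type one-hot, the degree normalized by the node count, and
a fixed-width slice of the node's similarity profile.

Masked multi-head graph attention (GAT) aggregates first-order neighborhoods:
attention logits e_ij = LeakyReLU(a . [W h_i || W h_j]) are computed for
neighbors only, softmax-normalized per node (non-neighbors get weight exactly
0), and head outputs are concatenated on hidden layers and averaged on the
final one. The biological attribute vector of a (drug, target) pair is the
element-wise maximum of the two endpoints' final embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, matmul, maximum, softmax

__all__ = [
    "HeteroGraph",
    "GATLayer",
    "GATStack",
    "build_hetero_graph",
    "gat_layer",
    "pool_pair",
    "mask_test_edges",
]

DRUG, TARGET = 0, 1


@dataclass
class HeteroGraph:
    """Undirected typed drug/target network with node features."""

    node_ids: list[str]
    node_type: np.ndarray  # (N,) 0=drug, 1=target
    features: np.ndarray  # (N, Z)
    interaction: np.ndarray  # (N, N) bool, symmetric
    similarity: np.ndarray  # (N, N) float weights in [0, 1], symmetric
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self, self_loops: bool = True) -> np.ndarray:
        a = self.interaction | (self.similarity > 0)
        if self_loops:
            a = a | np.eye(self.n_nodes, dtype=bool)
        return a

    def node_of(self, external_id: str) -> int:
        if external_id not in self.index:
            raise KeyError(f"unknown drug/target id {external_id!r}")
        return self.index[external_id]


def build_hetero_graph(
    interactions: list[tuple[str, str]],
    drug_ids: list[str],
    target_ids: list[str],
    drug_sim: np.ndarray | None = None,
    target_sim: np.ndarray | None = None,
    sim_threshold: float = 0.5,
    profile_width: int = 16,
) -> HeteroGraph:
    """Assemble the heterogeneous network.

    interactions: (drug_id, target_id) pairs (deduplicated, symmetrized).
    drug_sim / target_sim: square similarity matrices aligned with the id
    lists; values in [0, 1]. Asymmetric inputs are symmetrized (average) with
    a warning. Similarity edges below ``sim_threshold`` are dropped.
    Node features: [type one-hot (2) | degree / N | similarity-profile row
    truncated or zero-padded to ``profile_width``].
    """
    node_ids = list(drug_ids) + list(target_ids)
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("drug and target id lists overlap or contain duplicates")
    n_d, n_t = len(drug_ids), len(target_ids)
    n = n_d + n_t
    index = {nid: i for i, nid in enumerate(node_ids)}
    node_type = np.array([DRUG] * n_d + [TARGET] * n_t)

    inter = np.zeros((n, n), dtype=bool)
    dangling = sorted({d for d, t in interactions if d not in index}
                      | {t for d, t in interactions if t not in index})
    if dangling:
        raise ValueError(f"interaction edges reference unknown ids: {dangling}")
    for d, t in interactions:
        i, j = index[d], index[t]
        inter[i, j] = inter[j, i] = True
    np.fill_diagonal(inter, False)

    sim = np.zeros((n, n))

    def place(mat, ids, offset):
        m = np.asarray(mat, dtype=float)
        if m.shape != (len(ids), len(ids)):
            raise ValueError(f"similarity matrix shape {m.shape} does not match {len(ids)} ids")
        if not np.allclose(m, m.T):
            warnings.warn("asymmetric similarity matrix symmetrized by averaging")
            m = 0.5 * (m + m.T)
        m = np.clip(m, 0.0, 1.0)
        m = np.where(m >= sim_threshold, m, 0.0)
        np.fill_diagonal(m, 0.0)
        sim[offset : offset + len(ids), offset : offset + len(ids)] = m
        return m

    prof_d = place(drug_sim, drug_ids, 0) if drug_sim is not None else np.zeros((n_d, n_d))
    prof_t = place(target_sim, target_ids, n_d) if target_sim is not None else np.zeros((n_t, n_t))

    degree = (inter | (sim > 0)).sum(axis=1) / max(n, 1)

    def pad_profile(row):
        out = np.zeros(profile_width)
        k = min(profile_width, len(row))
        out[:k] = row[:k]
        return out

    feats = np.zeros((n, 2 + 1 + profile_width))
    for i in range(n):
        feats[i, node_type[i]] = 1.0
        feats[i, 2] = degree[i]
        row = prof_d[i] if i < n_d else prof_t[i - n_d]
        feats[i, 3:] = pad_profile(row)
    return HeteroGraph(node_ids=node_ids, node_type=node_type, features=feats,
                       interaction=inter, similarity=sim, index=index)


def mask_test_edges(graph: HeteroGraph, test_pairs: list[tuple[str, str]]) -> HeteroGraph:
    """Remove interaction edges of evaluation pairs from message passing
    (similarity edges are retained); absent edges are ignored."""
    inter = graph.interaction.copy()
    for d, t in test_pairs:
        if d in graph.index and t in graph.index:
            i, j = graph.index[d], graph.index[t]
            inter[i, j] = inter[j, i] = False
    feats = graph.features.copy()
    # degree feature recomputed so held-out edges leave no trace
    feats[:, 2] = (inter | (graph.similarity > 0)).sum(axis=1) / max(graph.n_nodes, 1)
    return HeteroGraph(node_ids=graph.node_ids, node_type=graph.node_type,
                       features=feats, interaction=inter,
                       similarity=graph.similarity, index=dict(graph.index))


class GATLayer:
    """One masked multi-head graph-attention layer.

    Per head k: e_ij = LeakyReLU(a_src . W_k h_i + a_dst . W_k h_j) over the
    first-order neighborhood (plus a self-loop so isolated nodes stay
    defined); a_ij = softmax_j(e_ij); output_k = beta(sum_j a_ij W_k h_j)
    with beta = LeakyReLU. Heads concatenate (``merge='concat'``) or average
    (``merge='mean'``, standard for output layers).
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int, rng: np.random.Generator,
                 slope: float = 0.2, merge: str = "concat", prefix: str = "gat"):
        self.heads, self.slope, self.merge = heads, slope, merge
        s = 1.0 / np.sqrt(in_dim)
        self.W = [Tensor(rng.normal(0.0, s, (in_dim, out_dim)), requires_grad=True,
                         name=f"{prefix}.W{k}") for k in range(heads)]
        # attention vector alpha (length 2*out_dim) split into source/dest halves
        self.a_src = [Tensor(rng.normal(0.0, 1.0 / np.sqrt(out_dim), (out_dim,)), requires_grad=True,
                             name=f"{prefix}.a_src{k}") for k in range(heads)]
        self.a_dst = [Tensor(rng.normal(0.0, 1.0 / np.sqrt(out_dim), (out_dim,)), requires_grad=True,
                             name=f"{prefix}.a_dst{k}") for k in range(heads)]

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.a_src, *self.a_dst]

    def attention(self, h: Tensor, adj: np.ndarray, head: int) -> tuple[Tensor, Tensor]:
        """Returns (attention matrix (N, N), transformed features (N, out))."""
        hw = matmul(h, self.W[head])
        s_src = matmul(hw, self.a_src[head])  # (N,)
        s_dst = matmul(hw, self.a_dst[head])
        n = adj.shape[0]
        e = (s_src.reshape(n, 1) + s_dst.reshape(1, n)).leaky_relu(self.slope)
        a = softmax(e, axis=-1, mask=adj)  # exact zeros outside the neighborhood
        return a, hw

    def forward(self, h: Tensor, adj: np.ndarray) -> Tensor:
        outs = []
        for k in range(self.heads):
            a, hw = self.attention(h, adj, k)
            outs.append(matmul(a, hw).leaky_relu(self.slope))
        if self.merge == "concat":
            return concat(outs, axis=-1)
        out = outs[0]
        for o in outs[1:]:
            out = out + o
        return out * (1.0 / self.heads)


class GATStack:
    """Consecutive GAT layers over the heterogeneous graph."""

    def __init__(self, in_dim: int, hidden_dim: int, heads: int, layers: int,
                 rng: np.random.Generator, slope: float = 0.2,
                 final_merge: str = "mean", prefix: str = "gat"):
        if layers < 1:
            raise ValueError("need at least one GAT layer")
        self.layers: list[GATLayer] = []
        dim = in_dim
        for i in range(layers):
            last = i == layers - 1
            merge = final_merge if last else "concat"
            self.layers.append(GATLayer(dim, hidden_dim, heads, rng, slope=slope,
                                        merge=merge, prefix=f"{prefix}{i}"))
            dim = hidden_dim * (1 if merge == "mean" else heads)
        self.out_dim = dim

    def parameters(self) -> list[Tensor]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, graph: HeteroGraph, features: np.ndarray | Tensor | None = None) -> Tensor:
        h = features if isinstance(features, Tensor) else Tensor(
            graph.features if features is None else features)
        adj = graph.adjacency(self_loops=True)
        for layer in self.layers:
            h = layer.forward(h, adj)
        return h


def gat_layer(graph: HeteroGraph, layer: GATLayer,
              features: np.ndarray | None = None) -> np.ndarray:
    """Run one GAT layer over the graph; returns updated node features."""
    h = Tensor(graph.features if features is None else features)
    if not np.all(np.isfinite(h.data)):
        raise FloatingPointError("non-finite node features")
    return layer.forward(h, graph.adjacency(self_loops=True)).data


def pool_pair(node_embeddings: Tensor | np.ndarray, graph: HeteroGraph,
              drug_id: str, target_id: str, mode: str = "endpoints"):
    """Biological attribute vector of one pair: element-wise max of the two
    endpoint embeddings (``mode='endpoints'``), or of the union of their
    1-hop neighborhoods (``mode='neighborhood'``)."""
    i, j = graph.node_of(drug_id), graph.node_of(target_id)
    emb = node_embeddings if isinstance(node_embeddings, Tensor) else Tensor(node_embeddings)
    if mode == "endpoints":
        out = maximum(emb[i], emb[j])
    elif mode == "neighborhood":
        adj = graph.adjacency(self_loops=True)
        nodes = np.flatnonzero(adj[i] | adj[j])
        out = emb.take(nodes).max(axis=0)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return out if isinstance(node_embeddings, Tensor) else out.data
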