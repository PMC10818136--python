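"""End-to-end interaction classifier: fusion head, loss, training loop.

The model fuses two attribute vectors per (drug, target) pair:

* ``X_Mol`` — molecular attributes: both branches are encoded by transformer
  stacks (the drug branch biased by the relative-aware relationship matrix,
  the protein branch by the pocket adjacency), combined into the interaction
  pairing map and read out by a zero-padded convolution;
* ``X_Bio`` — biological attributes: masked multi-head graph attention over
  the heterogeneous drug/target network, max-pooled over the pair endpoints.

The concatenation ``X_Ult = [X_Mol ; X_Bio]`` is reshaped to a two-row map,
passed through a convolution-pooling block and a small fully connected head,
and squashed by a sigmoid into an interaction score. Training minimizes
binary cross-entropy with Adam; early stopping watches validation AUPR.

Ablation variants (structural switches on :class:`~sagdti.config.ModelConfig`):
``no_gat`` removes ``X_Bio`` entirely, ``no_3d`` replaces pocket atom graphs
with a plain residue-token sequence, ``no_rel`` zeroes the relative matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, matmul, maximum
from .bio_graph import GATStack, HeteroGraph, mask_test_edges
from .config import ModelConfig, TrainConfig
from .drug_encoder import DrugEmbedder, DrugEmbeddingConfig, DrugSequence, tokenize
from .evaluation import PairRecord, compute_metrics
from .molecular_transformer import ConvReadout, EncoderStack, pairing_map
from .synthetic_data import SyntheticDataset

__all__ = ["PreparedData", "prepare", "DTIModel", "bce_loss", "fuse", "train", "fit", "FitResult"]

CHECKPOINT_SCHEMA = 1


# ---------------------------------------------------------------------------
# dataset adapter
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    """Dataset tensors keyed by external ids, shaped for one ModelConfig."""

    drug_seqs: dict[str, DrugSequence]
    protein_feats: dict[str, np.ndarray]  # (protein_max_tokens, K_FEAT)
    protein_adj: dict[str, np.ndarray]  # (protein_max_tokens,) x same, bool
    protein_mask: dict[str, np.ndarray]  # (protein_max_tokens,) bool
    residue_tokens: dict[str, np.ndarray]  # (protein_max_tokens,) int, for no_3d
    residue_vocab: dict[str, int]
    graph: HeteroGraph
    config: ModelConfig


def prepare(dataset: SyntheticDataset, config: ModelConfig) -> PreparedData:
    """Tokenize drugs, flatten pocket graphs to fixed-size token inputs and
    build the residue-token fallback used by the ``no_3d`` variant."""
    dcfg = DrugEmbeddingConfig(max_len=config.drug_max_len, hidden_dim=config.hidden_dim,
                               clip=config.clip, denominator=config.denominator)
    drug_seqs = {d.drug_id: tokenize(d.smiles, dcfg) for d in dataset.drugs}

    n_tok = config.protein_max_tokens
    from .protein_encoder import K_FEAT

    feats: dict[str, np.ndarray] = {}
    adjs: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    res_tokens: dict[str, np.ndarray] = {}
    res_vocab: dict[str, int] = {"<pad>": 0}
    for t in dataset.targets:
        x = np.zeros((n_tok, K_FEAT))
        a = np.zeros((n_tok, n_tok), dtype=bool)
        m = np.zeros(n_tok, dtype=bool)
        ofs = 0
        for g in t.sites[: config.max_sites]:
            k = min(g.n_atoms, config.max_atoms_per_site, n_tok - ofs)
            if k <= 0:
                break
            x[ofs : ofs + k] = g.features[:k]
            a[ofs : ofs + k, ofs : ofs + k] = g.adjacency()[:k, :k]
            m[ofs : ofs + k] = True
            ofs += k
        feats[t.target_id] = x
        adjs[t.target_id] = a
        masks[t.target_id] = m
        ids = np.zeros(n_tok, dtype=np.int64)
        for i, rn in enumerate(t.residue_names[:n_tok]):
            if rn not in res_vocab:
                res_vocab[rn] = len(res_vocab)
            ids[i] = res_vocab[rn]
        res_tokens[t.target_id] = ids
    return PreparedData(drug_seqs=drug_seqs, protein_feats=feats, protein_adj=adjs,
                        protein_mask=masks, residue_tokens=res_tokens,
                        residue_vocab=res_vocab, graph=dataset.graph, config=config)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def fuse(x_mol: Tensor, x_bio: Tensor | None) -> Tensor:
    """X_Ult = [X_Mol ; X_Bio] (molecular part first); without the biological
    branch the fused vector is X_Mol alone."""
    if x_bio is None:
        return x_mol
    return concat([x_mol, x_bio], axis=-1)


def bce_loss(scores: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped at eps for stability."""
    labels = np.asarray(labels, dtype=np.float64)
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    p = scores.clip_probs(eps)
    y = Tensor(labels)
    ll = y * p.log() + (1.0 - y) * (1.0 - p).log()
    return -ll.mean()


class DTIModel:
    """All learnable parameters plus the pair-scoring forward pass."""

    def __init__(self, config: ModelConfig, data: PreparedData, seed: int = 0):
        self.config = config
        self.data = data
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = config.hidden_dim

        dcfg = DrugEmbeddingConfig(max_len=config.drug_max_len, hidden_dim=d,
                                   clip=config.clip, denominator=config.denominator)
        self.drug_embedder = DrugEmbedder(dcfg, rng)
        self.drug_stack = EncoderStack(d, config.drug_heads, config.encoder_depth, rng,
                                       fnn_mult=config.fnn_mult, prefix="denc")

        from .protein_encoder import K_FEAT

        s = 1.0 / np.sqrt(K_FEAT)
        self.W_P = Tensor(rng.normal(0.0, s, (d, K_FEAT)), requires_grad=True, name="W_P")
        self.gamma = Tensor(np.array(1.0), requires_grad=True, name="gamma")
        self.protein_stack = EncoderStack(d, config.protein_heads, config.encoder_depth, rng,
                                          fnn_mult=config.fnn_mult, prefix="penc")
        n_res = max(len(data.residue_vocab), 2)
        self.E_res = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (n_res, d)), requires_grad=True, name="E_res")
        self.E_res_pos = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (config.protein_max_tokens, d)),
                                requires_grad=True, name="E_res_pos")

        self.im_readout = ConvReadout(config.n_filters, rng, filter_size=config.filter_size,
                                      pool=config.im_pool, prefix="imconv")

        z = data.graph.features.shape[1]
        self.gat = GATStack(z, config.gat_hidden, config.gat_heads, config.gat_layers, rng,
                            slope=config.gat_slope, final_merge=config.gat_final_merge, prefix="gat")

        # fused-head geometry is fixed by the config
        ld, lp = config.drug_max_len, config.protein_max_tokens
        self.x_mol_len = self.im_readout.out_len(ld, lp)
        bio_len = self.gat.out_dim if config.use_gat else 0
        ult = self.x_mol_len + bio_len
        self.ult_pad = (-ult) % 2 if config.head_reshape == "2rows" else 0
        rows = 2 if config.head_reshape == "2rows" else 1
        width = (ult + self.ult_pad) // rows
        self.head_rows = rows
        self.head_conv = ConvReadout(config.head_filters, rng, filter_size=config.filter_size,
                                     pool=config.pool, prefix="headconv")
        flat = config.head_filters * max(rows // config.pool, 1) * (width // config.pool)
        dims = [flat, *config.head_fnn]
        self.head_W: list[Tensor] = []
        self.head_b: list[Tensor] = []
        for i in range(len(dims) - 1):
            self.head_W.append(Tensor(rng.normal(0.0, 1.0 / np.sqrt(dims[i]), (dims[i], dims[i + 1])),
                                      requires_grad=True, name=f"head.W{i}"))
            self.head_b.append(Tensor(np.zeros(dims[i + 1]), requires_grad=True, name=f"head.b{i}"))
        self.w_out = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dims[-1]), (dims[-1],)),
                            requires_grad=True, name="head.w_out")
        self.b_out = Tensor(np.array(0.0), requires_grad=True, name="head.b_out")

        self._train_graph: HeteroGraph = data.graph

    # ------------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = list(self.drug_embedder.parameters().values())
        ps += self.drug_stack.parameters()
        cfg = self.config
        if cfg.use_3d:
            ps += [self.W_P]
            if cfg.protein_graph_bias == "adjacency":
                ps += [self.gamma]
        else:
            ps += [self.E_res, self.E_res_pos]
        ps += self.protein_stack.parameters()
        ps += self.im_readout.parameters()
        if cfg.use_gat:
            ps += self.gat.parameters()
        ps += self.head_conv.parameters()
        ps += self.head_W + self.head_b + [self.w_out, self.b_out]
        return ps

    def set_message_graph(self, graph: HeteroGraph):
        """Graph used for GAT message passing (evaluation interaction edges
        should be masked out of it)."""
        self._train_graph = graph

    # ------------------------------------------------------------------
    def _encode_drugs(self, drug_ids: list[str]) -> tuple[Tensor, np.ndarray]:
        seqs = [self.data.drug_seqs[d] for d in drug_ids]
        emb = self.drug_embedder
        ids, pad, atom = emb.pad_batch(seqs)
        x = emb.token_embedding(ids, pad)
        if self.config.use_rel:
            a_r = emb.relative_matrix(x, atom)
        else:
            a_r = None
        q = matmul(x, emb.W_Q)
        k = matmul(x, emb.W_K)
        v = matmul(x, emb.W_V)
        logits = matmul(q, k.transpose(0, 2, 1))
        if a_r is not None:
            logits = logits + a_r
        from .autodiff import softmax

        attn = softmax(logits * (1.0 / emb.config.scale), axis=-1, mask=pad[:, None, :])
        d_in = matmul(attn, v)
        d_r = self.drug_stack.forward(d_in, bias=a_r, key_mask=pad)
        return d_r, pad

    def _encode_proteins(self, target_ids: list[str]) -> tuple[Tensor, np.ndarray]:
        data, cfg = self.data, self.config
        mask = np.stack([data.protein_mask[t] for t in target_ids])
        if cfg.use_3d:
            feats = np.stack([data.protein_feats[t] for t in target_ids])
            x = matmul(Tensor(feats), self.W_P.T)
            bias = None
            if cfg.protein_graph_bias == "adjacency":
                adj = np.stack([data.protein_adj[t] for t in target_ids]).astype(np.float64)
                bias = self.gamma * Tensor(adj)
        else:
            ids = np.stack([data.residue_tokens[t] for t in target_ids])
            b, n = ids.shape
            rmask = ids > 0
            x = self.E_res.take(ids.ravel()).reshape(b, n, cfg.hidden_dim) + self.E_res_pos[:n]
            x = x * Tensor(rmask[..., None].astype(np.float64))
            mask = rmask
            bias = None
        p_r = self.protein_stack.forward(x, bias=bias, key_mask=mask)
        return p_r, mask

    def forward(self, pairs: list[tuple[str, str]], train: bool = False,
                dropout_rng: np.random.Generator | None = None,
                dropout: float = 0.0) -> Tensor:
        """Interaction logits for a batch of (drug_id, target_id) pairs."""
        cfg = self.config
        drugs = sorted({d for d, _ in pairs})
        targets = sorted({t for _, t in pairs})
        for d, t in pairs:
            if d not in self.data.drug_seqs:
                raise KeyError(f"unknown drug id {d!r}")
            if t not in self.data.protein_mask:
                raise KeyError(f"unknown target id {t!r}")
        d_pos = {d: i for i, d in enumerate(drugs)}
        t_pos = {t: i for i, t in enumerate(targets)}
        d_r, d_mask = self._encode_drugs(drugs)
        p_r, p_mask = self._encode_proteins(targets)

        di = np.array([d_pos[d] for d, _ in pairs])
        ti = np.array([t_pos[t] for _, t in pairs])
        im = pairing_map(d_r.take(di), p_r.take(ti), row_mask=d_mask[di], col_mask=p_mask[ti],
                         transform=cfg.map_transform)
        x_mol = self.im_readout.forward(im)

        x_bio = None
        if cfg.use_gat:
            node_emb = self.gat.forward(self._train_graph)
            g = self._train_graph
            dn = np.array([g.node_of(d) for d, _ in pairs])
            tn = np.array([g.node_of(t) for _, t in pairs])
            x_bio = maximum(node_emb.take(dn), node_emb.take(tn))

        x_ult = fuse(x_mol, x_bio)
        b = x_ult.shape[0]
        if self.ult_pad:
            x_ult = concat([x_ult, Tensor(np.zeros((b, self.ult_pad)))], axis=-1)
        width = x_ult.shape[1] // self.head_rows
        x = x_ult.reshape(b, 1, self.head_rows, width)
        x = self.head_conv.forward(x)
        for w, bb in zip(self.head_W, self.head_b):
            x = (matmul(x, w) + bb).relu()
            if train and dropout > 0.0:
                keep = (dropout_rng.random(x.shape) >= dropout).astype(np.float64)
                x = x * Tensor(keep / (1.0 - dropout))
        logit = matmul(x, self.w_out) + self.b_out
        return logit

    def predict(self, pairs: list[tuple[str, str]], batch_size: int = 256) -> np.ndarray:
        """Interaction scores in (0, 1), deterministic in eval mode."""
        out = []
        for i in range(0, len(pairs), batch_size):
            logit = self.forward(pairs[i : i + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-logit.data)))
        return np.concatenate(out) if out else np.array([])

    def interaction_map(self, drug_id: str, target_id: str):
        """Atom-level interpretability: the pairing map of one pair, with the
        raw scalar products and the validity masks."""
        from .molecular_transformer import InteractionMap

        d_r, d_mask = self._encode_drugs([drug_id])
        p_r, p_mask = self._encode_proteins([target_id])
        raw = pairing_map(d_r, p_r, transform="raw").data[0]
        im = pairing_map(d_r, p_r, row_mask=d_mask, col_mask=p_mask,
                         transform=self.config.map_transform).data[0]
        return InteractionMap(IM=im, raw=raw, row_mask=d_mask[0], col_mask=p_mask[0])

    # ------------------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def save(self, path):
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = json.dumps({"schema": CHECKPOINT_SCHEMA, "seed": self.seed,
                           "config": self.config.to_dict()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    def load(self, path):
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"checkpoint schema {meta['schema']} unsupported")
            params = self.parameters()
            for i, p in enumerate(params):
                arr = z[f"param_{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
                p.data = arr.copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: DTIModel
    history: dict[str, list[float]]
    best_epoch: int
    val_report: dict | None = None


def train(model: DTIModel, train_pairs: list[PairRecord], val_pairs: list[PairRecord],
          tcfg: TrainConfig) -> FitResult:
    """Minibatch Adam on BCE; keeps the best-validation-AUPR parameters.

    Fully reproducible given ``tcfg.seed`` (single-threaded, NumPy only).
    Aborts with diagnostics if the loss goes non-finite.
    """
    rng = np.random.default_rng(tcfg.seed)
    drop_rng = np.random.default_rng(tcfg.seed + 1)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_auroc": [], "val_aupr": []}
    best = (-np.inf, 0, None)  # (val aupr, epoch, params snapshot)
    vp = [(r.drug_id, r.target_id) for r in val_pairs]
    vy = np.array([r.label for r in val_pairs])
    stale = 0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = [train_pairs[i] for i in order[start : start + tcfg.batch_size]]
            pairs = [(r.drug_id, r.target_id) for r in batch]
            y = np.array([r.label for r in batch])
            logit = model.forward(pairs, train=True, dropout_rng=drop_rng, dropout=tcfg.dropout)
            loss = bce_loss(logit.sigmoid(), y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // tcfg.batch_size} "
                    f"(lr={tcfg.learning_rate})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if vp:
            scores = model.predict(vp)
            vl = float(-(vy * np.log(np.clip(scores, 1e-7, 1)) +
                         (1 - vy) * np.log(np.clip(1 - scores, 1e-7, 1))).mean())
            rep = compute_metrics(scores, vy)
            history["val_loss"].append(vl)
            history["val_auroc"].append(rep.auroc)
            history["val_aupr"].append(rep.aupr)
            crit = rep.aupr if np.isfinite(rep.aupr) else -vl
            if crit > best[0]:
                best = (crit, epoch, [p.data.copy() for p in model.parameters()])
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.patience:
                    break
        if tcfg.verbose:
            msg = f"epoch {epoch}: train_loss={history['train_loss'][-1]:.4f}"
            if vp:
                msg += f" val_auroc={history['val_auroc'][-1]:.3f} val_aupr={history['val_aupr'][-1]:.3f}"
            print(msg)
    if best[2] is not None:
        for p, arr in zip(model.parameters(), best[2]):
            p.data = arr
    report = None
    if vp:
        report = compute_metrics(model.predict(vp), vy).as_dict()
    return FitResult(model=model, history=history, best_epoch=best[1], val_report=report)


def fit(dataset: SyntheticDataset, config: ModelConfig, tcfg: TrainConfig,
        train_pairs: list[PairRecord], val_pairs: list[PairRecord]) -> FitResult:
    """Prepare the dataset for ``config``, mask validation interaction edges
    out of the message-passing graph, build the model and train it."""
    data = prepare(dataset, config)
    model = DTIModel(config, data, seed=tcfg.seed)
    masked = mask_test_edges(dataset.graph, [(r.drug_id, r.target_id) for r in val_pairs])
    model.set_message_graph(masked)
    return train(model, train_pairs, val_pairs, tcfg)
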