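"""Molecular transformer: shared encoder stacks, interaction pairing map and
convolutional readout.

Both branches (drug tokens, concatenated pocket atoms) run through stacks of
multi-head self-attention + feed-forward blocks with residual connections and
post-norm layer normalization. An optional additive bias enters every
attention logit: the relative-aware relationship matrix on the drug side, a
scaled graph adjacency on the protein side.

The two encoded branches meet in the *interaction pairing map* IM: the matrix
of scalar products between every drug token and every protein token. The raw
product is unbounded, so by default entries are squashed with a scaled sigmoid
to land in [0, 1] — an entry near 1 reads as "these two atoms plausibly bind".
A 2-D convolution with zero padding, ReLU and optional pooling then flattens
the map into the molecular attribute vector X_Mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d, layer_norm, matmul, max_pool2d, softmax

__all__ = ["EncoderStack", "InteractionMap", "ConvReadout", "pairing_map"]


class EncoderBlock:
    """One MSA + FNN encoder block (post-norm, residual)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 fnn_mult: int = 4, prefix: str = "enc"):
        if dim % heads != 0:
            raise ValueError(f"hidden dim {dim} not divisible by head count {heads}")
        self.dim, self.heads = dim, heads
        self.head_dim = dim // heads
        s = 1.0 / np.sqrt(dim)
        inner = fnn_mult * dim

        def p(name, shape, scale=s):
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True, name=f"{prefix}.{name}")

        self.W_Q = p("W_Q", (dim, dim))
        self.W_K = p("W_K", (dim, dim))
        self.W_V = p("W_V", (dim, dim))
        self.W_O = p("W_O", (dim, dim))
        self.W_1 = p("W_1", (dim, inner))
        self.b_1 = Tensor(np.zeros(inner), requires_grad=True, name=f"{prefix}.b_1")
        self.W_2 = p("W_2", (inner, dim), scale=1.0 / np.sqrt(inner))
        self.b_2 = Tensor(np.zeros(dim), requires_grad=True, name=f"{prefix}.b_2")
        self.ln1_g = Tensor(np.ones(dim), requires_grad=True, name=f"{prefix}.ln1_g")
        self.ln1_b = Tensor(np.zeros(dim), requires_grad=True, name=f"{prefix}.ln1_b")
        self.ln2_g = Tensor(np.ones(dim), requires_grad=True, name=f"{prefix}.ln2_g")
        self.ln2_b = Tensor(np.zeros(dim), requires_grad=True, name=f"{prefix}.ln2_b")

    def parameters(self) -> list[Tensor]:
        return [self.W_Q, self.W_K, self.W_V, self.W_O, self.W_1, self.b_1,
                self.W_2, self.b_2, self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]

    def msa(self, x: Tensor, bias: Tensor | np.ndarray | None, key_mask: np.ndarray | None) -> Tensor:
        """Multi-head self-attention with optional additive logit bias."""
        b, n, d = x.shape
        h, hd = self.heads, self.head_dim

        def split(t):  # (b, n, d) -> (b, h, n, hd)
            return t.reshape(b, n, h, hd).transpose(0, 2, 1, 3)

        q = split(matmul(x, self.W_Q))
        k = split(matmul(x, self.W_K))
        v = split(matmul(x, self.W_V))
        logits = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if bias is not None:
            bias_t = bias if isinstance(bias, Tensor) else Tensor(bias)
            logits = logits + bias_t.reshape(b, 1, n, n)
        mask = None if key_mask is None else key_mask[:, None, None, :]
        attn = softmax(logits, axis=-1, mask=mask)
        out = matmul(attn, v)  # (b, h, n, hd)
        out = out.transpose(0, 2, 1, 3).reshape(b, n, d)
        return matmul(out, self.W_O)

    def forward(self, x: Tensor, bias, key_mask) -> Tensor:
        a = layer_norm(self.msa(x, bias, key_mask) + x, self.ln1_g, self.ln1_b)
        f = matmul(a, self.W_1) + self.b_1
        f = matmul(f.relu(), self.W_2) + self.b_2
        return layer_norm(f + a, self.ln2_g, self.ln2_b)


class EncoderStack:
    """L stacked encoder blocks; each block output is residually added."""

    def __init__(self, dim: int, heads: int, depth: int, rng: np.random.Generator,
                 fnn_mult: int = 4, prefix: str = "enc"):
        if depth < 1:
            raise ValueError("encoder depth must be >= 1")
        self.blocks = [EncoderBlock(dim, heads, rng, fnn_mult, prefix=f"{prefix}{i}") for i in range(depth)]

    def parameters(self) -> list[Tensor]:
        return [p for blk in self.blocks for p in blk.parameters()]

    def forward(self, x: Tensor, bias=None, key_mask: np.ndarray | None = None) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError("non-finite encoder input")
        for blk in self.blocks:
            x = blk.forward(x, bias, key_mask) + x
        return x


def encode(x: Tensor, bias, stack: EncoderStack, key_mask: np.ndarray | None = None) -> Tensor:
    return stack.forward(x, bias=bias, key_mask=key_mask)


@dataclass
class InteractionMap:
    """Pairwise drug-token x protein-token scores with validity masks."""

    IM: np.ndarray  # (n_drug, n_prot), transformed scores
    raw: np.ndarray  # untransformed scalar products
    row_mask: np.ndarray
    col_mask: np.ndarray


def pairing_map(d_r: Tensor, p_r: Tensor, row_mask: np.ndarray | None = None,
                col_mask: np.ndarray | None = None, transform: str = "sigmoid") -> Tensor:
    """Interaction pairing map between encoded drug and protein tokens.

    d_r: (b, n_d, dim); p_r: (b, n_p, dim). The raw score is the scalar
    product of the two token embeddings; with ``transform='sigmoid'`` the
    stored entry is sigmoid(raw / sqrt(dim)) in [0, 1]; ``'raw'`` keeps the
    literal scalar product. Masked entries are exactly 0.
    """
    if d_r.shape[-1] != p_r.shape[-1]:
        raise ValueError(f"hidden-dimension mismatch: drug {d_r.shape[-1]} vs protein {p_r.shape[-1]}")
    dim = d_r.shape[-1]
    raw = matmul(d_r, p_r.transpose(0, 2, 1))  # (b, n_d, n_p)
    if transform == "sigmoid":
        im = (raw * (1.0 / np.sqrt(dim))).sigmoid()
    elif transform == "raw":
        im = raw
    else:
        raise ValueError(f"unknown map transform {transform!r}")
    if row_mask is not None or col_mask is not None:
        b, nd, npp = im.shape
        rm = np.ones((b, nd), dtype=bool) if row_mask is None else row_mask
        cm = np.ones((b, npp), dtype=bool) if col_mask is None else col_mask
        im = im * Tensor((rm[:, :, None] & cm[:, None, :]).astype(np.float64))
    return im


class ConvReadout:
    """Zero-padded 2-D convolution + ReLU + pooling + flatten.

    ``pool`` is a window size (max pooling, e.g. 2), ``'global'`` (per-channel
    max over the whole map — position-invariant, one value per filter), or
    0/None for flatten-direct.
    """

    def __init__(self, n_filters: int, rng: np.random.Generator, filter_size: tuple[int, int] = (3, 3),
                 pool: int | str | None = 2, in_channels: int = 1, prefix: str = "conv"):
        kh, kw = filter_size
        fan_in = in_channels * kh * kw
        self.filters = Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in), (n_filters, in_channels, kh, kw)),
                              requires_grad=True, name=f"{prefix}.filters")
        self.bias = Tensor(np.zeros(n_filters), requires_grad=True, name=f"{prefix}.bias")
        self.pool = pool
        self.n_filters = n_filters

    def parameters(self) -> list[Tensor]:
        return [self.filters, self.bias]

    def out_len(self, h: int, w: int) -> int:
        """Flattened output length for an h x w single-channel input."""
        if self.pool == "global":
            return self.n_filters
        if self.pool and int(self.pool) > 1:
            return self.n_filters * (h // int(self.pool)) * (w // int(self.pool))
        return self.n_filters * h * w

    def forward(self, im: Tensor, activation: str = "relu", flatten: bool = True) -> Tensor:
        if im.ndim == 3:  # (b, H, W) single-channel map
            b, h, w = im.shape
            im = im.reshape(b, 1, h, w)
        y = conv2d(im, self.filters, self.bias, padding="same")
        if activation == "relu":
            y = y.relu()
        elif activation != "linear":
            raise ValueError(f"unknown activation {activation!r}")
        if self.pool == "global":
            b, c, h, w = y.shape
            return y.reshape(b, c, h * w).max(axis=2)
        if self.pool and int(self.pool) > 1:
            y = max_pool2d(y, int(self.pool))
        if flatten:
            b = y.shape[0]
            y = y.reshape(b, int(np.prod(y.shape[1:])))
        return y


def conv_readout(im: Tensor, readout: ConvReadout, activation: str = "relu") -> Tensor:
    """Molecular attribute vector X_Mol from an interaction map."""
    return readout.forward(im, activation=activation)
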