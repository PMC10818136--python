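"""Drug branch input: SMILES tokenization and relative-distance-aware embedding.

A drug is a SMILES string. It is tokenized at the character level (with
two-character lookahead so ``Cl`` and ``Br`` are single atom tokens) against a
fixed, versioned vocabulary shipped with the package. The input embedding adds
a learned token table and a learned positional table, then applies one
relative-position self-attention block: attention logits receive an additive
relationship matrix ``A_R`` whose entry (i, j) is the dot product of token i's
query with a learned vector indexed by the clipped token distance
``min(clip, |i - j|)``. Rows and columns of ``A_R`` at *virtual* tokens
(brackets, bond symbols, ring digits, padding) are exactly zero, so relative
distance is modelled between chemical atoms only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .autodiff import Tensor, matmul, softmax

__all__ = [
    "Vocabulary",
    "DrugSequence",
    "DrugEmbeddingConfig",
    "DrugInputEmbedding",
    "TokenizationError",
    "load_default_vocab",
    "tokenize",
    "build_relative_matrix",
    "embed_drug",
    "DrugEmbedder",
]

PAD_ID = 0


class TokenizationError(ValueError):
    """Raised when a SMILES string contains a character outside the vocabulary."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token -> id table; ids are contiguous from 0 (0 is padding)."""

    tokens: tuple[str, ...]
    atom_tokens: frozenset[str]
    version: int = 1

    def __post_init__(self):
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def id_of(self, token: str) -> int:
        return self._index[token]

    def __contains__(self, token: str) -> bool:
        return token in self._index


def load_default_vocab() -> Vocabulary:
    with resources.files("sagdti.data").joinpath("smiles_vocab.json").open() as f:
        raw = json.load(f)
    return Vocabulary(tokens=tuple(raw["tokens"]), atom_tokens=frozenset(raw["atom_tokens"]),
                      version=raw["version"])


@dataclass
class DrugEmbeddingConfig:
    """Hyperparameters of the drug input embedding.

    max_len: maximum SMILES token length (sequences are truncated).
    hidden_dim: embedding width.
    clip: relative-distance clip constant; the relation table has clip+1 rows.
    denominator: 'sqrt_dim' scales attention logits by sqrt(hidden_dim)
        (standard scaled attention); 'dim' divides by hidden_dim literally.
    """

    max_len: int = 150
    hidden_dim: int = 64
    clip: int = 5
    denominator: str = "sqrt_dim"
    vocab: Vocabulary = field(default_factory=load_default_vocab)

    def __post_init__(self):
        if self.max_len < 1 or self.hidden_dim < 1 or self.clip < 1:
            raise ValueError("max_len, hidden_dim and clip must all be >= 1")
        if self.denominator not in ("sqrt_dim", "dim"):
            raise ValueError(f"unknown denominator mode {self.denominator!r}")

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.hidden_dim)) if self.denominator == "sqrt_dim" else float(self.hidden_dim)


@dataclass
class DrugSequence:
    """Tokenized SMILES: integer ids plus a per-token chemical-atom mask."""

    tokens: np.ndarray  # (n,) int ids, n <= max_len
    raw: str
    atom_mask: np.ndarray  # (n,) bool, True iff token is a chemical atom

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class DrugInputEmbedding:
    """Output of the drug input block, padded to max_len."""

    X_D: np.ndarray  # (max_len, d) token+position embedding
    A_R: np.ndarray  # (max_len, max_len) relative-aware relationship matrix
    D_In: np.ndarray  # (max_len, d) relative-attention output
    pad_mask: np.ndarray  # (max_len,) True at real tokens


_TWO_CHAR = ("Cl", "Br")


def tokenize(smiles: str, config: DrugEmbeddingConfig) -> DrugSequence:
    """Deterministically map a SMILES string to token ids.

    Two-character elements (Cl, Br) become single atom tokens; any character
    not in the vocabulary raises :class:`TokenizationError` naming the
    offending character and its position. Sequences longer than
    ``config.max_len`` are truncated.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    vocab = config.vocab
    ids: list[int] = []
    mask: list[bool] = []
    i = 0
    while i < len(smiles) and len(ids) < config.max_len:
        two = smiles[i : i + 2]
        if two in _TWO_CHAR:
            tok = two
            i += 2
        else:
            tok = smiles[i]
            i += 1
        if tok not in vocab:
            raise TokenizationError(f"character {tok!r} at position {i - len(tok)} is not in the vocabulary")
        ids.append(vocab.id_of(tok))
        mask.append(tok in vocab.atom_tokens)
    return DrugSequence(tokens=np.asarray(ids, dtype=np.int64), raw=smiles,
                        atom_mask=np.asarray(mask, dtype=bool))


def _relative_index_matrix(n: int, clip: int) -> np.ndarray:
    idx = np.arange(n)
    return np.minimum(clip, np.abs(idx[:, None] - idx[None, :]))


class DrugEmbedder:
    """Learnable parameters of the drug input block.

    Holds the token table E_T, position table E_P, attention projections
    W_Q/W_K/W_V and the relative-relation table W_R with clip+1 rows
    (indices 0..clip, since only min(clip, |i-j|) is ever used).
    """

    def __init__(self, config: DrugEmbeddingConfig, rng: np.random.Generator):
        self.config = config
        d = config.hidden_dim
        s = 1.0 / np.sqrt(d)
        self.E_T = Tensor(rng.normal(0.0, s, (len(config.vocab), d)), requires_grad=True, name="E_T")
        self.E_P = Tensor(rng.normal(0.0, s, (config.max_len, d)), requires_grad=True, name="E_P")
        self.W_Q = Tensor(rng.normal(0.0, s, (d, d)), requires_grad=True, name="W_Q")
        self.W_K = Tensor(rng.normal(0.0, s, (d, d)), requires_grad=True, name="W_K")
        self.W_V = Tensor(rng.normal(0.0, s, (d, d)), requires_grad=True, name="W_V")
        self.W_R = Tensor(rng.normal(0.0, s, (config.clip + 1, d)), requires_grad=True, name="W_R")

    def parameters(self) -> dict[str, Tensor]:
        return {t.name: t for t in (self.E_T, self.E_P, self.W_Q, self.W_K, self.W_V, self.W_R)}

    # ------------------------------------------------------------------
    def pad_batch(self, seqs: list[DrugSequence]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right-pad to max_len; returns (ids, pad_mask, atom_mask)."""
        n = self.config.max_len
        ids = np.full((len(seqs), n), PAD_ID, dtype=np.int64)
        pad = np.zeros((len(seqs), n), dtype=bool)
        atom = np.zeros((len(seqs), n), dtype=bool)
        for b, s in enumerate(seqs):
            k = len(s)
            ids[b, :k] = s.tokens
            pad[b, :k] = True
            atom[b, :k] = s.atom_mask
        return ids, pad, atom

    def token_embedding(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        """X_D = E_T[tokens] + E_P, zeroed at padding."""
        b, n = ids.shape
        x = self.E_T.take(ids.ravel()).reshape(b, n, self.config.hidden_dim)
        x = x + self.E_P[:n]
        return x * Tensor(pad_mask[..., None].astype(np.float64))

    def relative_matrix(self, X_D: Tensor, atom_mask: np.ndarray) -> Tensor:
        """A_R[b, i, j] = (X_D[b, i] @ W_Q) . W_R[min(clip, |i-j|)], zero at virtual tokens.

        W_R rows must number clip+1; a mismatch is a configuration error.
        """
        cfg = self.config
        if self.W_R.shape[0] != cfg.clip + 1:
            raise ValueError(f"W_R has {self.W_R.shape[0]} rows but clip={cfg.clip} requires {cfg.clip + 1}")
        b, n, _ = X_D.shape
        q = matmul(X_D, self.W_Q)  # (b, n, d)
        rel = _relative_index_matrix(n, cfg.clip)
        scores = matmul(q, self.W_R.T)  # (b, n, clip+1): dot with every relation vector
        a = Tensor(np.zeros((b, n, n)))
        for r in range(cfg.clip + 1):
            sel = Tensor((rel == r).astype(np.float64))  # (n, n), constant
            a = a + scores[:, :, r : r + 1] * sel
        pair_ok = atom_mask[:, :, None] & atom_mask[:, None, :]
        return a * Tensor(pair_ok.astype(np.float64))

    def forward(self, seqs: list[DrugSequence]) -> tuple[Tensor, Tensor, np.ndarray, np.ndarray]:
        """Run the input block; returns (D_In, A_R, pad_mask, atom_mask)."""
        ids, pad, atom = self.pad_batch(seqs)
        x = self.token_embedding(ids, pad)
        for t in (self.W_Q, self.W_K, self.W_V, self.W_R):
            if not np.all(np.isfinite(t.data)):
                raise FloatingPointError(f"non-finite values in parameter {t.name}")
        a_r = self.relative_matrix(x, atom)
        q = matmul(x, self.W_Q)
        k = matmul(x, self.W_K)
        v = matmul(x, self.W_V)
        logits = (matmul(q, k.transpose(0, 2, 1)) + a_r) * (1.0 / self.config.scale)
        attn = softmax(logits, axis=-1, mask=pad[:, None, :])
        d_in = matmul(attn, v)
        return d_in, a_r, pad, atom


def build_relative_matrix(seq: DrugSequence, embedder: DrugEmbedder) -> np.ndarray:
    """Relationship matrix for one sequence (max_len x max_len numpy array)."""
    ids, pad, atom = embedder.pad_batch([seq])
    x = embedder.token_embedding(ids, pad)
    return embedder.relative_matrix(x, atom).data[0]


def embed_drug(seq: DrugSequence, embedder: DrugEmbedder) -> DrugInputEmbedding:
    """Full input block for one sequence, returned as plain arrays."""
    ids, pad, atom = embedder.pad_batch([seq])
    x = embedder.token_embedding(ids, pad)
    d_in, a_r, pad, _ = embedder.forward([seq])
    return DrugInputEmbedding(X_D=x.data[0], A_R=a_r.data[0], D_In=d_in.data[0], pad_mask=pad[0])
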