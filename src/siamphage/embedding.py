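"""k-mer vocabulary and skip-gram embeddings.

Each k-mer token is mapped to a ``d``-dimensional vector trained with the
skip-gram objective and negative sampling (SGNS): co-occurring k-mers are
pulled together in the vector space, so the embedding encodes local sequence
context. A single table is trained on the pooled phage+host corpus and shared
by both towers. The reserved UNK token (padding / ambiguity windows) is
excluded from training and its vector pinned to zero, so padded sequence
regions contribute exact zeros to the segment matrix.

The trainer is a self-contained, seeded, single-threaded numpy SGNS
implementation (word2vec-style: unigram^0.75 negative distribution, linearly
decaying SGD). For large corpora the number of (center, context) pairs per
epoch is capped by seeded subsampling; the embedding has only
``(4^k + 1) * d`` parameters and converges long before the full pair set is
consumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DataError
from .sequence import UNK, encode_kmer_ids

__all__ = [
    "EmbeddingTable",
    "SkipGramEmbedder",
    "build_vocabulary",
    "embed_segment",
    "random_table",
    "train_skipgram",
]


def build_vocabulary(k: int) -> list[str]:
    """All 4^k ACGT k-mers in lexicographic order, with UNK appended last."""
    if not 1 <= k <= 8:
        raise ConfigurationError(f"k must be in [1, 8], got {k}")
    return ["".join(p) for p in product("ACGT", repeat=k)] + [UNK]


@dataclass
class EmbeddingTable:
    """Trained token -> vector map. Row order matches ``build_vocabulary(k)``;
    the final row (UNK) is all zeros."""

    k: int
    d: int
    matrix: np.ndarray  # (4^k + 1, d), float64

    def __post_init__(self):
        expected = (4 ** self.k + 1, self.d)
        if self.matrix.shape != expected:
            raise ConfigurationError(
                f"embedding matrix shape {self.matrix.shape} != {expected}")

    @property
    def tokens(self) -> list[str]:
        return build_vocabulary(self.k)

    @property
    def unk_id(self) -> int:
        return 4 ** self.k

    def vector(self, token: str) -> np.ndarray:
        try:
            idx = self.unk_id if token == UNK else _kmer_index(token, self.k)
        except KeyError:
            raise DataError(f"token {token!r} not in the k={self.k} vocabulary")
        return self.matrix[idx]

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vector(token)

    # -- persistence: token list (text), dense matrix, json header ----------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.tokens.txt").write_text("\n".join(self.tokens) + "\n")
        np.save(f"{prefix}.vectors.npy", self.matrix)
        Path(f"{prefix}.meta.json").write_text(
            json.dumps({"k": self.k, "d": self.d, "format": "siamphage-embedding-v1"}))

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingTable":
        meta = json.loads(Path(f"{prefix}.meta.json").read_text())
        matrix = np.load(f"{prefix}.vectors.npy")
        table = cls(k=meta["k"], d=meta["d"], matrix=matrix)
        stored = Path(f"{prefix}.tokens.txt").read_text().splitlines()
        if stored != table.tokens:
            raise DataError(f"{prefix}: stored token list does not match k={meta['k']}")
        return table


def _kmer_index(token: str, k: int) -> int:
    if len(token) != k:
        raise KeyError(token)
    idx = 0
    for ch in token:
        pos = "ACGT".find(ch)
        if pos < 0:
            raise KeyError(token)
        idx = idx * 4 + pos
    return idx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _corpus_to_ids(corpus, k: int) -> list[np.ndarray]:
    """Accept token-lists or raw segment strings; return int id arrays."""
    unk_id = 4 ** k
    out = []
    for item in corpus:
        if isinstance(item, str):
            out.append(encode_kmer_ids(item, k))
        elif isinstance(item, np.ndarray):
            out.append(item.astype(np.int64))
        else:
            ids = np.empty(len(item), dtype=np.int64)
            for i, tok in enumerate(item):
                ids[i] = unk_id if tok == UNK else _kmer_index(tok, k)
            out.append(ids)
    return out


def train_skipgram(corpus, k: int = 3, d: int = 64, window: int = 5,
                   negative_samples: int = 5, epochs: int = 5, seed: int = 0,
                   learning_rate: float = 0.02,
                   max_pairs_per_epoch: int = 500_000) -> EmbeddingTable:
    """Train SGNS embeddings over a corpus of tokenised segments.

    ``corpus`` is an iterable of token-lists (or segment strings, which are
    tokenised on the fly). UNK-involving pairs are dropped; the UNK row of the
    returned table is zero. Deterministic for a fixed seed.
    """
    if d < 1 or window < 1 or negative_samples < 1 or epochs < 1:
        raise ConfigurationError("skip-gram hyperparameters must be positive")
    sentences = _corpus_to_ids(corpus, k)
    if not sentences or all(len(s) == 0 for s in sentences):
        raise DataError("skip-gram corpus is empty")
    vocab_size = 4 ** k + 1
    unk_id = vocab_size - 1

    # (center, context) pairs, vectorised per sentence, UNK pairs dropped
    centers_parts, contexts_parts = [], []
    counts = np.zeros(vocab_size, dtype=np.int64)
    for ids in sentences:
        valid = ids != unk_id
        np.add.at(counts, ids[valid], 1)
        for off in range(1, window + 1):
            if len(ids) <= off:
                continue
            a, b = ids[:-off], ids[off:]
            keep = (a != unk_id) & (b != unk_id)
            centers_parts.append(a[keep])
            contexts_parts.append(b[keep])
            # symmetric direction
            centers_parts.append(b[keep])
            contexts_parts.append(a[keep])
    centers = np.concatenate(centers_parts)
    contexts = np.concatenate(contexts_parts)
    if centers.size == 0:
        raise DataError("corpus contains no trainable (non-UNK) k-mer pairs")

    rng = np.random.default_rng(seed)
    n_epoch_pairs = min(len(centers), max_pairs_per_epoch)

    # word2vec negative-sampling distribution: unigram^0.75 over seen tokens
    neg_w = counts.astype(np.float64) ** 0.75
    neg_w[unk_id] = 0.0
    neg_p = neg_w / neg_w.sum()

    w_in = ((rng.random((vocab_size, d)) - 0.5) / d)
    w_out = np.zeros((vocab_size, d))
    w_in[unk_id] = 0.0

    # small batches: a 3-mer vocabulary is tiny, so each token recurs within
    # a batch and the summed update must stay well below 1/lr to be stable
    batch = 256
    total_batches = epochs * ((n_epoch_pairs + batch - 1) // batch)
    step = 0
    for _ in range(epochs):
        sel = (rng.permutation(len(centers))[:n_epoch_pairs]
               if n_epoch_pairs < len(centers)
               else rng.permutation(len(centers)))
        for lo in range(0, n_epoch_pairs, batch):
            idx = sel[lo:lo + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(vocab_size, size=(len(idx), negative_samples), p=neg_p)
            lr = learning_rate * max(1.0 - step / total_batches, 1e-4)
            step += 1

            v = w_in[c]                       # (B, d)
            u_pos = w_out[o]                  # (B, d)
            u_neg = w_out[neg]                # (B, n, d)
            g_pos = _sigmoid((v * u_pos).sum(axis=1)) - 1.0          # (B,)
            g_neg = _sigmoid(np.einsum("bnd,bd->bn", u_neg, v))      # (B, n)

            # per-token updates are averaged over their occurrences in the
            # batch, so the step size stays bounded however skewed the corpus
            grad_v = g_pos[:, None] * u_pos + np.einsum("bn,bnd->bd", g_neg, u_neg)
            upd_in = np.zeros_like(w_in)
            np.add.at(upd_in, c, grad_v)
            cnt_in = np.bincount(c, minlength=vocab_size)[:, None]
            w_in -= lr * upd_in / np.maximum(cnt_in, 1)

            upd_out = np.zeros_like(w_out)
            np.add.at(upd_out, o, g_pos[:, None] * v)
            np.add.at(upd_out, neg, g_neg[..., None] * v[:, None, :])
            cnt_out = (np.bincount(o, minlength=vocab_size)
                       + np.bincount(neg.reshape(-1), minlength=vocab_size))[:, None]
            w_out -= lr * upd_out / np.maximum(cnt_out, 1)
    w_in[unk_id] = 0.0
    return EmbeddingTable(k=k, d=d, matrix=w_in)


def random_table(k: int, d: int, seed: int) -> EmbeddingTable:
    """Seeded random embedding table (the 'without skip-gram' ablation:
    same shapes, no pretrained semantics; UNK still zero)."""
    rng = np.random.default_rng(seed)
    matrix = rng.normal(0.0, 0.02, size=(4 ** k + 1, d))
    matrix[-1] = 0.0
    return EmbeddingTable(k=k, d=d, matrix=matrix)


def embed_segment(tokens, table: EmbeddingTable) -> np.ndarray:
    """Stack token vectors into the (n_tokens, d) segment matrix.

    UNK rows are all-zero. Raises :class:`DataError` on an out-of-vocabulary
    token.
    """
    if isinstance(tokens, np.ndarray) and tokens.dtype.kind in "iu":
        if tokens.max(initial=0) > table.unk_id or tokens.min(initial=0) < 0:
            raise DataError("token id outside the vocabulary")
        return table.matrix[tokens]
    ids = np.empty(len(tokens), dtype=np.int64)
    for i, tok in enumerate(tokens):
        if tok == UNK:
            ids[i] = table.unk_id
        else:
            try:
                ids[i] = _kmer_index(tok, table.k)
            except KeyError:
                raise DataError(f"token {tok!r} not in the k={table.k} vocabulary")
    return table.matrix[ids]


class SkipGramEmbedder(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit an SGNS table on a tokenised corpus, then
    transform token-lists (or segment strings) into (n_tokens, d) matrices."""

    def __init__(self, k: int = 3, d: int = 64, window: int = 5,
                 negative_samples: int = 5, epochs: int = 5,
                 learning_rate: float = 0.05, max_pairs_per_epoch: int = 500_000,
                 seed: int = 0):
        self.k = k
        self.d = d
        self.window = window
        self.negative_samples = negative_samples
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.max_pairs_per_epoch = max_pairs_per_epoch
        self.seed = seed

    def fit(self, X, y=None):
        self.table_ = train_skipgram(
            X, k=self.k, d=self.d, window=self.window,
            negative_samples=self.negative_samples, epochs=self.epochs,
            seed=self.seed, learning_rate=self.learning_rate,
            max_pairs_per_epoch=self.max_pairs_per_epoch)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "table_")
        out = []
        for item in X:
            if isinstance(item, str):
                item = encode_kmer_ids(item, self.k)
            out.append(embed_segment(item, self.table_))
        return out
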