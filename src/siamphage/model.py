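"""The dual-tower (pseudo-Siamese) phage-host interaction network.

Per genome: each 2000-bp segment's (2000-k+1) x d embedding matrix is treated
as a one-channel 2-D image and pushed through a three-block CNN
(conv -> batch-norm -> ReLU, with max pooling after the first two blocks),
then global average pooling compresses the feature map to a fixed
``tower_dim``-length vector regardless of spatial extent. The per-segment
vectors are aggregated by a Transformer encoder: a learnable CLS vector is
prepended, the stack of post-norm layers (multi-head self-attention and
position-wise FFN, each wrapped in residual + LayerNorm) mixes segments, and
the final CLS state is the genome's global representation. Phage and host
towers share architecture but have independent parameters (a
``share_tower_weights`` flag gives the strictly-Siamese variant). The two
global vectors are concatenated and classified by an MLP
(2*tower_dim -> mlp_hidden -> 2) with a softmax over {non-match, match}.

No positional encoding is applied by default: segments enter the encoder as
an unordered set, which makes the CLS output provably invariant to segment
permutation (a tested property). Sinusoidal encodings are available behind
``use_positional_encoding`` for users who want order sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn as nn
from ._autodiff import (Tensor, concat, embedding_lookup, max_pool2d,
                        relu, softmax)
from .embedding import EmbeddingTable
from .errors import ConfigurationError, ContractError
from .records import GenomeRecord
from .sequence import encode_kmer_ids, segment_genome

__all__ = [
    "DualTowerNetwork",
    "MatchProbability",
    "ModelConfig",
    "attention_head",
    "genome_token_ids",
    "load_checkpoint",
    "save_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter of the network."""

    segment_length: int = 2000
    k: int = 3
    d_embed: int = 64
    tower_dim: int = 256
    n_transformer_layers: int = 6
    n_heads: int = 4
    head_dim: int | None = None          # default tower_dim // n_heads
    ffn_dim: int | None = None           # default 4 * tower_dim
    mlp_hidden: int = 4096
    n_classes: int = 2
    conv_channels: tuple[int, int, int] = (64, 128, 256)
    conv_kernel: int = 3
    pool_kernel: int | tuple[int, int] = 2
    share_tower_weights: bool = False
    use_positional_encoding: bool = False
    use_transformer: bool = True         # ablation: mean-pool segments instead
    use_pretrained_embedding: bool = True  # ablation: trainable random table
    fusion_batchnorm: bool = False       # batch-standardise z before the MLP
    dtype: str = "float64"

    def __post_init__(self):
        if self.head_dim is None:
            object.__setattr__(self, "head_dim", self.tower_dim // self.n_heads)
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.tower_dim)
        if self.head_dim * self.n_heads != self.tower_dim:
            raise ConfigurationError(
                f"head_dim ({self.head_dim}) * n_heads ({self.n_heads}) "
                f"must equal tower_dim ({self.tower_dim})")
        if len(self.conv_channels) != 3:
            raise ConfigurationError("conv_channels must list three layer widths")
        if self.conv_channels[-1] != self.tower_dim:
            raise ConfigurationError(
                "last conv channel count must equal tower_dim "
                "(global average pooling sets the tower output width)")

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """CPU-scale profile: 2 Transformer layers, 2 heads, conv 16/32/64,
        tower 64, narrow embeddings, aggressive pooling, float32 arithmetic."""
        base = dict(d_embed=8, tower_dim=64, n_transformer_layers=2, n_heads=2,
                    conv_channels=(16, 32, 64), pool_kernel=((8, 4), (8, 2)),
                    mlp_hidden=256, fusion_batchnorm=True, dtype="float32")
        base.update(overrides)
        return cls(**base)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    @property
    def n_tokens(self) -> int:
        return self.segment_length - self.k + 1


@dataclass(frozen=True)
class MatchProbability:
    """Softmax output: index 0 = non-match, index 1 = match."""

    p_non_match: float
    p_match: float

    def __post_init__(self):
        if not (0.0 <= self.p_match <= 1.0 and 0.0 <= self.p_non_match <= 1.0):
            raise ContractError("probabilities outside [0, 1]")
        if abs(self.p_match + self.p_non_match - 1.0) > 1e-6:
            raise ContractError("probabilities do not sum to 1")

    @property
    def label(self) -> int:
        return int(self.p_match > self.p_non_match)


def attention_head(q: Tensor | np.ndarray, k: Tensor | np.ndarray,
                   v: Tensor | np.ndarray, d_k: int,
                   mask: np.ndarray | None = None,
                   return_weights: bool = False):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V.

    ``mask`` flags valid key positions; masked keys get -inf logits and hence
    zero attention weight. Works on raw arrays or autodiff tensors.
    """
    if d_k <= 0:
        raise ConfigurationError("d_k must be positive")
    wrap = not isinstance(q, Tensor)
    if wrap:
        q, k, v = Tensor(q), Tensor(k), Tensor(v)
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k))
    if mask is not None:
        bias = np.where(np.asarray(mask, dtype=bool), 0.0, -1e9)
        scores = scores + Tensor(bias.astype(scores.dtype))
    weights = softmax(scores, axis=-1)
    out = weights @ v
    if return_weights:
        return (out.data, weights.data) if wrap else (out, weights)
    return out.data if wrap else out


def sinusoidal_encoding(length: int, dim: int, dtype=np.float64) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(dtype)


def _pool_pair(pool_kernel):
    """Normalise the pool spec: an int or (h, w) applies to both pooling
    steps; a pair of pairs gives each step its own window."""
    if isinstance(pool_kernel, int):
        return (pool_kernel, pool_kernel)
    pk = tuple(pool_kernel)
    if len(pk) == 2 and all(isinstance(v, int) for v in pk):
        return (pk, pk)
    if len(pk) == 2:
        return (tuple(pk[0]), tuple(pk[1]))
    raise ConfigurationError(f"unsupported pool_kernel spec: {pool_kernel!r}")


class _CnnTower(nn.Module):
    """conv-BN-ReLU x3 with pooling after blocks 1 and 2, then global average
    pooling to a fixed-width vector."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dt = cfg.np_dtype
        c1, c2, c3 = cfg.conv_channels
        self.conv1 = nn.Conv2d(1, c1, cfg.conv_kernel, rng, dt)
        self.bn1 = nn.BatchNorm2d(c1, dtype=dt)
        self.conv2 = nn.Conv2d(c1, c2, cfg.conv_kernel, rng, dt)
        self.bn2 = nn.BatchNorm2d(c2, dtype=dt)
        self.conv3 = nn.Conv2d(c2, c3, cfg.conv_kernel, rng, dt)
        self.bn3 = nn.BatchNorm2d(c3, dtype=dt)
        self.pools = _pool_pair(cfg.pool_kernel)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = relu(self.bn1(self.conv1(x), training))
        h = max_pool2d(h, self.pools[0])
        h = relu(self.bn2(self.conv2(h), training))
        h = max_pool2d(h, self.pools[1])
        h = relu(self.bn3(self.conv3(h), training))
        return h.mean(axis=(2, 3))  # (B, tower_dim)


class _TransformerLayer(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dt = cfg.np_dtype
        d, h, dk = cfg.tower_dim, cfg.n_heads, cfg.head_dim
        scale = 1.0 / np.sqrt(d)
        def proj(shape):
            return Tensor(rng.normal(0.0, scale, size=shape).astype(dt),
                          requires_grad=True)
        self.wq = proj((h, d, dk))
        self.wk = proj((h, d, dk))
        self.wv = proj((h, d, dk))
        self.wo = Tensor(rng.normal(0.0, scale, size=(d, d)).astype(dt),
                         requires_grad=True)
        self.ln1 = nn.LayerNorm(d, dtype=dt)
        self.ln2 = nn.LayerNorm(d, dtype=dt)
        self.ffn1 = nn.Linear(d, cfg.ffn_dim, rng, dt)
        self.ffn2 = nn.Linear(cfg.ffn_dim, d, rng, dt)
        self.d_k = dk

    def __call__(self, x: Tensor, key_mask: np.ndarray | None) -> Tensor:
        # x: (S, d); per-head projections -> (h, S, d_k)
        xb = x.reshape(1, *x.shape)
        q = xb @ self.wq
        k = xb @ self.wk
        v = xb @ self.wv
        mask = None if key_mask is None else key_mask[None, None, :]
        heads = attention_head(q, k, v, self.d_k, mask=mask)  # (h, S, d_k)
        h_, s, dk = heads.shape
        merged = heads.transpose(1, 0, 2).reshape(s, h_ * dk)
        att = merged @ self.wo
        x = self.ln1(x + att)
        ff = self.ffn2(relu(self.ffn1(x)))
        return self.ln2(x + ff)


class _TransformerEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dt = cfg.np_dtype
        self.cls = Tensor(rng.normal(0.0, 0.02, size=(1, cfg.tower_dim)).astype(dt),
                          requires_grad=True)
        self.layers = [_TransformerLayer(cfg, rng)
                       for _ in range(cfg.n_transformer_layers)]
        self.cfg = cfg

    def __call__(self, segments: Tensor, mask: np.ndarray | None) -> Tensor:
        """segments: (c, tower_dim); mask flags valid segments. Returns the
        final CLS row, shape (tower_dim,)."""
        c = segments.shape[0]
        if c == 0:
            raise ContractError("transformer_encode requires >= 1 segment vector")
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (c,):
                raise ContractError("mask length must equal segment count")
            if not mask.any():
                raise ContractError("mask excludes every segment")
        if self.cfg.use_positional_encoding:
            pe = sinusoidal_encoding(c, self.cfg.tower_dim, segments.dtype)
            segments = segments + Tensor(pe)
        x = concat([self.cls, segments], axis=0)  # (c+1, d)
        key_mask = None
        if mask is not None:
            key_mask = np.concatenate([[True], mask])
        for layer in self.layers:
            x = layer(x, key_mask)
        return x[0]


class _MeanAggregator(nn.Module):
    """No-Transformer ablation: mask-weighted mean of segment vectors."""

    def __call__(self, segments: Tensor, mask: np.ndarray | None) -> Tensor:
        if segments.shape[0] == 0:
            raise ContractError("aggregation requires >= 1 segment vector")
        if mask is None:
            return segments.mean(axis=0)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ContractError("mask excludes every segment")
        w = (mask / mask.sum()).astype(segments.dtype)
        return (segments * Tensor(w[:, None])).sum(axis=0)


class DualTowerNetwork(nn.Module):
    """End-to-end network; all weights drawn from a single seeded stream."""

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 embedding: EmbeddingTable | None = None):
        rng = np.random.default_rng([seed, 97])
        dt = cfg.np_dtype
        self.cfg = cfg
        self.phage_cnn = _CnnTower(cfg, rng)
        self.host_cnn = self.phage_cnn if cfg.share_tower_weights \
            else _CnnTower(cfg, rng)
        if cfg.use_transformer:
            self.phage_encoder = _TransformerEncoder(cfg, rng)
            self.host_encoder = self.phage_encoder if cfg.share_tower_weights \
                else _TransformerEncoder(cfg, rng)
        else:
            self.phage_encoder = _MeanAggregator()
            self.host_encoder = _MeanAggregator()
        self.fc1 = nn.Linear(2 * cfg.tower_dim, cfg.mlp_hidden, rng, dt)
        self.fc2 = nn.Linear(cfg.mlp_hidden, cfg.n_classes, rng, dt)
        # optional batch standardisation of the fused vector: at desk scale
        # the between-genome variation that carries the signal is tiny
        # relative to the LayerNorm-fixed coordinate scale, and equalising it
        # lets the classifier see it within a small step budget
        self.fuse_bn = nn.BatchNorm2d(2 * cfg.tower_dim, dtype=dt) \
            if cfg.fusion_batchnorm else None

        if cfg.use_pretrained_embedding:
            if embedding is None:
                raise ConfigurationError(
                    "use_pretrained_embedding=True requires an EmbeddingTable")
            if embedding.k != cfg.k or embedding.d != cfg.d_embed:
                raise ConfigurationError(
                    f"embedding table (k={embedding.k}, d={embedding.d}) does not "
                    f"match config (k={cfg.k}, d={cfg.d_embed})")
            self._frozen_embedding = embedding.matrix.astype(dt)
            self.embed_param = None
        else:
            # trainable, seeded random table of the same shape; UNK row is
            # re-zeroed after every optimiser step by the training loop
            mat = rng.normal(0.0, 0.02, size=(4 ** cfg.k + 1, cfg.d_embed))
            mat[-1] = 0.0
            self._frozen_embedding = None
            self.embed_param = Tensor(mat.astype(dt), requires_grad=True)

    # -- embedding ----------------------------------------------------------
    def embed_ids(self, ids: np.ndarray) -> Tensor:
        """(c, n_tokens) token ids -> (c, 1, n_tokens, d_embed) image stack."""
        if self._frozen_embedding is not None:
            x = Tensor(self._frozen_embedding[ids])
        else:
            x = embedding_lookup(self.embed_param, ids)
        c, n = ids.shape
        return x.reshape(c, 1, n, self.cfg.d_embed)

    # -- tower operations ---------------------------------------------------
    def cnn_tower_forward(self, x: Tensor | np.ndarray, tower: str,
                          training: bool = False) -> Tensor:
        """(B, 1, n_tokens, d_embed) -> (B, tower_dim)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.cfg.np_dtype))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[3] != self.cfg.d_embed:
            raise ContractError(f"expected (B, 1, n_tokens, {self.cfg.d_embed}), "
                                f"got {x.shape}")
        cnn = self.phage_cnn if tower == "phage" else self.host_cnn
        return cnn(x, training)

    def transformer_encode(self, segment_vectors: Tensor | np.ndarray, tower: str,
                           mask: np.ndarray | None = None) -> Tensor:
        if not isinstance(segment_vectors, Tensor):
            segment_vectors = Tensor(
                np.asarray(segment_vectors, dtype=self.cfg.np_dtype))
        enc = self.phage_encoder if tower == "phage" else self.host_encoder
        return enc(segment_vectors, mask)

    def _classify(self, z: Tensor, training: bool) -> Tensor:
        """(B, 2*tower_dim) fused vectors -> (B, 2) logits."""
        if self.fuse_bn is not None:
            b, d2 = z.shape
            z = self.fuse_bn(z.reshape(b, d2, 1, 1), training).reshape(b, d2)
        h = relu(self.fc1(z))
        return self.fc2(h)

    def fuse_and_classify(self, c_phage: Tensor, c_host: Tensor,
                          training: bool = False) -> Tensor:
        """Concatenate the two 256-vectors and return the 2-class logits."""
        if c_phage.shape != (self.cfg.tower_dim,) or \
                c_host.shape != (self.cfg.tower_dim,):
            raise ContractError("global vectors must have shape (tower_dim,)")
        z = concat([c_phage.reshape(1, -1), c_host.reshape(1, -1)], axis=1)
        return self._classify(z, training)  # (1, 2) logits

    # -- end-to-end ---------------------------------------------------------
    def encode_genome(self, ids: np.ndarray, tower: str,
                      training: bool = False) -> Tensor:
        x = self.embed_ids(ids)
        seg_vecs = self.cnn_tower_forward(x, tower, training)
        return self.transformer_encode(seg_vecs, tower)

    def forward_pair(self, phage: GenomeRecord, host: GenomeRecord,
                     training: bool = False) -> MatchProbability:
        logits = self.pair_logits(genome_token_ids(phage, self.cfg),
                                  genome_token_ids(host, self.cfg), training)
        p = _softmax_np(logits.data[0])
        return MatchProbability(p_non_match=float(p[0]), p_match=float(p[1]))

    def pair_logits(self, phage_ids: np.ndarray, host_ids: np.ndarray,
                    training: bool = False) -> Tensor:
        cp = self.encode_genome(phage_ids, "phage", training)
        ch = self.encode_genome(host_ids, "host", training)
        return self.fuse_and_classify(cp, ch, training)

    def fused_batch(self, phage_ids_list: list[np.ndarray],
                    host_ids_list: list[np.ndarray],
                    training: bool = False) -> Tensor:
        """(B, 2*tower_dim) fused vectors for a batch of pairs (see
        :meth:`batch_logits` for the batching/dedup semantics)."""
        return self._fused(phage_ids_list, host_ids_list, training)

    def batch_logits(self, phage_ids_list: list[np.ndarray],
                     host_ids_list: list[np.ndarray],
                     training: bool = False) -> Tensor:
        """Joint forward over a mini-batch of pairs.

        All phage segments in the batch go through the phage CNN together (so
        batch-norm statistics are computed over the whole mini-batch), then
        each genome's segment vectors are aggregated by its tower's encoder.
        A genome appearing several times in the batch (the same ndarray
        object, as produced by a token-id cache) is encoded once and its
        representation shared across pairs. Returns (B, 2) logits.
        """
        z = self._fused(phage_ids_list, host_ids_list, training)
        return self._classify(z, training)

    def _fused(self, phage_ids_list, host_ids_list, training) -> Tensor:
        def tower_pass(ids_list, tower):
            uniq: dict[int, np.ndarray] = {}
            for ids in ids_list:
                uniq.setdefault(id(ids), ids)
            keys = list(uniq)
            stacked = np.concatenate([uniq[kk] for kk in keys], axis=0)
            vecs = self.cnn_tower_forward(self.embed_ids(stacked), tower, training)
            encoded, lo = {}, 0
            for kk in keys:
                c = uniq[kk].shape[0]
                encoded[kk] = self.transformer_encode(vecs[lo:lo + c], tower)
                lo += c
            return [encoded[id(ids)] for ids in ids_list]

        cps = tower_pass(phage_ids_list, "phage")
        chs = tower_pass(host_ids_list, "host")
        return concat([concat([cp.reshape(1, -1), ch.reshape(1, -1)], axis=1)
                       for cp, ch in zip(cps, chs)], axis=0)


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def genome_token_ids(record: GenomeRecord, cfg: ModelConfig) -> np.ndarray:
    """(c, n_tokens) int array of k-mer ids for a genome's padded segments."""
    segments = segment_genome(record, cfg.segment_length)
    return np.stack([encode_kmer_ids(s, cfg.k) for s in segments])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = "siamphage-checkpoint-v1"


def save_checkpoint(model: DualTowerNetwork, path: str | Path, seed: int = 0,
                    extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"format": _CHECKPOINT_VERSION, "seed": seed,
              "config": asdict(model.cfg), "extra": extra or {}}
    np.savez(path, **{"__header__": np.asarray(json.dumps(header)),
                      **model.state_arrays()})


def load_checkpoint(path: str | Path,
                    embedding: EmbeddingTable | None = None
                    ) -> tuple[DualTowerNetwork, dict]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        if header.get("format") != _CHECKPOINT_VERSION:
            raise ConfigurationError(f"{path}: unknown checkpoint format")
        cfg_dict = dict(header["config"])
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        if isinstance(cfg_dict.get("pool_kernel"), list):
            cfg_dict["pool_kernel"] = tuple(
                tuple(v) if isinstance(v, list) else v
                for v in cfg_dict["pool_kernel"])
        cfg = ModelConfig(**cfg_dict)
        model = DualTowerNetwork(cfg, seed=header.get("seed", 0),
                                 embedding=embedding)
        state = {k: data[k] for k in data.files if k != "__header__"}
        model.load_state_arrays(state)
    return model, header
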