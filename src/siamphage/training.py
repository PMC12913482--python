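"""Optimisation protocol for the dual-tower network.

Cross-entropy over the softmax outputs with an L2 penalty folded into the
loss (weight matrices only; biases and normalisation gains are exempt, the
usual convention), Adam with (lr=1e-4, beta1=0.9, beta2=0.999), global-norm
gradient clipping at 5.0, mini-batches of 32 seeded-shuffled pairs, and
batch-norm moving statistics with decay 0.999. Probabilities are clamped at
1e-12 before the log so the loss is finite everywhere; a NaN gradient aborts
with the offending batch index.

:class:`DualTowerHostClassifier` wraps the whole protocol as a scikit-learn
estimator: ``fit`` takes (phage, host) genome pairs and binary labels,
optionally pretraining the skip-gram table on the training genomes;
``predict_proba`` scores new pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Tensor, log_softmax
from .embedding import EmbeddingTable, train_skipgram
from .errors import ConfigurationError, DataError, TrainingError
from .model import DualTowerNetwork, ModelConfig, genome_token_ids
from .records import GenomeRecord, InteractionPair
from .sequence import segment_genome

__all__ = [
    "Adam",
    "DualTowerHostClassifier",
    "TrainConfig",
    "TrainingHistory",
    "clip_gradients",
    "compute_loss",
    "train",
    "update_bn_statistics",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    l2_coefficient: float = 1e-3
    grad_clip_threshold: float = 5.0
    bn_moving_decay: float = 0.999
    seed: int = 0
    validation_fraction: float = 0.0
    early_stop_accuracy: float | None = None  # stop once training acc reaches this
    lr_decay: float = 1.0  # final-epoch lr as a fraction of learning_rate (linear)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        for name in ("learning_rate", "beta1", "beta2", "grad_clip_threshold",
                     "bn_moving_decay", "lr_decay"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.l2_coefficient < 0:
            raise ConfigurationError("l2_coefficient must be >= 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must be in [0, 1)")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


def compute_loss(p, label: int, model_weights=(), l2: float = 0.0) -> float:
    """Reference loss: -log p[label] + l2 * sum of squared weights.

    ``p`` is a :class:`~siamphage.model.MatchProbability` or a length-2
    probability vector; ``model_weights`` an iterable of weight arrays (pass
    only the matrices subject to decay). Probabilities are clamped at 1e-12.
    """
    if hasattr(p, "p_match"):
        probs = (p.p_non_match, p.p_match)
    else:
        probs = tuple(float(v) for v in p)
    if label not in (0, 1):
        raise DataError("label must be 0 or 1")
    ce = -np.log(max(probs[label], PROB_FLOOR))
    penalty = l2 * sum(float(np.sum(np.square(w))) for w in model_weights)
    return float(ce + penalty)


def clip_gradients(grads: list[np.ndarray], threshold: float = 5.0,
                   batch_index: int | None = None
                   ) -> tuple[list[np.ndarray], float]:
    """Global L2-norm clipping; returns (clipped grads, pre-clip norm)."""
    sq = 0.0
    for g in grads:
        if not np.all(np.isfinite(g)):
            where = f" in batch {batch_index}" if batch_index is not None else ""
            raise TrainingError(f"non-finite gradient{where}")
        sq += float(np.sum(np.square(g, dtype=np.float64)))
    norm = float(np.sqrt(sq))
    if norm > threshold:
        scale = threshold / norm
        grads = [g * scale for g in grads]
    return grads, norm


def update_bn_statistics(batch_mean, batch_var, moving_mean, moving_var,
                         decay: float = 0.999):
    """moving <- decay * moving + (1 - decay) * batch (both statistics)."""
    moving_mean = decay * np.asarray(moving_mean, dtype=np.float64) \
        + (1 - decay) * np.asarray(batch_mean, dtype=np.float64)
    moving_var = decay * np.asarray(moving_var, dtype=np.float64) \
        + (1 - decay) * np.asarray(batch_var, dtype=np.float64)
    return moving_mean, moving_var


class Adam:
    """Standard Adam with bias correction; operates on a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = (p.data.astype(np.float64)
                      - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(p.data.dtype)


def decayed_weights(model: DualTowerNetwork) -> list[Tensor]:
    """Parameters subject to L2: matrices/kernels only (ndim >= 2), which
    exempts biases and normalisation gains/offsets."""
    return [p for p in model.parameters() if p.data.ndim >= 2]


def train(model: DualTowerNetwork, pairs: list[InteractionPair],
          genomes: dict[str, GenomeRecord], cfg: TrainConfig,
          val_pairs: list[InteractionPair] | None = None) -> TrainingHistory:
    """Run the full optimisation protocol; returns per-epoch history."""
    if not pairs:
        raise DataError("training requires a non-empty pair list")
    missing = sorted({pid for p in pairs for pid in (p.phage_id, p.host_id)
                      if pid not in genomes})
    if missing:
        raise DataError(f"pairs reference unknown genome ids: {missing[:5]}")

    # propagate the configured BN decay into the network's BN layers
    from ._nn import BatchNorm2d
    for mod in model.modules():
        if isinstance(mod, BatchNorm2d):
            mod.decay = cfg.bn_moving_decay

    ids_cache = {gid: genome_token_ids(genomes[gid], model.cfg)
                 for gid in {pid for p in pairs for pid in (p.phage_id, p.host_id)}}
    rng = np.random.default_rng([cfg.seed, 7])
    params = model.parameters()
    decay_set = {id(p) for p in decayed_weights(model)}
    optimiser = Adam(params, lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    history = TrainingHistory()
    order = np.arange(len(pairs))

    for epoch in range(cfg.epochs):
        if cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
            optimiser.lr = cfg.learning_rate * (1 + (cfg.lr_decay - 1) * frac)
        rng.shuffle(order)
        epoch_loss, epoch_correct, epoch_norms = 0.0, 0, []
        for bstart in range(0, len(order), cfg.batch_size):
            batch = [pairs[i] for i in order[bstart:bstart + cfg.batch_size]]
            batch_index = bstart // cfg.batch_size
            labels = np.array([p.label for p in batch])
            logits = model.batch_logits(
                [ids_cache[p.phage_id] for p in batch],
                [ids_cache[p.host_id] for p in batch], training=True)
            logp = log_softmax(logits, axis=-1)
            picked = logp[np.arange(len(batch)), labels]
            loss = -picked.mean()
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss in batch {batch_index}")
            model.zero_grad()
            loss.backward()
            grads = []
            penalty = 0.0
            for p in params:
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                if id(p) in decay_set and cfg.l2_coefficient > 0:
                    # d/dw of l2 * sum(w^2): the L2 term lives inside the loss
                    g = g + 2.0 * cfg.l2_coefficient * p.data
                    penalty += cfg.l2_coefficient * float(np.sum(np.square(p.data)))
                grads.append(np.asarray(g, dtype=np.float64))
            grads, norm = clip_gradients(grads, cfg.grad_clip_threshold,
                                         batch_index=batch_index)
            optimiser.step(grads)
            if model.embed_param is not None:
                model.embed_param.data[-1] = 0.0  # UNK stays pinned to zero
            probs = logits.data
            epoch_correct += int((probs.argmax(axis=1) == labels).sum())
            epoch_loss += (float(loss.data) + penalty) * len(batch)
            epoch_norms.append(min(norm, cfg.grad_clip_threshold))
        history.loss.append(epoch_loss / len(order))
        history.accuracy.append(epoch_correct / len(order))
        history.grad_norm.append(float(np.mean(epoch_norms)))
        if val_pairs:
            if model.fuse_bn is not None:
                _calibrate_fusion_bn(model, pairs, ids_cache, cfg.batch_size)
            history.val_accuracy.append(
                _eval_accuracy(model, val_pairs, ids_cache, genomes))
        if cfg.early_stop_accuracy is not None and \
                history.accuracy[-1] >= cfg.early_stop_accuracy:
            break

    if model.fuse_bn is not None:
        _calibrate_fusion_bn(model, pairs, ids_cache, cfg.batch_size)
    return history


def _calibrate_fusion_bn(model: DualTowerNetwork, pairs, ids_cache,
                         batch_size: int) -> None:
    """Estimate the fusion layer's population statistics from the training
    pairs with the towers in inference mode, so evaluation standardises the
    fused vector consistently with how it is produced at inference time."""
    rows = []
    for lo in range(0, len(pairs), max(batch_size, 8)):
        chunk = pairs[lo:lo + max(batch_size, 8)]
        z = model.fused_batch([ids_cache[p.phage_id] for p in chunk],
                              [ids_cache[p.host_id] for p in chunk],
                              training=False)
        rows.append(z.data)
    allz = np.concatenate(rows, axis=0)
    model.fuse_bn.set_population(allz.mean(axis=0), allz.var(axis=0))


def _eval_accuracy(model, pairs, ids_cache, genomes) -> float:
    correct = 0
    for p in pairs:
        for gid in (p.phage_id, p.host_id):
            if gid not in ids_cache:
                ids_cache[gid] = genome_token_ids(genomes[gid], model.cfg)
        logits = model.pair_logits(ids_cache[p.phage_id], ids_cache[p.host_id],
                                   training=False)
        correct += int(int(logits.data[0].argmax()) == p.label)
    return correct / len(pairs)


class DualTowerHostClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn interface to the dual-tower pair classifier.

    ``X`` is a sequence of (phage GenomeRecord, host GenomeRecord) tuples and
    ``y`` the binary match labels. When ``embedding="auto"`` the skip-gram
    table is pretrained (and frozen) on the segments of all genomes seen in
    ``fit``; pass an :class:`EmbeddingTable` to reuse one, or configure the
    model with ``use_pretrained_embedding=False`` for the trainable-embedding
    ablation.
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 embedding: EmbeddingTable | str = "auto",
                 skipgram_params: dict | None = None, seed: int = 0):
        self.model_config = model_config
        self.train_config = train_config
        self.embedding = embedding
        self.skipgram_params = skipgram_params
        self.seed = seed

    def _configs(self) -> tuple[ModelConfig, TrainConfig]:
        return (self.model_config or ModelConfig(),
                self.train_config or TrainConfig(seed=self.seed))

    def fit(self, X, y):
        mcfg, tcfg = self._configs()
        X = list(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise DataError("X and y length mismatch")
        genomes: dict[str, GenomeRecord] = {}
        for phage, host in X:
            genomes[phage.id] = phage
            genomes[host.id] = host
        pairs = [InteractionPair(ph.id, ho.id, int(lbl))
                 for (ph, ho), lbl in zip(X, y)]

        table = None
        if mcfg.use_pretrained_embedding:
            if isinstance(self.embedding, EmbeddingTable):
                table = self.embedding
            elif self.embedding == "auto":
                corpus = [seg for g in genomes.values()
                          for seg in segment_genome(g, mcfg.segment_length)]
                sg = dict(k=mcfg.k, d=mcfg.d_embed, seed=self.seed)
                sg.update(self.skipgram_params or {})
                table = train_skipgram(corpus, **sg)
            else:
                raise ConfigurationError(
                    "embedding must be an EmbeddingTable or 'auto'")

        val_pairs = None
        if tcfg.validation_fraction > 0:
            split_rng = np.random.default_rng([tcfg.seed, 3])
            idx = split_rng.permutation(len(pairs))
            n_val = max(1, int(round(len(pairs) * tcfg.validation_fraction)))
            val_pairs = [pairs[i] for i in idx[:n_val]]
            pairs = [pairs[i] for i in idx[n_val:]]

        self.model_ = DualTowerNetwork(mcfg, seed=self.seed, embedding=table)
        self.embedding_table_ = table
        self.history_ = train(self.model_, pairs, genomes, tcfg,
                              val_pairs=val_pairs)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        out = np.empty((len(X), 2))
        for i, (phage, host) in enumerate(X):
            p = self.model_.forward_pair(phage, host, training=False)
            out[i] = (p.p_non_match, p.p_match)
        return out

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
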