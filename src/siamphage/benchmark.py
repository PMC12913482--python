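"""The package's scaled-down reference study on synthetic data.

The full-size protocol (2,288 genomes, 62k candidate hosts, 200 epochs of a
6-layer Transformer) is a GPU-scale computation; this module fixes a desk-
scale study with the same structure so results are reproducible end to end
on one CPU in minutes:

* four phyla of hosts (two genera-level hosts each), 20-kb genomes,
  phage mimicry strength 0.9 — a strong but noisy compositional signal
  (a naive nearest-profile baseline recovers the phylum but not the exact
  host);
* 20 training phages -> 40 balanced training pairs, 10 held-out phages ->
  20 balanced test pairs, negatives drawn with the phylum-exclusion rule;
* the reduced architecture (2 Transformer layers, 2 heads, conv channels
  16/32/64 into a 64-d tower) trained with the standard protocol at
  desk-scale settings.

`run_scaled_benchmark` executes the whole pipeline from scratch and returns
every quantity it measures.
"""

from __future__ import annotations

import numpy as np

from .embedding import train_skipgram
from .evaluation import evaluate_testset, pair_accuracy
from .model import DualTowerNetwork, ModelConfig
from .records import RANKS
from .sequence import segment_genome
from .synthetic import (SyntheticConfig, build_pair_dataset, generate_dataset,
                        nearest_composition_host)
from .training import TrainConfig, train

__all__ = ["run_scaled_benchmark", "scaled_study"]

N_TRAIN_PHAGES = 20
N_TEST_PHAGES = 10


def scaled_study(seed: int):
    """Generate the benchmark dataset and its train/test split."""
    scfg = SyntheticConfig(n_phyla=4, children_per_node=1, hosts_per_genus=2,
                           phages_per_host=4, host_length=20_000,
                           phage_length=20_000, mimicry_strength=0.9,
                           seed=seed % (2 ** 31))
    hosts, phages = generate_dataset(scfg)
    rng = np.random.default_rng([seed % (2 ** 31), 5])
    order = rng.permutation(len(phages))
    train_phages = [phages[i] for i in order[:N_TRAIN_PHAGES]]
    test_phages = [phages[i] for i in
                   order[N_TRAIN_PHAGES:N_TRAIN_PHAGES + N_TEST_PHAGES]]
    train_pairs = build_pair_dataset(train_phages, hosts, 1,
                                     seed=(seed * 31 + 11) % (2 ** 31))
    test_pairs = build_pair_dataset(test_phages, hosts, 1,
                                    seed=(seed * 31 + 12) % (2 ** 31))
    return hosts, phages, train_phages, test_phages, train_pairs, test_pairs


def training_profile(seed: int, epochs: int) -> TrainConfig:
    """Desk-scale optimisation settings for the reduced architecture.

    The defaults in :class:`TrainConfig` are tuned for the full-scale
    protocol (~10k optimiser steps); at a few hundred steps the learning
    rate, L2 coefficient and batch-norm memory are rescaled accordingly
    (rationale in the methods note).
    """
    return TrainConfig(epochs=epochs, learning_rate=1e-3, batch_size=4,
                       l2_coefficient=1e-4, bn_moving_decay=0.9, lr_decay=0.1,
                       seed=seed % (2 ** 31))


def run_scaled_benchmark(seed: int = 1, variant: str = "full",
                         epochs: int = 30, rank_evaluation: bool = True) -> dict:
    """Train and evaluate one variant of the scaled study from scratch.

    ``variant``: "full", "no_transformer" (Skip-gram + CNN) or "no_skipgram"
    (CNN + Transformer with a trainable random embedding).
    Returns a dict of measured quantities.
    """
    if variant not in ("full", "no_transformer", "no_skipgram"):
        raise ValueError(f"unknown variant {variant!r}")
    (hosts, phages, train_phages, test_phages,
     train_pairs, test_pairs) = scaled_study(seed)
    genomes = {g.id: g for g in hosts + phages}

    mcfg = ModelConfig.reduced(
        use_transformer=(variant != "no_transformer"),
        use_pretrained_embedding=(variant != "no_skipgram"))
    table = None
    if mcfg.use_pretrained_embedding:
        corpus = [seg for g in hosts + train_phages for seg in segment_genome(g)]
        table = train_skipgram(corpus, k=mcfg.k, d=mcfg.d_embed,
                               seed=seed % (2 ** 31), epochs=3,
                               max_pairs_per_epoch=200_000)

    net = DualTowerNetwork(mcfg, seed=seed % (2 ** 31), embedding=table)
    history = train(net, train_pairs, genomes, training_profile(seed, epochs))

    test_accuracy = pair_accuracy(net, test_pairs, genomes)
    result = {
        "variant": variant,
        "n_train_pairs": len(train_pairs),
        "n_test_pairs": len(test_pairs),
        "epochs_run": history.n_epochs,
        "final_train_accuracy": history.accuracy[-1],
        "final_train_loss": history.loss[-1],
        "held_out_pair_accuracy": test_accuracy,
    }
    if rank_evaluation:
        truth = {p.id: p.lineage for p in test_phages}
        report, _ = evaluate_testset(
            net, test_phages, hosts, truth,
            train_phage_ids={p.id for p in train_phages})
        for rank in RANKS:
            result[f"accuracy_{rank.rstrip('_')}"] = report.per_rank[rank]

        baseline_hits = sum(
            next(h for h in hosts if h.id == nearest_composition_host(p, hosts)
                 ).lineage.phylum == p.lineage.phylum
            for p in test_phages)
        result["baseline_phylum_accuracy"] = baseline_hits / len(test_phages)
        result["chance_phylum_accuracy"] = 1.0 / 4
    return result
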