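"""Host ranking and hierarchical (five-rank) accuracy.

The binary pair classifier becomes a host predictor by scoring a phage
against every candidate host and taking the top-1 match probability — the
protocol used by alignment-free host-prediction tools. Accuracy is then
reported at each taxonomic rank: a prediction counts as correct at rank L
when the predicted host's name at L equals the true host's name at L, so with
tree-consistent lineages accuracy is monotone non-decreasing from genus up to
phylum.

Candidate host representations (the host tower's CLS vector) are computed
once and cached across phages; only the cheap fusion MLP runs per
(phage, candidate) combination. A cache-equivalence test guarantees this
matches independent single-pair forward passes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .errors import ContractError, DataError, ProtocolError
from .model import DualTowerNetwork, genome_token_ids, _softmax_np
from .records import (RANKS, GenomeRecord, HostRanking, RankAccuracyReport,
                      TaxonomyLineage)

__all__ = [
    "evaluate_testset",
    "hierarchical_accuracy",
    "pair_accuracy",
    "rank_hosts",
    "write_report",
]


def _host_vector_cache(model: DualTowerNetwork,
                       candidates: list[GenomeRecord]) -> dict[str, np.ndarray]:
    cache = {}
    for host in candidates:
        ids = genome_token_ids(host, model.cfg)
        cache[host.id] = model.encode_genome(ids, "host", training=False).data
    return cache


def rank_hosts(phage: GenomeRecord, candidates: list[GenomeRecord],
               model: DualTowerNetwork,
               host_cache: dict[str, np.ndarray] | None = None) -> HostRanking:
    """Score every candidate host for one phage, sorted by descending
    p_match; ties broken by lexicographic host id."""
    if not candidates:
        raise ContractError("rank_hosts requires a non-empty candidate list")
    if host_cache is None:
        host_cache = _host_vector_cache(model, candidates)
    phage_ids = genome_token_ids(phage, model.cfg)
    c_phage = model.encode_genome(phage_ids, "phage", training=False)
    scored = []
    for host in candidates:
        logits = model.fuse_and_classify(c_phage, Tensor(host_cache[host.id]))
        p = _softmax_np(logits.data[0])
        scored.append((host.id, float(p[1])))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return HostRanking(phage_id=phage.id, scored_hosts=scored)


def hierarchical_accuracy(predictions: list[tuple[str, str]],
                          truth: dict[str, TaxonomyLineage],
                          host_lineages: dict[str, TaxonomyLineage]
                          ) -> RankAccuracyReport:
    """Per-rank accuracy over (phage_id, predicted_host_id) pairs.

    ``truth`` maps each phage to its true host's lineage; ``host_lineages``
    maps every predictable host to its lineage.
    """
    if not predictions:
        raise DataError("no predictions to score")
    correct = {rank: 0 for rank in RANKS}
    for phage_id, host_id in predictions:
        if phage_id not in truth:
            raise DataError(f"no true-host lineage for phage {phage_id!r}")
        if host_id not in host_lineages:
            raise DataError(f"no lineage for predicted host {host_id!r}")
        true_lin, pred_lin = truth[phage_id], host_lineages[host_id]
        for rank in RANKS:
            if true_lin.name_at(rank) == pred_lin.name_at(rank):
                correct[rank] += 1
    n = len(predictions)
    return RankAccuracyReport(
        n_total=n, per_rank={rank: correct[rank] / n for rank in RANKS})


def evaluate_testset(model: DualTowerNetwork, phages: list[GenomeRecord],
                     candidates: list[GenomeRecord],
                     truth: dict[str, TaxonomyLineage],
                     train_phage_ids: set[str] | None = None
                     ) -> tuple[RankAccuracyReport, list[HostRanking]]:
    """Rank all candidates for every test phage and score per-rank accuracy.

    ``train_phage_ids``, when given, is used to enforce train/test
    disjointness (a :class:`ProtocolError` lists any overlap).
    """
    if train_phage_ids:
        overlap = sorted({p.id for p in phages} & set(train_phage_ids))
        if overlap:
            raise ProtocolError(f"test phages also in training set: {overlap[:10]}")
    host_lineages = {}
    for host in candidates:
        if host.lineage is None:
            raise DataError(f"candidate host {host.id!r} has no lineage")
        host_lineages[host.id] = host.lineage
    cache = _host_vector_cache(model, candidates)
    rankings = [rank_hosts(p, candidates, model, host_cache=cache) for p in phages]
    predictions = [(r.phage_id, r.predicted_host_id) for r in rankings]
    report = hierarchical_accuracy(predictions, truth, host_lineages)
    return report, rankings


def pair_accuracy(model: DualTowerNetwork, pairs,
                  genomes: dict[str, GenomeRecord]) -> float:
    """Binary match/non-match accuracy on labelled held-out pairs."""
    correct = 0
    cache: dict[str, np.ndarray] = {}
    for p in pairs:
        for gid in (p.phage_id, p.host_id):
            if gid not in cache:
                cache[gid] = genome_token_ids(genomes[gid], model.cfg)
        logits = model.pair_logits(cache[p.phage_id], cache[p.host_id],
                                   training=False)
        correct += int(int(logits.data[0].argmax()) == p.label)
    return correct / len(pairs)


def write_report(report: RankAccuracyReport, path: str | Path,
                 method: str = "siamphage") -> None:
    """Tab-separated report row: Method / Genus / Family / Order / Class /
    Phylum (accuracies as fractions)."""
    with open(path, "w") as fh:
        fh.write("Method\tGenus\tFamily\tOrder\tClass\tPhylum\n")
        row = report.as_row()
        fh.write(method + "\t" +
                 "\t".join(f"{row[r]:.4f}" for r in RANKS) + "\n")


def write_rankings(rankings: list[HostRanking], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phage_id\thost_id\tp_match\trank\n")
        for r in rankings:
            for i, (host_id, score) in enumerate(r.scored_hosts, start=1):
                fh.write(f"{r.phage_id}\t{host_id}\t{score:.6f}\t{i}\n")
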