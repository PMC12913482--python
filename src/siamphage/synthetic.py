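"""Synthetic phage-host benchmark generator.

Real phage-host data couples hosts to a five-rank taxonomy (genus, family,
order, class, phylum) whose clades differ in k-mer composition, and phages
whose composition partially mirrors that of their true host — the signal all
alignment-free host-prediction methods exploit. This module plants exactly
that structure, nothing more (no genes, no GC skew, no prophages):

* every phylum gets an order-2 Markov chain over {A,C,G,T} whose transition
  rows are Dirichlet draws; child clades inherit a mixture of the parent's
  rows with fresh Dirichlet noise, so compositional similarity decays with
  taxonomic distance;
* a clade's :class:`CompositionProfile` is the *stationary* 3-mer law of its
  chain, which makes the empirical 3-mer frequency of a generated genome
  converge to the stated profile;
* a phage follows, per emitted base, a mixture
  ``mimicry_strength * P_host(next | prev two) + (1 - mimicry_strength)/4``,
  so ``mimicry_strength`` is a single dial from no signal (iid uniform) to a
  perfect copy of the host clade's composition;
* labelled pairs combine one positive (true host) per phage with negatives
  drawn uniformly among hosts from a *different phylum* than the true host.

Everything is a pure function of (config, seed); per-genome streams are
derived from the global seed and a CRC of the genome id, so regeneration of
any single record is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError, SamplingInfeasibleError
from .records import GenomeRecord, InteractionPair, TaxonomyLineage

__all__ = [
    "CompositionProfile",
    "SyntheticConfig",
    "build_pair_dataset",
    "generate_dataset",
    "generate_host_genome",
    "generate_phage_genome",
    "generate_profiles",
    "generate_taxonomy",
    "kmer_frequency",
    "nearest_composition_host",
    "read_pair_table",
    "write_pair_table",
]

_BASES = "ACGT"
_RANK_PREFIX = {"phylum": "phy", "class_": "cls", "order": "ord",
                "family": "fam", "genus": "gen"}


@dataclass(frozen=True)
class CompositionProfile:
    """Probability vector over the 4^k canonical k-mers of a clade."""

    kmer_weights: np.ndarray  # (4^k,), non-negative, sums to 1
    rank_scope: str = "genus"

    def __post_init__(self):
        w = np.asarray(self.kmer_weights, dtype=np.float64)
        if np.any(w < 0):
            raise ConfigurationError("profile weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"profile weights sum to {w.sum()}, not 1")
        object.__setattr__(self, "kmer_weights", w)

    @property
    def k(self) -> int:
        return int(round(np.log(len(self.kmer_weights)) / np.log(4)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark."""

    n_phyla: int = 4
    children_per_node: int = 1
    hosts_per_genus: int = 2
    phages_per_host: int = 3
    host_length: int = 20_000
    phage_length: int = 20_000
    mimicry_strength: float = 0.9
    profile_concentration: float = 1.0
    rank_inheritance: float = 0.75  # weight on the parent's transition rows
    seed: int = 0

    def __post_init__(self):
        for name in ("n_phyla", "children_per_node", "hosts_per_genus",
                     "phages_per_host", "host_length", "phage_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.mimicry_strength <= 1.0:
            raise ConfigurationError("mimicry_strength must be in [0, 1]")
        if self.profile_concentration <= 0:
            raise ConfigurationError("profile_concentration must be positive")
        if not 0.0 <= self.rank_inheritance <= 1.0:
            raise ConfigurationError("rank_inheritance must be in [0, 1]")


def generate_taxonomy(cfg: SyntheticConfig) -> list[TaxonomyLineage]:
    """Enumerate a proper five-rank tree: ``n_phyla`` roots, each inner node
    with ``children_per_node`` children, yielding
    n_phyla * children_per_node^4 genus-level lineages."""
    lineages = []
    b = cfg.children_per_node
    for path in np.ndindex(cfg.n_phyla, b, b, b, b):
        names = {}
        for depth, rank in enumerate(("phylum", "class_", "order", "family", "genus")):
            names[rank] = _RANK_PREFIX[rank] + ".".join(str(p) for p in path[:depth + 1])
        lineages.append(TaxonomyLineage(genus=names["genus"], family=names["family"],
                                        order=names["order"], class_=names["class_"],
                                        phylum=names["phylum"]))
    return lineages


# ---------------------------------------------------------------------------
# clade composition model: order-2 Markov chains perturbed down the ranks
# ---------------------------------------------------------------------------

def _stationary_3mer(transitions: np.ndarray) -> np.ndarray:
    """Stationary 3-mer distribution of an order-2 chain.

    ``transitions`` is (16, 4): row ``4*a + b`` holds P(next | prev = ab).
    The chain over 2-mer states moves (a,b) -> (b,c); its stationary law pi
    gives the 3-mer law w(abc) = pi(ab) * P(c | ab).
    """
    m = np.zeros((16, 16))
    for s in range(16):
        b = s % 4
        for c in range(4):
            m[s, 4 * b + c] = transitions[s, c]
    pi = np.full(16, 1 / 16)
    for _ in range(500):
        pi = pi @ m
    pi /= pi.sum()
    w = (pi[:, None] * transitions).reshape(64)
    return w / w.sum()


def _dirichlet_rows(rng: np.random.Generator, concentration: float) -> np.ndarray:
    return rng.dirichlet(np.full(4, concentration), size=16)


def generate_profiles(cfg: SyntheticConfig) -> dict[str, CompositionProfile]:
    """Genus name -> stationary 3-mer profile, with clade structure.

    Transition rows are drawn per phylum and perturbed toward fresh Dirichlet
    noise at every step down the tree, so genera sharing low ranks have more
    similar profiles than genera that only share a phylum.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    b = cfg.children_per_node
    profiles: dict[str, CompositionProfile] = {}

    # walk the tree depth-first so each node's chain derives from its parent
    def descend(depth: int, parent_rows: np.ndarray | None, path: tuple[int, ...]):
        if parent_rows is None:
            rows = _dirichlet_rows(rng, cfg.profile_concentration)
        else:
            fresh = _dirichlet_rows(rng, cfg.profile_concentration)
            rows = cfg.rank_inheritance * parent_rows + (1 - cfg.rank_inheritance) * fresh
        if depth == 4:  # genus level
            genus = _RANK_PREFIX["genus"] + ".".join(str(p) for p in path)
            profiles[genus] = CompositionProfile(_stationary_3mer(rows), "genus")
            return
        for child in range(b):
            descend(depth + 1, rows, path + (child,))

    for phylum in range(cfg.n_phyla):
        descend(0, None, (phylum,))
    return profiles


def _transitions_from_profile(weights: np.ndarray) -> np.ndarray:
    """Recover P(c | ab) and the 2-mer marginal from a 3-mer law."""
    w3 = weights.reshape(16, 4)
    row_sum = w3.sum(axis=1, keepdims=True)
    trans = np.where(row_sum > 0, w3 / np.where(row_sum == 0, 1, row_sum), 0.25)
    return trans, row_sum.reshape(16)


def _sample_chain(length: int, transitions: np.ndarray, start_p: np.ndarray,
                  rng: np.random.Generator) -> str:
    """Emit ``length`` bases from an order-2 chain."""
    cum = np.cumsum(transitions, axis=1)
    cum[:, -1] = 1.0
    start = start_p / start_p.sum() if start_p.sum() > 0 else np.full(16, 1 / 16)
    state = int(rng.choice(16, p=start))
    out = [_BASES[state // 4], _BASES[state % 4]]
    if length == 1:
        return out[0]
    u = rng.random(max(length - 2, 0))
    for i in range(length - 2):
        c = int(np.searchsorted(cum[state], u[i], side="right"))
        out.append(_BASES[c])
        state = (state % 4) * 4 + c
    return "".join(out[:length])


def _genome_rng(cfg: SyntheticConfig, genome_id: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, zlib.crc32(genome_id.encode())])


def generate_host_genome(lineage: TaxonomyLineage,
                         profiles: dict[str, CompositionProfile],
                         cfg: SyntheticConfig, id: str) -> GenomeRecord:
    """Sample a host genome from its genus profile's order-2 chain."""
    if lineage.genus not in profiles:
        raise DataError(f"no composition profile for genus {lineage.genus!r}")
    profile = profiles[lineage.genus]
    trans, marginal2 = _transitions_from_profile(profile.kmer_weights)
    rng = _genome_rng(cfg, id)
    seq = _sample_chain(cfg.host_length, trans, marginal2, rng)
    return GenomeRecord(id=id, sequence=seq, role="host", lineage=lineage)


def generate_phage_genome(host: GenomeRecord,
                          profiles: dict[str, CompositionProfile],
                          cfg: SyntheticConfig, id: str) -> GenomeRecord:
    """Sample a phage that mimics its host clade's composition.

    Each base follows ``m * P_host(c | ab) + (1 - m)/4`` with
    ``m = mimicry_strength``: m=0 gives an iid-uniform genome, m=1 reproduces
    the host clade's chain exactly.
    """
    if host.lineage is None:
        raise DataError(f"host {host.id!r} has no lineage")
    profile = profiles[host.lineage.genus]
    host_trans, _ = _transitions_from_profile(profile.kmer_weights)
    m = cfg.mimicry_strength
    mixed = m * host_trans + (1 - m) * 0.25
    mixed_profile = _stationary_3mer(mixed)
    _, marginal2 = _transitions_from_profile(mixed_profile)
    rng = _genome_rng(cfg, id)
    seq = _sample_chain(cfg.phage_length, mixed, marginal2, rng)
    return GenomeRecord(id=id, sequence=seq, role="phage",
                        lineage=host.lineage, true_host_id=host.id)


def generate_dataset(cfg: SyntheticConfig
                     ) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Full benchmark: (hosts, phages) with ids ``host_<genus>_<i>`` and
    ``phage_<host>_<j>``. Hosts carry lineages; phages carry true-host ids."""
    profiles = generate_profiles(cfg)
    hosts, phages = [], []
    for lineage in generate_taxonomy(cfg):
        for i in range(cfg.hosts_per_genus):
            host = generate_host_genome(lineage, profiles, cfg,
                                        id=f"host_{lineage.genus}_{i}")
            hosts.append(host)
            for j in range(cfg.phages_per_host):
                phages.append(generate_phage_genome(
                    host, profiles, cfg, id=f"phage_{host.id}_{j}"))
    return hosts, phages


def build_pair_dataset(phages: list[GenomeRecord], hosts: list[GenomeRecord],
                       negatives_per_positive: int = 1,
                       seed: int = 0) -> list[InteractionPair]:
    """One positive pair per phage plus phylum-exclusion negatives.

    Negative hosts are drawn uniformly, without replacement per phage, among
    hosts whose phylum differs from the phage's true host's phylum. Raises
    :class:`SamplingInfeasibleError` when all hosts share one phylum (the
    exclusion rule cannot be satisfied).
    """
    if negatives_per_positive < 0:
        raise ConfigurationError("negatives_per_positive must be >= 0")
    host_by_id = {h.id: h for h in hosts}
    phyla = {h.lineage.phylum for h in hosts if h.lineage is not None}
    if len(phyla) < 2 and negatives_per_positive > 0:
        raise SamplingInfeasibleError(
            "all hosts share one phylum; phylum-exclusion negatives are impossible")
    rng = np.random.default_rng(seed)
    pairs: list[InteractionPair] = []
    for phage in phages:
        if phage.true_host_id is None or phage.true_host_id not in host_by_id:
            raise DataError(f"phage {phage.id!r}: true host not among hosts")
        true_host = host_by_id[phage.true_host_id]
        pairs.append(InteractionPair(phage.id, true_host.id, 1))
        if negatives_per_positive == 0:
            continue
        candidates = sorted(h.id for h in hosts
                            if h.lineage.phylum != true_host.lineage.phylum)
        if len(candidates) < negatives_per_positive:
            raise SamplingInfeasibleError(
                f"phage {phage.id!r}: only {len(candidates)} out-of-phylum hosts "
                f"for {negatives_per_positive} requested negatives")
        chosen = rng.choice(len(candidates), size=negatives_per_positive,
                            replace=False)
        for c in sorted(chosen):
            pairs.append(InteractionPair(phage.id, candidates[c], 0))
    return pairs


# ---------------------------------------------------------------------------
# composition utilities / naive baseline
# ---------------------------------------------------------------------------

def kmer_frequency(sequence: str, k: int = 3) -> np.ndarray:
    """Empirical frequency vector over the 4^k k-mers (non-ACGT windows
    ignored)."""
    from .sequence import encode_kmer_ids

    ids = encode_kmer_ids(sequence, k)
    counts = np.bincount(ids[ids < 4 ** k], minlength=4 ** k).astype(np.float64)
    total = counts.sum()
    return counts / total if total > 0 else counts


def nearest_composition_host(phage: GenomeRecord, hosts: list[GenomeRecord],
                             k: int = 3) -> str:
    """Naive alignment-free baseline: the host whose k-mer frequency vector
    has the highest cosine similarity with the phage's. Serves as the in-repo
    oracle showing the planted signal is recoverable before any training."""
    pv = kmer_frequency(phage.sequence, k)
    best_id, best_sim = None, -np.inf
    for host in sorted(hosts, key=lambda h: h.id):
        hv = kmer_frequency(host.sequence, k)
        sim = float(pv @ hv / (np.linalg.norm(pv) * np.linalg.norm(hv) + 1e-12))
        if sim > best_sim:
            best_id, best_sim = host.id, sim
    return best_id


# ---------------------------------------------------------------------------
# pair-table I/O (tab-separated, header: phage_id host_id label)
# ---------------------------------------------------------------------------

def write_pair_table(pairs: list[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phage_id\thost_id\tlabel\n")
        for p in pairs:
            fh.write(f"{p.phage_id}\t{p.host_id}\t{p.label}\n")


def read_pair_table(path: str | Path) -> list[InteractionPair]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"phage_id": str, "host_id": str,
                                            "label": int})
    for col in ("phage_id", "host_id", "label"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return [InteractionPair(r["phage_id"], r["host_id"], int(r["label"]))
            for r in df.to_dict("records")]
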