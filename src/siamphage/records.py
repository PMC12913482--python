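"""Domain records shared across the package.

A dataset is a collection of :class:`GenomeRecord` objects (phages and hosts),
a lineage for every host, and a table of labelled :class:`InteractionPair`
rows. Hosts carry their own five-rank lineage; phages carry the identifier and
lineage of their true host when that ground truth is known (synthetic data and
training sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("genus", "family", "order", "class_", "phylum")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Five-rank host lineage, finest (genus) to coarsest (phylum)."""

    genus: str
    family: str
    order: str
    class_: str
    phylum: str

    def __post_init__(self):
        for rank in RANKS:
            if not getattr(self, rank):
                raise ValueError(f"lineage rank {rank!r} must be non-empty")

    def name_at(self, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def as_tuple(self) -> tuple[str, str, str, str, str]:
        return (self.genus, self.family, self.order, self.class_, self.phylum)


@dataclass
class GenomeRecord:
    """One genome sequence plus its role and (optional) taxonomic context."""

    id: str
    sequence: str
    role: str  # "phage" | "host"
    lineage: TaxonomyLineage | None = None
    true_host_id: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        if self.role not in ("phage", "host"):
            raise ValueError(f"genome {self.id!r}: role must be 'phage' or 'host'")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InteractionPair:
    """A (phage, host) pair with a binary interaction label."""

    phage_id: str
    host_id: str
    label: int  # 1 = match, 0 = non-match

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (non-match) or 1 (match)")


@dataclass
class HostRanking:
    """All candidate hosts for one phage, sorted by descending match score."""

    phage_id: str
    scored_hosts: list[tuple[str, float]]

    @property
    def predicted_host_id(self) -> str:
        return self.scored_hosts[0][0]


@dataclass
class RankAccuracyReport:
    """Host-prediction accuracy at each of the five taxonomic ranks."""

    n_total: int
    per_rank: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for rank, acc in self.per_rank.items():
            if rank not in RANKS:
                raise KeyError(f"unknown rank {rank!r}")
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy at {rank} outside [0, 1]: {acc}")

    def as_row(self) -> dict[str, float]:
        return {rank: self.per_rank[rank] for rank in RANKS}
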