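"""Genome I/O and the fixed-width segmentation / k-mer tokenisation front end.

A genome of length ``N`` is cut into ``ceil(N / segment_length)`` windows of
exactly ``segment_length`` bases; the final window is right-padded with the
PAD symbol so every window has identical width (the CNN needs fixed-size
inputs, and the pad region is arranged to contribute zeros downstream: every
k-mer window touching a PAD or ambiguity base becomes the UNK token, whose
embedding vector is pinned to zero).

Coordinates are 0-based half-open throughout. Only the forward strand is
tokenised by default; reverse-complement canonicalisation is available via
``canonical=True`` on :func:`tokenize_kmers` for users who want strand
symmetry, but is off by default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractError, FormatError
from .records import GenomeRecord, TaxonomyLineage

SEGMENT_LENGTH = 2000
K = 3
PAD_BASE = "-"
UNK = "UNK"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def read_fasta(path: str | Path, role: str = "host") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; the header token before the first whitespace
    becomes the record id. Raises :class:`FormatError` on an empty file or a
    zero-length entry.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: entry #{i} ({rec.id!r}) has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq, role=role))
    if not records:
        raise FormatError(f"{path}: no FASTA entries found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate ids {dupes}")
    return records


def write_fasta(records: list[GenomeRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def segment_genome(record: GenomeRecord | str,
                   segment_length: int = SEGMENT_LENGTH) -> list[str]:
    """Cut a genome into fixed-width windows, right-padding the last one.

    Returns exactly ``ceil(N / segment_length)`` strings of ``segment_length``
    symbols each; concatenating them and stripping trailing PAD recovers the
    input sequence.
    """
    seq = record.sequence if isinstance(record, GenomeRecord) else record
    if not seq:
        raise ContractError("cannot segment an empty sequence")
    n = len(seq)
    n_segments = -(-n // segment_length)  # ceil
    padded = seq + PAD_BASE * (n_segments * segment_length - n)
    return [padded[i * segment_length:(i + 1) * segment_length]
            for i in range(n_segments)]


def pad_lengths(record: GenomeRecord | str,
                segment_length: int = SEGMENT_LENGTH) -> list[int]:
    """Per-segment count of padded positions (non-zero only for the last)."""
    seq = record.sequence if isinstance(record, GenomeRecord) else record
    n = len(seq)
    n_segments = -(-n // segment_length)
    pads = [0] * n_segments
    pads[-1] = n_segments * segment_length - n
    return pads


def tokenize_kmers(segment: str, k: int = K,
                   expected_length: int | None = SEGMENT_LENGTH,
                   canonical: bool = False) -> list[str]:
    """Overlapping k-mer tokens of a segment.

    Returns ``len(segment) - k + 1`` tokens; any window containing a
    non-ACGT symbol (PAD or an IUPAC ambiguity code) becomes UNK. With
    ``canonical=True`` each k-mer is replaced by the lexicographic minimum of
    itself and its reverse complement.
    """
    if expected_length is not None and len(segment) != expected_length:
        raise ContractError(
            f"segment length {len(segment)} != expected {expected_length}")
    if len(segment) < k:
        raise ContractError(f"segment shorter than k={k}")
    ids = encode_kmer_ids(segment, k)
    vocab = _kmer_strings(k)
    tokens = [UNK if i == len(vocab) else vocab[i] for i in ids]
    if canonical:
        tokens = [t if t == UNK else min(t, t.translate(_COMPLEMENT)[::-1])
                  for t in tokens]
    return tokens


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode_kmer_ids(segment: str, k: int = K) -> np.ndarray:
    """Vectorised token ids: lexicographic k-mer index in [0, 4^k), or 4^k
    (the UNK id) for windows touching any non-ACGT symbol."""
    codes = _BASE_CODE[np.frombuffer(segment.encode("ascii"), dtype=np.uint8)]
    n_tokens = len(segment) - k + 1
    ids = np.zeros(n_tokens, dtype=np.int64)
    bad = np.zeros(n_tokens, dtype=bool)
    for j in range(k):
        window = codes[j:j + n_tokens]
        bad |= window < 0
        ids = ids * 4 + np.where(window < 0, 0, window)
    ids[bad] = 4 ** k
    return ids


def _kmer_strings(k: int) -> list[str]:
    from itertools import product
    return ["".join(p) for p in product("ACGT", repeat=k)]


def read_lineage_table(path: str | Path) -> dict[str, TaxonomyLineage]:
    """Read the tab-separated host-lineage table
    (columns: host_id genus family order class phylum)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["host_id", "genus", "family", "order", "class", "phylum"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return {
        row["host_id"]: TaxonomyLineage(genus=row["genus"], family=row["family"],
                                        order=row["order"], class_=row["class"],
                                        phylum=row["phylum"])
        for row in df.to_dict("records")
    }


def write_lineage_table(lineages: dict[str, TaxonomyLineage],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("host_id\tgenus\tfamily\torder\tclass\tphylum\n")
        for host_id in sorted(lineages):
            lin = lineages[host_id]
            fh.write("\t".join([host_id, *lin.as_tuple()]) + "\n")
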