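"""Protein sequence I/O and record-level filters.

Records are plain amino-acid sequences over the 20 standard one-letter codes
(plus ``X`` for unknown).  Ambiguity codes B, Z, U, O are rejected by default
because silently mis-scoring translated ORFs is worse than an explicit flag;
``allow_ambiguous=True`` maps them to ``X``, which contributes nothing to any
scored quantity downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
ACCEPTED_ALPHABET = STANDARD_RESIDUES | {"X"}
#: ambiguity/rare codes remapped to X under ``allow_ambiguous``
AMBIGUOUS_RESIDUES = set("BZUO")


class FastaParseError(ValueError):
    """Raised for malformed FASTA entries, naming the record and position."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with identifier and optional annotations."""

    id: str
    sequence: str
    description: str = ""
    source: str = "real"  # "real" | "synthetic"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        for pos, ch in enumerate(self.sequence):
            if ch not in ACCEPTED_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeSet:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


def _normalise_sequence(raw: str, record_id: str, allow_ambiguous: bool) -> str:
    seq = raw.upper().rstrip("*")
    if allow_ambiguous:
        seq = "".join("X" if ch in AMBIGUOUS_RESIDUES else ch for ch in seq)
    for pos, ch in enumerate(seq):
        if ch not in ACCEPTED_ALPHABET:
            raise FastaParseError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos + 1}"
            )
    return seq


def read_fasta(
    path: str | Path,
    source: str = "real",
    allow_ambiguous: bool = False,
) -> ProteomeSet:
    """Read a protein FASTA file into a :class:`ProteomeSet`.

    Sequences are uppercased and trailing ``*`` stop characters stripped;
    entry order is preserved.  Illegal residues raise
    :class:`FastaParseError` naming the record and 1-based position.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"{path}: FASTA entry with empty header")
        seq = _normalise_sequence(str(entry.seq), entry.id, allow_ambiguous)
        if not seq:
            raise FastaParseError(f"record {entry.id!r}: empty sequence")
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, description=entry.description, source=source)
        )
    return ProteomeSet(records=records, provenance=str(path))


def write_fasta(proteome: ProteomeSet, path: str | Path) -> Path:
    """Write a :class:`ProteomeSet` as standard 60-column FASTA.

    Output is byte-stable for identical input.  Writing an empty set is an
    error (an empty FASTA file is indistinguishable from a failed run).
    """
    if len(proteome) == 0:
        raise ValueError("refusing to write an empty proteome set")
    path = Path(path)
    bio_records = (
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        for rec in proteome
    )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio_records)
    return path


def filter_by_length(proteome: ProteomeSet, min_length: int = 100) -> ProteomeSet:
    """Retain records with at least ``min_length`` residues.

    The default of 100 aa is the standard cutoff separating genuine LEA
    proteins from fragments in proteome-wide surveys.  Idempotent.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [rec for rec in proteome if len(rec) >= min_length]
    removed = len(proteome) - len(kept)
    logger.info("length filter (>= %d aa): kept %d, removed %d", min_length, len(kept), removed)
    return ProteomeSet(records=kept, provenance=proteome.provenance)


def records_from_sequences(
    pairs: Iterable[tuple[str, str]], source: str = "synthetic"
) -> ProteomeSet:
    """Build a set from ``(id, sequence)`` pairs. Convenience for tests/drivers."""
    return ProteomeSet(records=[ProteinRecord(id=i, sequence=s, source=source) for i, s in pairs])
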