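"""Conserved-motif registry, motif scanning, dehydrin segments, subgroups.

The built-in registry holds the 28 MEME-derived consensus motifs (M1.1-M7.2)
that structure the seven LEA families (LEA1-LEA5, dehydrins, SMPs), each with
its family, consensus string, discovery e-value, and published GRAVY
reference.  Scanning matches degenerate consensus patterns by per-position
identity (position weight matrices are not available), so presence/absence of
a motif - the signal subgroup assignment consumes - is what the scanner is
built to report.

Dehydrin segment grammars:

* K-segment: ``KKG[_N][MF]M[DE]KIKEK`` - literal KKG, one optional N, one of
  M/F, literal M, one of D/E, literal KIKEK.
* Y-segment: exact ``DEYGNP``.
* S-segment: maximal runs matching any of SGSSSSSSS, TGSSSSSS, S7, S8;
  overlapping matches are merged into one maximal hit.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from lea_profiler.seq_io import ProteinRecord

FAMILIES = ("LEA1", "LEA2", "LEA3", "LEA4", "LEA5", "DEH", "SMP")

# (name, family, consensus, discovery e-value or None, printed GRAVY)
_TABLE_MOTIFS: list[tuple[str, str, str, float | None, float]] = [
    ("M1.1", "LEA1", "TKATVQEKAEQMKTRDPLQKEMATQKKEAKIQEAERQKQEARQQNSAAKH", 1.25e-52, -1.786),
    ("M1.2", "LEA1", "MQAAKETAANVAASANSGMEK", 3.8e-21, -0.352),
    ("M2.1", "LEA2", "IEETIGFGKPTADVTDVDLKDINLEKADYVVDVLVKNPYPIPIPLIDINY", 5.4e-55, 0.048),
    ("M2.2", "LEA2", "KSTYADIGPGWIIPYRLKVDLIVDVPVFGRLTLPLEKKGEIPIPYKPDID", 2.7e-55, -0.018),
    ("M2.3", "LEA2", "IRFDKFSFEETVATLHLKLENKNDFDLGLKDLDYEVWLCNVSIGGAYMKK", 5.1e-63, -0.268),
    ("M2.4", "LEA2", "TLNLTVTVRNPNFYSIKYDSSTVSIGYRGNKLGRVTIPAGRIGARSSQRV", 1.1e-44, -0.328),
    ("M2.5", "LEA2", "ITFRPKDFGSALWDMIRGKGTGYTIKGNINVDTPFGFMKLPISKEGGTTC", 1.9e-64, -0.238),
    ("M2.6", "LEA2", "SGLIPDAGSLKAHGSTTVKVPICLIYDDI", 1.9e-34, 0.444),
    ("M2.7", "LEA2", "NATLQLERVEIMSDVILLLEDLAKGEIMFDTEVDISGKLRVFFFDLPLKT", 3.1e-57, 0.376),
    ("M2.8", "LEA2", "RNPNKRIGIYYDQIDAYASYK", 1.6e-22, -1.200),
    ("M2.9", "LEA2", "GGGKRINDKGWPECNVIMEEGKYD", 1.2e-28, -1.204),
    ("M3.1", "LEA3", "TYDKNPDEEHAFSAVVPDNVIPPQTQQYWAPHPKTGVFGPA", 1.8e-53, -0.817),
    ("M3.2", "LEA3", "SVSNGGADSVLEQKAFFRPLEDLDKPHHP", 1.6e-36, -0.766),
    ("M3.3", "LEA3", "MAANLQSRGLASFSKQFVIRVRSRDSTII", 2.4e-35, 0.048),
    ("M3.4", "LEA3", "IRMLNKESEEPTKISWVPDPVTGYYRPENKATEIDAAELRRILIKDNTRR", 1.9e-48, -0.994),
    ("M3.5", "LEA3", "RRGVHV", 1e-8, -0.700),
    ("M4.1", "LEA4", "AKDYVADKAKEAKDSAAEKAKETKDKAGE", 8.5e-29, -1.617),
    ("M4.2", "LEA4", "IIGSLIGTVQGTVEHAKEAVLGKSQEASE", None, 0.059),
    ("M4.3", "LEA4", "AKMKAEDTTEAAKETYEETKENARKKMEEMKIVGEG", None, -1.962),
    ("M4.4", "LEA4", "AKEKAKEAKDSAKDKAGETKD", None, -1.438),
    ("M5.1", "LEA5", "QDKRAELDAKASQGETVVPGGTGGKSLEAQEHLAEGRSKGGQTRKEQMGT", 1.8e-60, -1.228),
    ("M5.2", "LEA5", "YQEMGRKGGLSSNDKSGAERAEEEGITID", 3.4e-36, -1.256),
    ("M6.1", "DEH", "GGGGVAGQEEPEKKGMMDKIKEKLPGGHH", 2.3e-30, -1.214),
    ("M6.2", "DEH", "GPTTGPPKHRRSGSSSSSSSEDDGMGGRR", 8.4e-33, -1.679),
    ("M6.3", "DEH", "MAEYGGNYGNETKQTDEYGNPVHHPQGGG", 7.2e-37, -1.559),
    ("M6.4", "DEH", "KGLKDKIKEKLPGGKKETEPP", 5.4e-23, -1.710),
    ("M7.1", "SMP", "PQDAATMQAAENSVLGQTQKGGVAATMQSAANRNERAGVVGHNDVTDIIS", 3.5e-60, -0.402),
    ("M7.2", "SMP", "SAAGDKPVDESDAAAIQAAEARATGLGRVVPGGLGAEAKSA", 1.3e-48, -0.090),
]

#: per-position element of a degenerate pattern
Position = tuple[frozenset, bool]  # (allowed residues, optional)


def parse_pattern(text: str) -> list[Position]:
    """Parse a degenerate pattern string into per-position allowed sets.

    Plain letters are fixed positions; ``[...]`` lists the allowed residues
    at one position; a ``_`` inside brackets marks the position optional
    (``[_N]`` = one optional N).
    """
    positions: list[Position] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            close = text.find("]", i)
            if close < 0:
                raise ValueError(f"unclosed bracket in pattern {text!r}")
            body = text[i + 1 : close]
            optional = "_" in body
            allowed = frozenset(body.replace("_", ""))
            if not allowed:
                raise ValueError(f"empty bracket in pattern {text!r}")
            positions.append((allowed, optional))
            i = close + 1
        elif ch.isalpha():
            positions.append((frozenset(ch), False))
            i += 1
        else:
            raise ValueError(f"unexpected character {ch!r} in pattern {text!r}")
    return positions


@dataclass(frozen=True)
class MotifDefinition:
    """One named consensus motif with its degenerate pattern."""

    name: str
    family: str
    consensus: str
    pattern: tuple[Position, ...] = ()
    evalue: float | None = None
    printed_gravy: float | None = None

    def __post_init__(self) -> None:
        pattern = self.pattern or tuple(parse_pattern(self.consensus))
        object.__setattr__(self, "pattern", pattern)
        # the consensus must be realisable by the pattern (optional positions
        # may be absent from it)
        required = [p for p in pattern if not p[1]]
        if len(required) > len(self.consensus) or len(pattern) < len(self.consensus):
            raise ValueError(f"motif {self.name}: pattern/consensus length mismatch")
        if not self._consensus_matches():
            raise ValueError(f"motif {self.name}: consensus not accepted by pattern")

    def _consensus_matches(self) -> bool:
        for keep in _optional_subsets(self.pattern):
            variant = [p for p, k in zip(self.pattern, keep) if k]
            if len(variant) == len(self.consensus) and all(
                ch in allowed for ch, (allowed, _) in zip(self.consensus, variant)
            ):
                return True
        return False

    @property
    def length(self) -> int:
        return len(self.consensus)


def _optional_subsets(pattern: tuple[Position, ...]):
    """Yield keep-masks over the pattern, toggling optional positions."""
    optional_idx = [i for i, (_, opt) in enumerate(pattern) if opt]
    for drops in itertools.chain.from_iterable(
        itertools.combinations(optional_idx, r) for r in range(len(optional_idx) + 1)
    ):
        yield [i not in drops for i in range(len(pattern))]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    protein: str
    start: int  # 0-based half-open
    end: int
    identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit coordinates")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


@dataclass(frozen=True)
class SegmentHit:
    kind: str  # "K" | "Y" | "S"
    protein: str
    start: int
    end: int
    matched_text: str


def default_registry() -> dict[str, MotifDefinition]:
    """The built-in registry of all 28 consensus motifs."""
    return {
        name: MotifDefinition(
            name=name, family=family, consensus=consensus,
            evalue=evalue, printed_gravy=printed,
        )
        for name, family, consensus, evalue, printed in _TABLE_MOTIFS
    }


def load_registry(config: str | Path | None = None) -> dict[str, MotifDefinition]:
    """Load the default registry, optionally adding/overriding from YAML.

    The YAML is a list of mappings with keys ``name``, ``family``,
    ``consensus`` and optionally ``pattern``, ``evalue``, ``gravy``.
    """
    registry = default_registry()
    if config is None:
        return registry
    with open(config) as handle:
        entries = yaml.safe_load(handle) or []
    for entry in entries:
        try:
            pattern = tuple(parse_pattern(entry["pattern"])) if "pattern" in entry else ()
            motif = MotifDefinition(
                name=entry["name"],
                family=entry["family"],
                consensus=entry["consensus"],
                pattern=pattern,
                evalue=entry.get("evalue"),
                printed_gravy=entry.get("gravy"),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"invalid motif entry {entry!r}: {exc}") from exc
        registry[motif.name] = motif
    return registry


def _window_identity(sequence: str, start: int, variant: list[Position]) -> float:
    matched = sum(
        1 for offset, (allowed, _) in enumerate(variant) if sequence[start + offset] in allowed
    )
    return matched / len(variant)


def scan_motif(
    record: ProteinRecord, motif: MotifDefinition, min_identity: float = 0.8
) -> list[MotifHit]:
    """Non-overlapping motif hits by per-position pattern identity.

    Every window whose match fraction reaches ``min_identity`` is a
    candidate; candidates are taken greedily left to right, and where several
    variants share a start (optional positions present/absent) the higher
    identity wins, longer variant breaking exact ties.
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    variants = []
    for keep in _optional_subsets(motif.pattern):
        variant = [p for p, k in zip(motif.pattern, keep) if k]
        if variant:
            variants.append(variant)
    seq = record.sequence
    # best candidate per start: (identity, length)
    best: dict[int, tuple[float, int]] = {}
    for variant in variants:
        width = len(variant)
        for start in range(len(seq) - width + 1):
            identity = _window_identity(seq, start, variant)
            if identity >= min_identity:
                cand = (identity, width)
                if start not in best or cand > best[start]:
                    best[start] = cand
    hits: list[MotifHit] = []
    cursor = 0
    for start in sorted(best):
        if start < cursor:
            continue
        identity, width = best[start]
        hits.append(MotifHit(motif.name, record.id, start, start + width, identity))
        cursor = start + width
    return hits


K_SEGMENT_RE = re.compile(r"KKGN?[MF]M[DE]KIKEK")
Y_SEGMENT_RE = re.compile(r"DEYGNP")
DEFAULT_S_PATTERNS = ("SGSSSSSSS", "TGSSSSSS", "S{7}", "S{8}")


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def detect_dehydrin_segments(
    record: ProteinRecord, s_patterns: tuple[str, ...] = DEFAULT_S_PATTERNS
) -> list[SegmentHit]:
    """K-, Y- and S-segment hits under the literal dehydrin grammars."""
    seq = record.sequence
    hits: list[SegmentHit] = []
    for kind, regex in (("K", K_SEGMENT_RE), ("Y", Y_SEGMENT_RE)):
        pos = 0
        while (m := regex.search(seq, pos)) is not None:
            hits.append(SegmentHit(kind, record.id, m.start(), m.end(), m.group()))
            pos = m.end()
    s_intervals: list[tuple[int, int]] = []
    for pattern in s_patterns:
        regex = re.compile(pattern)
        for start in range(len(seq)):
            if (m := regex.match(seq, start)) is not None:
                s_intervals.append((m.start(), m.end()))
    for start, end in _merge_intervals(s_intervals):
        hits.append(SegmentHit("S", record.id, start, end, seq[start:end]))
    hits.sort(key=lambda h: (h.start, h.kind))
    return hits


def motif_presence_profile(
    record: ProteinRecord,
    registry: dict[str, MotifDefinition] | None = None,
    min_identity: float = 0.8,
) -> set[str]:
    """Names of registry motifs with at least one hit in the record."""
    registry = registry if registry is not None else default_registry()
    return {
        name
        for name, motif in registry.items()
        if scan_motif(record, motif, min_identity=min_identity)
    }


# Subgroup rule tables: ordered (subgroup, required motifs, forbidden motifs).
# Most specific (largest required set) first; first rule whose requirements
# are met fires.  No rule firing yields "<family>.0".
_SUBGROUP_RULES: dict[str, list[tuple[str, frozenset, frozenset]]] = {
    "LEA1": [
        ("LEA1.1", frozenset({"M1.1", "M1.2"}), frozenset()),
        ("LEA1.2", frozenset({"M1.1"}), frozenset()),
        ("LEA1.3", frozenset({"M1.2"}), frozenset()),
    ],
    "LEA2": [
        ("LEA2.1", frozenset({"M2.1", "M2.2", "M2.6", "M2.3", "M2.5"}), frozenset()),
        ("LEA2.2", frozenset({"M2.1", "M2.2", "M2.6"}), frozenset()),
        ("LEA2.3", frozenset({"M2.4"}), frozenset()),
        ("LEA2.4", frozenset({"M2.9"}), frozenset()),
        ("LEA2.5", frozenset({"M2.8"}), frozenset()),
    ],
    "LEA3": [
        ("LEA3.2", frozenset({"M3.4"}), frozenset()),
        ("LEA3.1", frozenset({"M3.1"}), frozenset()),
        ("LEA3.1", frozenset({"M3.2"}), frozenset()),
        ("LEA3.1", frozenset({"M3.3"}), frozenset()),
        ("LEA3.1", frozenset({"M3.5"}), frozenset()),
    ],
    "LEA4": [
        ("LEA4.1", frozenset({"M4.3"}), frozenset()),
        ("LEA4.2", frozenset({"M4.2"}), frozenset()),
        ("LEA4.3", frozenset({"M4.1"}), frozenset()),
        ("LEA4.3", frozenset({"M4.4"}), frozenset()),
    ],
    # LEA5 has no published subdivision: any family motif keeps the family label
    "LEA5": [
        ("LEA5", frozenset({"M5.1"}), frozenset()),
        ("LEA5", frozenset({"M5.2"}), frozenset()),
    ],
    "DEH": [
        ("DEH1", frozenset({"M6.3"}), frozenset()),
        ("DEH2", frozenset({"M6.1"}), frozenset()),
        ("DEH2", frozenset({"M6.2"}), frozenset()),
        ("DEH2", frozenset({"M6.4"}), frozenset()),
    ],
    "SMP": [
        ("SMP3", frozenset({"M7.1", "M7.2"}), frozenset()),
        ("SMP2", frozenset({"M7.1"}), frozenset()),
        ("SMP1", frozenset({"M7.2"}), frozenset()),
    ],
}


def assign_subgroup(family: str, present: set[str]) -> str:
    """Deterministic subgroup label from the set of motifs present.

    Rules are evaluated most-specific first (e.g. the extended LEA2.1 motif
    set before LEA2.2; DEH1's determinant M6.3 before the generic dehydrin
    motifs).  If no rule fires the label is ``<family>.0``.
    """
    if family not in _SUBGROUP_RULES:
        raise ValueError(f"unknown family {family!r}")
    for label, required, forbidden in _SUBGROUP_RULES[family]:
        if required <= present and not (forbidden & present):
            return label
    return f"{family}.0"
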