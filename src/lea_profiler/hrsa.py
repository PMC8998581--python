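"""Additive hydroxyl-radical scavenging ability (HRSA) score.

The score sums (or averages) per-residue scavenging rates measured for free
amino acids by EPR spin trapping of Fenton-generated HO radicals.  Those
measured rate constants are not redistributable here, so the shipped default
table is ORDINAL ONLY: it encodes the published rank order

    Trp > Phe, Leu > Ile > His > Arg > Val > Lys, Tyr, Pro >
    Gln, Thr, Ser > Glu, Ala, Gly, Asn, Asp

as tier values 9..1 and is labelled non-quantitative.  Cys and Met are
absent from that rank order and sit unconstrained at a mid value.  Supplying
a measured table via YAML yields quantitative scores; with the ordinal table
only rank-based comparisons between proteins are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from lea_profiler.seq_io import STANDARD_RESIDUES

#: published scavenging-rate rank order; residues in one tier are tied
RANK_TIERS: tuple[tuple[str, ...], ...] = (
    ("W",),
    ("F", "L"),
    ("I",),
    ("H",),
    ("R",),
    ("V",),
    ("K", "Y", "P"),
    ("Q", "T", "S"),
    ("E", "A", "G", "N", "D"),
)

#: residues the published rank order does not place
UNRANKED_RESIDUES = ("C", "M")


@dataclass(frozen=True)
class HRSATable:
    """Residue -> scavenging rate (arbitrary units, all >= 0)."""

    rates: dict[str, float]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.rates)
        if missing:
            raise ValueError(f"HRSA table {self.name!r} missing residues: {sorted(missing)}")
        negative = [r for r, v in self.rates.items() if v < 0]
        if negative:
            raise ValueError(f"HRSA table {self.name!r} has negative rates: {negative}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.rates[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} absent from HRSA table {self.name!r}") from None


@dataclass(frozen=True)
class HRSAScore:
    protein: str
    score: float
    mode: str  # "sum" | "mean"

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("HRSA score must be >= 0")


def default_hrsa_table() -> HRSATable:
    """Ordinal placeholder table: tier ranks 9 (Trp) down to 1, non-quantitative."""
    rates: dict[str, float] = {}
    n = len(RANK_TIERS)
    for level, tier in enumerate(RANK_TIERS):
        for residue in tier:
            rates[residue] = float(n - level)
    for residue in UNRANKED_RESIDUES:
        rates[residue] = 5.0
    return HRSATable(rates=rates, name="ordinal-tiers")


def load_hrsa_table(path: str | Path) -> HRSATable:
    """Load a rate table from YAML (mapping ``rates:`` plus optional ``name:``)."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return HRSATable(rates={str(k): float(v) for k, v in data["rates"].items()},
                     name=str(data.get("name", Path(path).stem)))


def validate_rank_order(table: HRSATable) -> tuple[bool, list[tuple[str, str]]]:
    """Check the table against the published tier order.

    Every residue in a higher tier must score strictly above every residue
    in any lower tier; within-tier ties are allowed.  Returns ``(ok,
    violations)`` where each violation is ``(higher_residue,
    lower_residue)`` for a pair whose rates do not respect the order.
    """
    violations: list[tuple[str, str]] = []
    for i, upper in enumerate(RANK_TIERS):
        for lower in RANK_TIERS[i + 1 :]:
            for hi in upper:
                for lo in lower:
                    if not table[hi] > table[lo]:
                        violations.append((hi, lo))
    return (not violations), violations


def score_hrsa(
    sequence: str, table: HRSATable | None = None, mode: str = "sum", protein: str = ""
) -> HRSAScore:
    """Sum (default) or mean of per-residue scavenging rates.

    Composition-only, hence permutation-invariant; ``sum`` is additive over
    concatenation and grows with protein length.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    table = table if table is not None else default_hrsa_table()
    seq = sequence.replace("X", "")
    if not seq:
        raise ValueError("cannot score an empty (or all-X) sequence")
    total = sum(table[ch] for ch in seq)
    score = total if mode == "sum" else total / len(seq)
    return HRSAScore(protein=protein, score=score, mode=mode)
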