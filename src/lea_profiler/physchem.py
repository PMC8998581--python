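"""Per-protein physicochemical quantities.

GRAVY (grand average of hydropathicity) is the arithmetic mean of per-residue
hydropathies; negative values denote hydrophilic proteins.  The default scale
is Kyte-Doolittle, which reproduces published consensus-motif GRAVY values to
the printed 3-decimal precision.  Molecular weight and isoelectric point
follow ProtParam conventions (average isotopic residue masses; Bjellqvist pK
set with bisection), delegated to Biopython behind this module's surface.

A hydrophilin is a glycine-rich, strongly hydrophilic protein (Gly > 6 % and
GRAVY below a threshold); both bounds are strict and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from lea_profiler.seq_io import STANDARD_RESIDUES, ProteomeSet

#: Kyte & Doolittle hydropathy values (dimensionless).
KYTE_DOOLITTLE_VALUES = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

WATER_MASS_DA = 18.0153


@dataclass(frozen=True)
class HydropathyScale:
    """Named residue -> hydropathy mapping over the 20 standard residues."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} absent from scale {self.name!r}") from None


KYTE_DOOLITTLE = HydropathyScale("Kyte-Doolittle", KYTE_DOOLITTLE_VALUES)


@dataclass(frozen=True)
class CategoryScheme:
    """Named residue sets for composition summaries.

    The sets may overlap (aromatic H/Y also appear in polar), so category
    percentages do not sum to 100.  Charged excludes His, matching the
    charged-residue counts used for consensus-motif bookkeeping.
    """

    charged: frozenset[str] = frozenset("DEKR")
    polar: frozenset[str] = frozenset("STNQCHY")
    nonpolar: frozenset[str] = frozenset("GAVLIPMFW")
    aromatic: frozenset[str] = frozenset("FWYH")

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "charged": self.charged,
            "polar": self.polar,
            "nonpolar": self.nonpolar,
            "aromatic": self.aromatic,
        }


DEFAULT_SCHEME = CategoryScheme()


@dataclass
class PhyschemProfile:
    """Physicochemical summary of one protein."""

    id: str
    length: int
    mw_kda: float
    pi: float
    gravy: float
    composition: dict[str, float]
    category_percents: dict[str, float]
    cys_percent: float
    gly_percent: float
    is_hydrophilin: bool = False


def _scored_residues(sequence: str) -> str:
    """Drop X (unknown) residues: they contribute zero to scored quantities."""
    return sequence.replace("X", "")


def gravy(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathicity: mean per-residue hydropathy."""
    seq = _scored_residues(sequence)
    if not seq:
        raise ValueError("cannot compute GRAVY of an empty (or all-X) sequence")
    return sum(scale[ch] for ch in seq) / len(seq)


def hydropathy_profile(
    sequence: str, window: int, scale: HydropathyScale = KYTE_DOOLITTLE
) -> list[tuple[int, float]]:
    """Sliding-window mean hydropathy.

    Returns ``(centre, mean)`` pairs, centre positions 1-based, one value per
    window; ``window`` must be odd and no longer than the sequence.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(sequence):
        raise ValueError("window longer than sequence")
    half = window // 2
    values = [scale[ch] if ch != "X" else 0.0 for ch in sequence]
    n_scored = [0 if ch == "X" else 1 for ch in sequence]
    out: list[tuple[int, float]] = []
    running = sum(values[:window])
    scored = sum(n_scored[:window])
    for start in range(len(sequence) - window + 1):
        if start > 0:
            running += values[start + window - 1] - values[start - 1]
            scored += n_scored[start + window - 1] - n_scored[start - 1]
        centre = start + half + 1
        out.append((centre, running / scored if scored else 0.0))
    return out


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in kDa (residue masses + one water)."""
    seq = _scored_residues(sequence)
    if not seq:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    return ProteinAnalysis(seq).molecular_weight() / 1000.0


def isoelectric_point(sequence: str) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    Bjellqvist pK set over the termini and D, E, C, Y, H, K, R side chains;
    bisection on [0, 14].  Composition-only, hence permutation-invariant.
    """
    seq = _scored_residues(sequence)
    if not seq:
        raise ValueError("cannot compute pI of an empty sequence")
    # full [0, 14] bracket: the library default ([4.05, 12]) clamps strongly
    # acidic or basic sequences
    return IsoelectricPoint(seq).pi(7.0, 0.0, 14.0)


def charge_at_ph(sequence: str, ph: float) -> float:
    """Net charge of the sequence at a given pH (Bjellqvist pK set)."""
    return IsoelectricPoint(_scored_residues(sequence)).charge_at_pH(ph)


def composition_and_categories(
    sequence: str, scheme: CategoryScheme = DEFAULT_SCHEME
) -> tuple[dict[str, float], dict[str, float], float]:
    """Residue fractions plus category percentages.

    Fractions are over the scored (non-X) length and sum to 1; each category
    percent is ``100 * members / length``.
    """
    seq = _scored_residues(sequence)
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    n = len(seq)
    composition = {res: seq.count(res) / n for res in sorted(STANDARD_RESIDUES)}
    percents = {
        name: 100.0 * sum(seq.count(res) for res in members) / n
        for name, members in scheme.as_dict().items()
    }
    cys_percent = 100.0 * seq.count("C") / n
    return composition, percents, cys_percent


def net_formal_charge(sequence: str, count_his: bool = False) -> int:
    """Formal charge (#K + #R) - (#D + #E); His excluded by default."""
    pos = sum(sequence.count(res) for res in "KR")
    neg = sum(sequence.count(res) for res in "DE")
    if count_his:
        pos += sequence.count("H")
    return pos - neg


def is_hydrophilin(
    profile: PhyschemProfile, gly_min: float = 6.0, gravy_max: float = -1.0
) -> bool:
    """Hydrophilin test: Gly percent strictly above ``gly_min`` AND GRAVY
    strictly below ``gravy_max``.

    The default GRAVY bound is -1.0.  The looser bound of +1.0 seen in parts
    of the literature admits nearly every LEA protein and is available as the
    ``printed`` preset (pass ``gravy_max=1.0``).
    """
    return profile.gly_percent > gly_min and profile.gravy < gravy_max


def compute_profile(
    record_id: str,
    sequence: str,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    gly_min: float = 6.0,
    gravy_max: float = -1.0,
) -> PhyschemProfile:
    """All Table-style quantities for one sequence."""
    composition, percents, cys_pct = composition_and_categories(sequence, scheme)
    profile = PhyschemProfile(
        id=record_id,
        length=len(_scored_residues(sequence)),
        mw_kda=molecular_weight(sequence),
        pi=isoelectric_point(sequence),
        gravy=gravy(sequence, scale),
        composition=composition,
        category_percents=percents,
        cys_percent=cys_pct,
        gly_percent=100.0 * composition["G"],
    )
    profile.is_hydrophilin = is_hydrophilin(profile, gly_min=gly_min, gravy_max=gravy_max)
    return profile


def profile_table(
    proteome: ProteomeSet,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    gly_min: float = 6.0,
    gravy_max: float = -1.0,
) -> pd.DataFrame:
    """One profile row per protein (TSV-ready)."""
    rows = []
    for rec in proteome:
        p = compute_profile(rec.id, rec.sequence, scale, scheme, gly_min, gravy_max)
        rows.append(
            {
                "id": p.id,
                "length_aa": p.length,
                "mw_kda": p.mw_kda,
                "pi": p.pi,
                "gravy": p.gravy,
                "pct_charged": p.category_percents["charged"],
                "pct_polar": p.category_percents["polar"],
                "pct_nonpolar": p.category_percents["nonpolar"],
                "pct_aromatic": p.category_percents["aromatic"],
                "pct_cys": p.cys_percent,
                "pct_gly": p.gly_percent,
                "hydrophilin": p.is_hydrophilin,
            }
        )
    columns = [
        "id", "length_aa", "mw_kda", "pi", "gravy", "pct_charged", "pct_polar",
        "pct_nonpolar", "pct_aromatic", "pct_cys", "pct_gly", "hydrophilin",
    ]
    return pd.DataFrame(rows, columns=columns)


#: residue groupings plotted against GRAVY in composition scatter panels
SCATTER_PANELS: dict[str, tuple[str, ...]] = {
    "gly": ("G",),
    "lys_glu": ("K", "E"),
    "ala": ("A",),
    "ile_leu_val": ("I", "L", "V"),
    "cys": ("C",),
    "trp": ("W",),
    "his": ("H",),
    "pro": ("P",),
}


def gly_gravy_table(
    proteome: ProteomeSet,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    gly_min: float = 6.0,
    gravy_max: float = -1.0,
) -> pd.DataFrame:
    """Per-protein residue-percentage vs GRAVY scatter data.

    One row per protein with a percentage column per panel (Gly, Lys+Glu,
    Ala, Ile+Leu+Val, Cys, Trp, His, Pro), the GRAVY index, and the
    hydrophilin flag.
    """
    rows = []
    for rec in proteome:
        composition, _, _ = composition_and_categories(rec.sequence)
        g = gravy(rec.sequence, scale)
        row: dict[str, object] = {"id": rec.id, "gravy": g}
        for panel, residues in SCATTER_PANELS.items():
            row[f"pct_{panel}"] = 100.0 * sum(composition[r] for r in residues)
        row["hydrophilin"] = row["pct_gly"] > gly_min and g < gravy_max
        rows.append(row)
    columns = ["id", "gravy"] + [f"pct_{p}" for p in SCATTER_PANELS] + ["hydrophilin"]
    return pd.DataFrame(rows, columns=columns)
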