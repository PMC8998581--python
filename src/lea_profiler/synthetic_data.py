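"""Seeded generator of LEA-like proteomes and DEG tables.

Every downstream statistic in this package is composition- or motif-based,
so the background model is deliberately the simplest one consistent with
that: residues drawn i.i.d. from a per-family target composition, with the
family's consensus motifs embedded verbatim at non-overlapping random
positions.  Lengths follow a truncated normal per family.  The default
family profiles encode the study conditions of the source proteome survey:
seven families with counts 24/127/18/96/11/25/17 (318 proteins in all),
family mean lengths and GRAVY targets from the published per-family table,
and motif architectures from the published subgroup definitions.

Each family's composition is solved deterministically at construction time:
a hand-set base composition expressing the family's described residue
preferences is mixed with a hydrophobic or hydrophilic adjuster until its
expected GRAVY equals the family target.  The solve is closed-form (GRAVY
is linear in the mixture weight), so profiles are identical across runs.

What this generator does NOT emulate: positional residue dependence,
paralogue structure, motif degeneracy (embedded motifs are exact consensus
copies), or noisy domain annotations (each record is annotated with its
true family's Pfam accession at e-value 1e-10).  Recovery tests on this
material therefore exercise the pipeline's bookkeeping, not its robustness
to annotation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lea_profiler.family_classify import DEFAULT_DOMAIN_MAP, DomainAnnotation
from lea_profiler.motif_engine import FAMILIES, MotifDefinition, assign_subgroup, default_registry
from lea_profiler.physchem import KYTE_DOOLITTLE_VALUES
from lea_profiler.seq_io import ProteinRecord, ProteomeSet

RESIDUES = tuple(sorted(KYTE_DOOLITTLE_VALUES))

#: family -> Pfam accession (inverse of the classification map)
FAMILY_TO_PFAM = {family: pfam for pfam, family in DEFAULT_DOMAIN_MAP.items()}

#: published per-family protein counts (total 318)
DEFAULT_FAMILY_COUNTS: dict[str, int] = {
    "LEA1": 24, "LEA2": 127, "LEA3": 18, "LEA4": 96, "LEA5": 11, "DEH": 25, "SMP": 17,
}


@dataclass(frozen=True)
class FamilyProfile:
    """Generative recipe for one LEA family."""

    family: str
    target_composition: dict[str, float]
    length_mean: float
    length_sd: float
    motifs_to_embed: tuple[tuple[str, int], ...] = ()
    pi_bias: str | None = None  # "acidic" | "basic" | "neutral" (descriptive)

    def __post_init__(self) -> None:
        total = sum(self.target_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.family}: composition sums to {total}, not 1")
        if self.length_mean <= 0:
            raise ValueError("length_mean must be positive")

    @property
    def expected_gravy(self) -> float:
        return sum(p * KYTE_DOOLITTLE_VALUES[r] for r, p in self.target_composition.items())


@dataclass(frozen=True)
class DEGSpec:
    """Mixture weights and magnitude parameters for synthetic DEG tables."""

    frac_up: float = 0.76
    frac_down: float = 0.24
    up_loc: float = 5.0
    up_scale: float = 2.0
    down_loc: float = 2.0
    down_scale: float = 1.0
    null_scale: float = 0.5
    n_genes: int | None = None  # default: one row per generated protein

    def __post_init__(self) -> None:
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1 + 1e-12:
            raise ValueError("frac_up + frac_down must not exceed 1")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic dataset."""

    per_family_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_COUNTS)
    )
    seed: int = 0
    deg_spec: DEGSpec = field(default_factory=DEGSpec)

    def __post_init__(self) -> None:
        bad = {f: n for f, n in self.per_family_counts.items() if n < 0}
        if bad:
            raise ValueError(f"negative family counts: {bad}")


def _normalise(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {r: weights.get(r, 0.0) / total for r in RESIDUES}


def _gravy_of(composition: dict[str, float]) -> float:
    return sum(p * KYTE_DOOLITTLE_VALUES[r] for r, p in composition.items())


#: adjuster mixtures used to steer a base composition towards a GRAVY target
_HYDROPHOBIC_ADJUSTER = _normalise({"I": 1.0, "L": 1.0, "V": 1.0, "A": 1.0})
_HYDROPHILIC_ADJUSTER = _normalise({"K": 1.2, "E": 1.0, "D": 0.6, "Q": 0.5, "N": 0.5})


def tune_composition_to_gravy(
    base: dict[str, float], target_gravy: float
) -> dict[str, float]:
    """Mix ``base`` with a hydrophobic/hydrophilic adjuster so the expected
    GRAVY equals ``target_gravy``.

    GRAVY is linear in the mixture weight t, so t has a closed form; t is
    clamped to [0, 0.95] to keep the base character recognisable.
    """
    base = _normalise(base)
    g_base = _gravy_of(base)
    adjuster = _HYDROPHOBIC_ADJUSTER if target_gravy > g_base else _HYDROPHILIC_ADJUSTER
    g_adj = _gravy_of(adjuster)
    if abs(g_adj - g_base) < 1e-12:
        return base
    t = (target_gravy - g_base) / (g_adj - g_base)
    t = min(max(t, 0.0), 0.95)
    return {r: (1 - t) * base[r] + t * adjuster[r] for r in RESIDUES}


# Hand-set base compositions expressing each family's described residue
# character (glycine-rich hydrophilic LEA1/LEA5, aliphatic cysteine-bearing
# LEA2, Pro/Trp-marked LEA3, Lys/Glu/Ala-rich LEA4, K/G/H/P/S-rich
# dehydrins, Ala/Val-rich acidic SMPs).  GRAVY targets are the published
# per-family means; the tuner above enforces them exactly in expectation.
_FAMILY_RECIPES: dict[str, dict] = {
    "LEA1": {
        "base": {"G": 0.10, "A": 0.10, "K": 0.10, "E": 0.09, "Q": 0.06, "S": 0.07,
                 "T": 0.06, "N": 0.05, "D": 0.04, "R": 0.03, "H": 0.03, "P": 0.04,
                 "V": 0.06, "L": 0.06, "I": 0.04, "M": 0.03, "F": 0.02, "Y": 0.015,
                 "W": 0.003, "C": 0.001},
        "gravy": -0.93, "length": (139.0, 24.5), "pi": "basic",
        "motifs": (("M1.1", 1), ("M1.2", 1)),
    },
    "LEA2": {
        "base": {"I": 0.09, "L": 0.10, "V": 0.09, "A": 0.07, "G": 0.07, "P": 0.05,
                 "F": 0.04, "Y": 0.035, "W": 0.012, "C": 0.017, "S": 0.07, "T": 0.06,
                 "N": 0.04, "Q": 0.03, "D": 0.05, "E": 0.05, "K": 0.07, "R": 0.05,
                 "H": 0.02, "M": 0.02},
        "gravy": -0.09, "length": (226.0, 56.4), "pi": "basic",
        "motifs": (("M2.1", 1), ("M2.2", 1), ("M2.6", 1)),
    },
    "LEA3": {
        "base": {"P": 0.09, "G": 0.08, "A": 0.08, "S": 0.07, "T": 0.06, "V": 0.06,
                 "L": 0.05, "I": 0.04, "F": 0.035, "W": 0.012, "Y": 0.03, "H": 0.035,
                 "Q": 0.05, "N": 0.04, "D": 0.05, "E": 0.06, "K": 0.07, "R": 0.06,
                 "M": 0.02, "C": 0.006},
        "gravy": -0.59, "length": (126.0, 21.2), "pi": "neutral",
        "motifs": (("M3.1", 1), ("M3.2", 1)),
    },
    "LEA4": {
        "base": {"K": 0.14, "E": 0.13, "D": 0.06, "A": 0.16, "G": 0.06, "S": 0.06,
                 "T": 0.06, "Q": 0.04, "N": 0.03, "R": 0.02, "H": 0.015, "P": 0.03,
                 "V": 0.05, "L": 0.04, "I": 0.03, "M": 0.03, "F": 0.015, "Y": 0.015,
                 "W": 0.005, "C": 0.003},
        "gravy": -1.01, "length": (187.0, 68.6), "pi": "acidic",
        "motifs": (("M4.1", 1), ("M4.2", 1)),
    },
    "LEA5": {
        "base": {"G": 0.13, "K": 0.10, "E": 0.09, "D": 0.05, "R": 0.05, "Q": 0.06,
                 "S": 0.07, "T": 0.06, "A": 0.08, "N": 0.04, "H": 0.03, "P": 0.04,
                 "V": 0.05, "L": 0.05, "I": 0.03, "M": 0.03, "F": 0.02, "Y": 0.02,
                 "W": 0.005, "C": 0.005},
        "gravy": -1.02, "length": (118.0, 23.2), "pi": "basic",
        "motifs": (("M5.1", 1), ("M5.2", 1)),
    },
    "DEH": {
        "base": {"G": 0.13, "K": 0.12, "E": 0.10, "D": 0.05, "H": 0.04, "P": 0.06,
                 "S": 0.09, "T": 0.07, "Q": 0.04, "N": 0.04, "A": 0.07, "R": 0.03,
                 "V": 0.04, "L": 0.04, "I": 0.03, "M": 0.02, "F": 0.02, "Y": 0.025,
                 "W": 0.003, "C": 0.01},
        "gravy": -1.40, "length": (143.0, 45.0), "pi": "neutral",
        "motifs": (("M6.1", 1), ("M6.2", 1), ("M6.3", 1)),
    },
    "SMP": {
        "base": {"A": 0.16, "V": 0.09, "G": 0.09, "L": 0.06, "I": 0.04, "P": 0.05,
                 "S": 0.07, "T": 0.06, "N": 0.05, "Q": 0.05, "D": 0.07, "E": 0.07,
                 "K": 0.04, "R": 0.03, "H": 0.02, "M": 0.025, "F": 0.02, "Y": 0.02,
                 "W": 0.005, "C": 0.009},
        "gravy": -0.27, "length": (157.0, 61.8), "pi": "acidic",
        "motifs": (("M7.1", 1),),
    },
}


def default_family_profiles() -> dict[str, FamilyProfile]:
    """Per-family profiles matching the published study conditions.

    The background composition is solved so that the WHOLE protein - i.i.d.
    background plus embedded consensus motifs - hits the family GRAVY target
    in expectation: with motif fraction w = footprint / mean length, the
    background is tuned to (target - w * motif_gravy) / (1 - w).
    """
    registry = default_registry()
    profiles: dict[str, FamilyProfile] = {}
    for family, recipe in _FAMILY_RECIPES.items():
        mean, sd = recipe["length"]
        target = recipe["gravy"]
        footprint = sum(
            registry[name].length * copies for name, copies in recipe["motifs"]
        )
        if footprint:
            motif_gravy = sum(
                _gravy_of(
                    {r: registry[name].consensus.count(r) / registry[name].length
                     for r in RESIDUES}
                ) * registry[name].length * copies
                for name, copies in recipe["motifs"]
            ) / footprint
            w = min(footprint / mean, 0.9)
            background_target = (target - w * motif_gravy) / (1.0 - w)
        else:
            background_target = target
        profiles[family] = FamilyProfile(
            family=family,
            target_composition=tune_composition_to_gravy(recipe["base"], background_target),
            length_mean=mean,
            length_sd=sd,
            motifs_to_embed=recipe["motifs"],
            pi_bias=recipe["pi"],
        )
    return profiles


_MAX_LENGTH_RETRIES = 100
_MAX_PLACEMENT_RETRIES = 1000


def _draw_length(profile: FamilyProfile, rng: np.random.Generator, min_length: int) -> int:
    """Truncated-normal length draw (lower bound only)."""
    for _ in range(_MAX_LENGTH_RETRIES):
        length = int(round(rng.normal(profile.length_mean, profile.length_sd)))
        if length >= min_length:
            return length
    raise RuntimeError(
        f"{profile.family}: could not draw a length >= {min_length} "
        f"from N({profile.length_mean}, {profile.length_sd})"
    )


def _place_motifs(
    length: int, widths: list[int], rng: np.random.Generator
) -> list[int] | None:
    """Non-overlapping random start positions, or None if placement failed."""
    for _ in range(_MAX_PLACEMENT_RETRIES):
        starts = sorted(
            (int(rng.integers(0, length - w + 1)), w) for w in widths
        )
        ok = all(
            starts[i][0] + starts[i][1] <= starts[i + 1][0] for i in range(len(starts) - 1)
        )
        if ok:
            # return starts in the original widths order
            remaining = list(starts)
            out: list[int] = []
            for w in widths:
                for j, (s, w2) in enumerate(remaining):
                    if w2 == w:
                        out.append(s)
                        remaining.pop(j)
                        break
            return out
    return None


def generate_protein(
    profile: FamilyProfile,
    rng: np.random.Generator,
    record_id: str = "synthetic",
    registry: dict[str, MotifDefinition] | None = None,
    min_length: int = 100,
) -> ProteinRecord:
    """One record: i.i.d. background plus embedded consensus motifs.

    The drawn length is re-drawn (capped retries) if shorter than the total
    motif footprint; embedded motif names and 0-based starts are recorded in
    the description.
    """
    registry = registry if registry is not None else default_registry()
    motifs: list[MotifDefinition] = []
    for name, copies in profile.motifs_to_embed:
        if name not in registry:
            raise KeyError(f"motif {name!r} not in registry")
        motifs.extend([registry[name]] * copies)
    footprint = sum(m.length for m in motifs)
    probs = np.array([profile.target_composition[r] for r in RESIDUES])

    starts: list[int] | None = None
    length = 0
    for _ in range(_MAX_LENGTH_RETRIES):
        length = _draw_length(profile, rng, min_length)
        if length < footprint:
            continue
        starts = _place_motifs(length, [m.length for m in motifs], rng)
        if starts is not None:
            break
    if starts is None and motifs:
        raise RuntimeError(f"{profile.family}: could not place motifs in drawn lengths")

    residues = list(rng.choice(RESIDUES, size=length, p=probs))
    placements: list[str] = []
    for motif, start in zip(motifs, starts or []):
        residues[start : start + motif.length] = list(motif.consensus)
        placements.append(f"{motif.name}@{start}")
    description = (
        f"family={profile.family} motifs={','.join(placements) or '-'}"
    )
    return ProteinRecord(
        id=record_id, sequence="".join(residues), description=description, source="synthetic"
    )


def generate_proteome(
    spec: GeneratorSpec,
    profiles: dict[str, FamilyProfile] | None = None,
    registry: dict[str, MotifDefinition] | None = None,
) -> tuple[ProteomeSet, list[DomainAnnotation], pd.DataFrame]:
    """Full synthetic dataset: records, clean domain annotations, truth table.

    Each record is annotated with its family's Pfam accession at e-value
    1e-10; the truth table holds the generative family and the subgroup its
    embedded motif set implies.
    """
    profiles = profiles if profiles is not None else default_family_profiles()
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    truth_rows: list[dict] = []
    for family in FAMILIES:
        count = spec.per_family_counts.get(family, 0)
        if count == 0:
            continue
        profile = profiles[family]
        embedded = {name for name, copies in profile.motifs_to_embed if copies > 0}
        subgroup = assign_subgroup(family, embedded)
        for k in range(count):
            record_id = f"SYN_{family}_{k + 1:04d}"
            rec = generate_protein(profile, rng, record_id=record_id, registry=registry)
            records.append(rec)
            annotations.append(DomainAnnotation(record_id, FAMILY_TO_PFAM[family], 1e-10))
            truth_rows.append(
                {
                    "id": record_id,
                    "family": family,
                    "subgroup": subgroup,
                    "length": len(rec),
                    "motifs": ",".join(sorted(embedded)),
                    "seed": spec.seed,
                }
            )
    proteome = ProteomeSet(records=records, provenance=f"synthetic (seed={spec.seed})")
    truth = pd.DataFrame(
        truth_rows, columns=["id", "family", "subgroup", "length", "motifs", "seed"]
    )
    return proteome, annotations, truth


def generate_deg_table(spec: GeneratorSpec, truth: pd.DataFrame) -> pd.DataFrame:
    """Synthetic DEG table over the generated genes.

    Directions are assigned by count rounding (``round(n * frac)``), so the
    requested up/down fractions are honoured exactly up to integer counts.
    Magnitudes: up ~ |N(up_loc, up_scale)| + 2, down ~ -(|N(down_loc,
    down_scale)| + 2), null ~ N(0, null_scale).  FDR is uniform on (0,
    0.01) for non-null genes and uniform on (0, 1) for null ones.
    """
    deg = spec.deg_spec
    rng = np.random.default_rng(spec.seed + 1)
    pool = truth if deg.n_genes is None else truth.iloc[: deg.n_genes]
    n = len(pool)
    n_up = int(round(deg.frac_up * n))
    n_down = int(round(deg.frac_down * n))
    if n_up + n_down > n:
        n_down = n - n_up
    n_null = n - n_up - n_down
    directions = np.array(["up"] * n_up + ["down"] * n_down + ["null"] * n_null)
    rng.shuffle(directions)
    rows: list[dict] = []
    for (row, direction) in zip(pool.itertuples(), directions):
        if direction == "up":
            log2fc = abs(rng.normal(deg.up_loc, deg.up_scale)) + 2.0
            fdr = rng.uniform(0.0, 0.01)
        elif direction == "down":
            log2fc = -(abs(rng.normal(deg.down_loc, deg.down_scale)) + 2.0)
            fdr = rng.uniform(0.0, 0.01)
        else:
            log2fc = rng.normal(0.0, deg.null_scale)
            fdr = rng.uniform(0.0, 1.0)
        rows.append(
            {
                "rs_id": f"Rs_syn_{row.Index + 1:05d}",
                "leap_id": row.id,
                "subgroup": row.subgroup,
                "log2fc": float(log2fc),
                "fdr": float(fdr),
            }
        )
    return pd.DataFrame(rows, columns=["rs_id", "leap_id", "subgroup", "log2fc", "fdr"])
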