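"""Family/subgroup assignment from domain annotations and motif profiles.

Classification mirrors the standard proteome-survey pipeline: keep full-ish
sequences (>= 100 aa), accept the best (lowest e-value) LEA Pfam domain per
protein under the HMM e-value threshold of 1e-5, map that accession to one
of the seven families (LEA1-LEA5, dehydrins, SMPs), then refine to a
subgroup from the conserved-motif architecture.  Proteins with no qualifying
domain are "unclassified" and excluded from family summaries.

The default accession map uses the canonical pairing PF00257 = dehydrin and
PF04927 = SMP.  Published family tables occasionally swap these two rows;
the map is overridable for datasets annotated the other way round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lea_profiler.motif_engine import (
    FAMILIES,
    MotifDefinition,
    assign_subgroup,
    motif_presence_profile,
)
from lea_profiler.seq_io import ProteomeSet, filter_by_length

UNCLASSIFIED = "unclassified"

#: Pfam accession -> LEA family (canonical dehydrin/SMP pairing)
DEFAULT_DOMAIN_MAP: dict[str, str] = {
    "PF03760": "LEA1",
    "PF03168": "LEA2",
    "PF03242": "LEA3",
    "PF02987": "LEA4",
    "PF00477": "LEA5",
    "PF00257": "DEH",
    "PF04927": "SMP",
}

#: tie-break order for equal e-values (family-table row order)
_FAMILY_ORDER = {family: rank for rank, family in enumerate(FAMILIES)}


@dataclass(frozen=True)
class DomainAnnotation:
    protein: str
    pfam_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class FamilyAssignment:
    protein: str
    family: str
    subgroup: str
    evidence: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.family != UNCLASSIFIED and not self.subgroup.startswith(self.family):
            raise ValueError(
                f"subgroup {self.subgroup!r} does not belong to family {self.family!r}"
            )


def map_domain_to_family(pfam_id: str, domain_map: dict[str, str] | None = None) -> str:
    """Map a Pfam accession to its LEA family; unknown -> ``unclassified``."""
    domain_map = domain_map if domain_map is not None else DEFAULT_DOMAIN_MAP
    return domain_map.get(pfam_id, UNCLASSIFIED)


def read_annotations(path) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV: protein_id, pfam_id, evalue."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "pfam_id": str})
    required = {"protein_id", "pfam_id", "evalue"}
    if not required <= set(frame.columns):
        raise ValueError(f"annotation table missing columns: {sorted(required - set(frame.columns))}")
    return [
        DomainAnnotation(row.protein_id, row.pfam_id, float(row.evalue))
        for row in frame.itertuples()
    ]


def classify_proteome(
    proteome: ProteomeSet,
    annotations: list[DomainAnnotation],
    registry: dict[str, MotifDefinition] | None = None,
    evalue_max: float = 1e-5,
    min_length: int = 100,
    min_identity: float = 0.8,
    domain_map: dict[str, str] | None = None,
) -> list[FamilyAssignment]:
    """Length filter -> best qualifying domain -> family -> motif subgroup."""
    known = set(proteome.ids)
    for ann in annotations:
        if ann.protein not in known:
            raise ValueError(f"annotation references unknown protein {ann.protein!r}")
    kept = filter_by_length(proteome, min_length=min_length)

    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein, []).append(ann)

    assignments: list[FamilyAssignment] = []
    for rec in kept:
        qualifying = [
            (ann, map_domain_to_family(ann.pfam_id, domain_map))
            for ann in by_protein.get(rec.id, [])
            if ann.evalue <= evalue_max
        ]
        qualifying = [(ann, fam) for ann, fam in qualifying if fam != UNCLASSIFIED]
        if not qualifying:
            assignments.append(FamilyAssignment(rec.id, UNCLASSIFIED, UNCLASSIFIED))
            continue
        # lowest e-value wins; ties broken by family-table row order
        best_ann, family = min(
            qualifying, key=lambda pair: (pair[0].evalue, _FAMILY_ORDER[pair[1]])
        )
        present = motif_presence_profile(rec, registry, min_identity=min_identity)
        subgroup = assign_subgroup(family, present)
        evidence = (
            ("domain", f"{best_ann.pfam_id} (e={best_ann.evalue:g})"),
            ("motifs", ",".join(sorted(present)) or "-"),
        )
        assignments.append(FamilyAssignment(rec.id, family, subgroup, evidence))
    return assignments


SUMMARY_QUANTITIES = (
    "length_aa", "pi", "mw_kda", "gravy",
    "pct_charged", "pct_polar", "pct_nonpolar", "pct_aromatic", "pct_cys",
)


def _tukey_letters(values: pd.Series, groups: pd.Series, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from Tukey's HSD (statsmodels).

    Groups that are not significantly different share a letter; groups with
    fewer than two members are excluded.  Greedy insertion in order of
    descending mean (the usual CLD heuristic).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = groups.value_counts()
    eligible = [g for g in counts.index if counts[g] >= 2]
    if len(eligible) < 2:
        return {g: "a" for g in eligible}
    mask = groups.isin(eligible)
    result = pairwise_tukeyhsd(values[mask].to_numpy(), groups[mask].to_numpy(), alpha=alpha)
    names = list(result.groupsunique)
    significant: set[frozenset] = set()
    for (i, j), p in zip(
        [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))],
        result.pvalues,
    ):
        # NaN p-values (zero pooled variance) count as not significant
        if not math.isnan(p) and p < alpha:
            significant.add(frozenset((names[i], names[j])))
    ordered = sorted(eligible, key=lambda g: -values[groups == g].mean())
    letter_sets: list[set] = []
    for g in ordered:
        placed = False
        for members in letter_sets:
            if all(frozenset((g, other)) not in significant for other in members):
                members.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in eligible}
    for letter, members in zip(alphabet, letter_sets):
        for g in members:
            out[g] += letter
    return {g: "".join(sorted(s)) for g, s in out.items()}


def family_summary(
    assignments: list[FamilyAssignment],
    profiles: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family count, mean +/- SE, and Tukey grouping letters.

    ``profiles`` is the physchem profile table (one row per protein).
    Families with a single member report SE as missing and take no part in
    the post hoc comparison.  Unclassified proteins are excluded.
    """
    labels = pd.DataFrame(
        [(a.protein, a.family, a.subgroup) for a in assignments],
        columns=["id", "family", "subgroup"],
    )
    merged = labels[labels.family != UNCLASSIFIED].merge(profiles, on="id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["family", "count"])
    rows = []
    letters = {
        q: _tukey_letters(merged[q], merged["family"], alpha=alpha) for q in SUMMARY_QUANTITIES
    }
    for family, sub in merged.groupby("family", sort=False):
        row: dict[str, object] = {"family": family, "count": len(sub)}
        for q in SUMMARY_QUANTITIES:
            row[f"{q}_mean"] = sub[q].mean()
            row[f"{q}_se"] = sub[q].sem() if len(sub) >= 2 else np.nan
            row[f"{q}_group"] = letters[q].get(family, "")
        rows.append(row)
    order = [f for f in FAMILIES if f in {r["family"] for r in rows}]
    frame = pd.DataFrame(rows).set_index("family").loc[order].reset_index()
    return frame
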