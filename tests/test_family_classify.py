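"""Domain-to-family mapping, classification pipeline, family summaries."""

import numpy as np
import pandas as pd
import pytest

from lea_profiler.family_classify import (
    DEFAULT_DOMAIN_MAP,
    DomainAnnotation,
    classify_proteome,
    family_summary,
    map_domain_to_family,
)
from lea_profiler.motif_engine import default_registry
from lea_profiler.physchem import profile_table
from lea_profiler.seq_io import ProteinRecord, ProteomeSet
from lea_profiler.synthetic_data import GeneratorSpec, generate_proteome


class TestDomainMap:
    @pytest.mark.parametrize(
        "pfam,family",
        [
            ("PF03760", "LEA1"),
            ("PF03168", "LEA2"),
            ("PF03242", "LEA3"),
            ("PF02987", "LEA4"),
            ("PF00477", "LEA5"),
            ("PF00257", "DEH"),
            ("PF04927", "SMP"),
        ],
    )
    def test_default_accessions(self, pfam, family):
        assert map_domain_to_family(pfam) == family

    def test_unknown_accession_unclassified(self):
        assert map_domain_to_family("PF99999") == "unclassified"

    def test_override_map(self):
        swapped = {"PF04927": "DEH"}
        assert map_domain_to_family("PF04927", swapped) == "DEH"


def _pad(seq: str, length: int = 120) -> str:
    return seq + "G" * max(0, length - len(seq))


class TestClassifyProteome:
    def test_domain_plus_motif_gives_family_and_subgroup(self, registry):
        seq = _pad("A" * 30 + registry["M4.2"].consensus + "A" * 30)
        proteome = ProteomeSet(records=[ProteinRecord(id="p1", sequence=seq)])
        annotations = [DomainAnnotation("p1", "PF02987", 1e-10)]
        (assignment,) = classify_proteome(proteome, annotations, registry)
        assert (assignment.family, assignment.subgroup) == ("LEA4", "LEA4.2")

    def test_short_protein_dropped_despite_annotation(self):
        proteome = ProteomeSet(records=[ProteinRecord(id="p1", sequence="A" * 80)])
        annotations = [DomainAnnotation("p1", "PF02987", 1e-10)]
        assert classify_proteome(proteome, annotations) == []

    def test_unknown_protein_in_annotations_rejected(self):
        proteome = ProteomeSet(records=[ProteinRecord(id="p1", sequence="A" * 120)])
        with pytest.raises(ValueError, match="ghost"):
            classify_proteome(proteome, [DomainAnnotation("ghost", "PF02987", 1e-10)])

    def test_no_qualifying_domain_is_unclassified(self):
        proteome = ProteomeSet(records=[ProteinRecord(id="p1", sequence="A" * 120)])
        weak = [DomainAnnotation("p1", "PF02987", 1e-3)]  # above the 1e-5 cutoff
        (assignment,) = classify_proteome(proteome, weak)
        assert assignment.family == "unclassified"

    def test_lowest_evalue_wins_multi_domain(self):
        proteome = ProteomeSet(records=[ProteinRecord(id="p1", sequence="A" * 120)])
        annotations = [
            DomainAnnotation("p1", "PF03168", 1e-8),
            DomainAnnotation("p1", "PF00257", 1e-12),
        ]
        (assignment,) = classify_proteome(proteome, annotations)
        assert assignment.family == "DEH"

    def test_stage_composition_oracle(self, registry):
        """Classification equals running filter, domain choice, motif scan
        and subgroup assignment separately."""
        from lea_profiler.motif_engine import assign_subgroup, motif_presence_profile
        from lea_profiler.seq_io import filter_by_length

        spec = GeneratorSpec(
            per_family_counts={"LEA1": 3, "DEH": 3, "SMP": 2}, seed=11
        )
        proteome, annotations, _ = generate_proteome(spec)
        assignments = classify_proteome(proteome, annotations, registry)
        kept = filter_by_length(proteome, 100)
        assert len(assignments) == len(kept)
        for assignment, rec in zip(assignments, kept):
            anns = [a for a in annotations if a.protein == rec.id and a.evalue <= 1e-5]
            family = map_domain_to_family(min(anns, key=lambda a: a.evalue).pfam_id)
            present = motif_presence_profile(rec, registry)
            assert assignment.family == family
            assert assignment.subgroup == assign_subgroup(family, present)

    def test_count_conservation_and_evalue_monotonicity(self):
        spec = GeneratorSpec(per_family_counts={"LEA1": 4, "LEA5": 3}, seed=5)
        proteome, annotations, _ = generate_proteome(spec)
        # degrade some annotations so thresholds matter
        annotations = [
            DomainAnnotation(a.protein, a.pfam_id, 1e-4 if i % 3 == 0 else a.evalue)
            for i, a in enumerate(annotations)
        ]
        loose = classify_proteome(proteome, annotations, evalue_max=1e-3)
        strict = classify_proteome(proteome, annotations, evalue_max=1e-6)

        def counts(assignments):
            out = {}
            for a in assignments:
                out[a.family] = out.get(a.family, 0) + 1
            return out

        for assignments in (loose, strict):
            assert sum(counts(assignments).values()) == len(proteome)
        loose_counts, strict_counts = counts(loose), counts(strict)
        for family in set(loose_counts) | set(strict_counts):
            if family == "unclassified":
                continue
            assert strict_counts.get(family, 0) <= loose_counts.get(family, 0)


class TestFamilySummary:
    def _assignments_and_profiles(self, seed=3):
        spec = GeneratorSpec(per_family_counts={"DEH": 10, "LEA2": 10}, seed=seed)
        proteome, annotations, _ = generate_proteome(spec)
        assignments = classify_proteome(proteome, annotations)
        profiles = profile_table(proteome)
        return assignments, profiles

    def test_means_match_brute_force_arithmetic(self):
        assignments, profiles = self._assignments_and_profiles()
        summary = family_summary(assignments, profiles).set_index("family")
        for family, row in summary.iterrows():
            members = [a.protein for a in assignments if a.family == family]
            sub = profiles[profiles.id.isin(members)]
            assert row["count"] == len(sub)
            assert row["gravy_mean"] == pytest.approx(sub.gravy.mean())
            assert row["gravy_se"] == pytest.approx(
                sub.gravy.std(ddof=1) / np.sqrt(len(sub))
            )

    def test_identical_families_share_grouping_letter(self):
        """Two families whose members are copies of the same sequences are
        statistically indistinguishable."""
        seqs = ["A" * 110 + "K" * 10, "G" * 100 + "E" * 20, "A" * 60 + "G" * 60]
        records, assignments = [], []
        from lea_profiler.family_classify import FamilyAssignment

        for family in ("LEA1", "LEA5"):
            for i, seq in enumerate(seqs):
                pid = f"{family}_{i}"
                records.append(ProteinRecord(id=pid, sequence=seq))
                assignments.append(FamilyAssignment(pid, family, f"{family}.0"))
        profiles = profile_table(ProteomeSet(records=records))
        summary = family_summary(assignments, profiles)
        row1 = summary[summary.family == "LEA1"].iloc[0]
        row5 = summary[summary.family == "LEA5"].iloc[0]
        assert row1.gravy_mean == pytest.approx(row5.gravy_mean)
        assert row1.gravy_group == row5.gravy_group != ""

    def test_singleton_family_reports_missing_se(self):
        from lea_profiler.family_classify import FamilyAssignment

        records = [
            ProteinRecord(id="a", sequence="A" * 120),
            ProteinRecord(id="b", sequence="G" * 120),
            ProteinRecord(id="c", sequence="K" * 120),
        ]
        assignments = [
            FamilyAssignment("a", "LEA1", "LEA1.0"),
            FamilyAssignment("b", "LEA1", "LEA1.0"),
            FamilyAssignment("c", "LEA5", "LEA5.0"),
        ]
        summary = family_summary(assignments, profile_table(ProteomeSet(records=records)))
        lea5 = summary[summary.family == "LEA5"].iloc[0]
        assert np.isnan(lea5.gravy_se)
        assert lea5.gravy_group == ""  # excluded from the post hoc

    def test_generator_targets_recovered_at_n50(self):
        """A 50-member dehydrin cohort recovers the generator's GRAVY
        target (-1.40) within +/-0.1."""
        spec = GeneratorSpec(per_family_counts={"DEH": 50}, seed=17)
        proteome, annotations, _ = generate_proteome(spec)
        assignments = classify_proteome(proteome, annotations)
        summary = family_summary(assignments, profile_table(proteome))
        deh = summary[summary.family == "DEH"].iloc[0]
        assert deh.gravy_mean == pytest.approx(-1.40, abs=0.1)
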