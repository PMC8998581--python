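"""Motif registry, degenerate-pattern scanning, dehydrin segments, subgroups."""

import itertools

import pytest

from lea_profiler.motif_engine import (
    FAMILIES,
    MotifDefinition,
    _optional_subsets,
    assign_subgroup,
    default_registry,
    detect_dehydrin_segments,
    load_registry,
    motif_presence_profile,
    parse_pattern,
    scan_motif,
)
from lea_profiler.seq_io import ProteinRecord


class TestRegistry:
    def test_default_has_all_28_motifs_across_families(self, registry):
        assert len(registry) == 28
        assert {m.family for m in registry.values()} == set(FAMILIES)

    def test_m1_2_fields(self, registry):
        motif = registry["M1.2"]
        assert motif.length == 21
        assert motif.consensus == "MQAAKETAANVAASANSGMEK"
        assert motif.printed_gravy == pytest.approx(-0.352)

    def test_yaml_override_extends_registry(self, tmp_path):
        config = tmp_path / "extra.yaml"
        config.write_text("- {name: MX, family: LEA1, consensus: A}\n")
        registry = load_registry(config)
        assert "MX" in registry and len(registry) == 29
        assert registry["MX"].length == 1

    def test_inconsistent_pattern_rejected(self, tmp_path):
        config = tmp_path / "bad.yaml"
        config.write_text("- {name: MX, family: LEA1, consensus: AAA, pattern: GG}\n")
        with pytest.raises(ValueError, match="MX"):
            load_registry(config)

    def test_k_segment_style_pattern_parses(self):
        pattern = parse_pattern("KKG[_N][MF]M[DE]KIKEK")
        assert len(pattern) == 12  # 11 mandatory positions + optional N
        allowed, optional = pattern[3]
        assert allowed == frozenset("N") and optional
        assert pattern[4] == (frozenset("MF"), False)
        assert sum(1 for _, opt in pattern if not opt) == 11


class TestScanMotif:
    @pytest.mark.parametrize("name", sorted(default_registry()))
    def test_consensus_self_hit(self, registry, name):
        motif = registry[name]
        hits = scan_motif(ProteinRecord(id="t", sequence=motif.consensus), motif)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].identity) == (0, motif.length, 1.0)

    def test_poly_ala_no_hits(self, registry):
        rec = ProteinRecord(id="t", sequence="A" * 120)
        assert scan_motif(rec, registry["M1.1"], min_identity=0.8) == []

    def test_matches_exhaustive_window_oracle(self, registry, rng):
        """Greedy non-overlapping selection over all qualifying windows,
        re-derived here by brute-force enumeration."""
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        motif = registry["M3.5"]  # short motif: hits occur by chance
        for trial in range(10):
            seq = "".join(rng.choice(residues, size=150))
            rec = ProteinRecord(id=f"t{trial}", sequence=seq)
            threshold = 0.6
            width = motif.length
            candidates = {}
            for start in range(len(seq) - width + 1):
                matched = sum(
                    1 for off, (allowed, _) in enumerate(motif.pattern)
                    if seq[start + off] in allowed
                )
                identity = matched / width
                if identity >= threshold:
                    candidates[start] = identity
            expected = []
            cursor = 0
            for start in sorted(candidates):
                if start >= cursor:
                    expected.append((start, start + width, candidates[start]))
                    cursor = start + width
            hits = scan_motif(rec, motif, min_identity=threshold)
            assert [(h.start, h.end, h.identity) for h in hits] == expected

    def test_optional_position_tried_both_ways(self):
        motif = MotifDefinition(
            name="Kseg", family="DEH", consensus="KKGMMDKIKEK",
            pattern=tuple(parse_pattern("KKG[_N][MF]M[DE]KIKEK")),
        )
        with_n = scan_motif(ProteinRecord(id="a", sequence="KKGNMMDKIKEK"), motif)
        without_n = scan_motif(ProteinRecord(id="b", sequence="KKGMMDKIKEK"), motif)
        assert with_n[0].identity == 1.0 and (with_n[0].end - with_n[0].start) == 12
        assert without_n[0].identity == 1.0 and (without_n[0].end - without_n[0].start) == 11


class TestDehydrinSegments:
    def test_k_segment_in_m6_1(self, registry):
        rec = ProteinRecord(id="t", sequence=registry["M6.1"].consensus)
        k_hits = [h for h in detect_dehydrin_segments(rec) if h.kind == "K"]
        assert len(k_hits) == 1
        assert k_hits[0].matched_text == "KKGMMDKIKEK"

    def test_y_segment_in_m6_3_at_position(self, registry):
        rec = ProteinRecord(id="t", sequence=registry["M6.3"].consensus)
        y_hits = [h for h in detect_dehydrin_segments(rec) if h.kind == "Y"]
        assert [(h.start, h.end) for h in y_hits] == [(15, 21)]
        assert y_hits[0].matched_text == "DEYGNP"

    def test_s_segment_in_m6_2_merged_maximal(self, registry):
        rec = ProteinRecord(id="t", sequence=registry["M6.2"].consensus)
        s_hits = [h for h in detect_dehydrin_segments(rec) if h.kind == "S"]
        assert len(s_hits) == 1
        assert "SGSSSSSSS" in s_hits[0].matched_text
        assert s_hits[0].matched_text == rec.sequence[s_hits[0].start : s_hits[0].end]

    def test_m6_4_lacks_kkg_prefix_so_no_k_hit(self, registry):
        """The strict grammar requires the KKG prefix; the literal behaviour
        (no hit) is asserted, not the biology."""
        rec = ProteinRecord(id="t", sequence=registry["M6.4"].consensus)
        assert [h for h in detect_dehydrin_segments(rec) if h.kind == "K"] == []

    def test_alternate_s_patterns_detected(self):
        rec = ProteinRecord(id="t", sequence="MAAATGSSSSSSAAA")
        s_hits = [h for h in detect_dehydrin_segments(rec) if h.kind == "S"]
        assert len(s_hits) == 1 and s_hits[0].matched_text == "TGSSSSSS"


class TestPresenceAndSubgroups:
    def test_embedded_motifs_detected(self, registry):
        seq = registry["M1.1"].consensus + "G" * 10 + registry["M1.2"].consensus
        present = motif_presence_profile(ProteinRecord(id="t", sequence=seq), registry)
        assert {"M1.1", "M1.2"} <= present

    def test_poly_gly_has_empty_profile(self, registry):
        assert motif_presence_profile(ProteinRecord(id="t", sequence="G" * 200), registry) == set()

    def test_profile_equals_mapping_scan_motif(self, registry, rng):
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(residues, size=200))
        rec = ProteinRecord(id="t", sequence=seq)
        expected = {
            name for name, motif in registry.items() if scan_motif(rec, motif, 0.8)
        }
        assert motif_presence_profile(rec, registry, 0.8) == expected

    @pytest.mark.parametrize(
        "family,present,expected",
        [
            ("LEA1", {"M1.1", "M1.2"}, "LEA1.1"),
            ("LEA1", {"M1.1"}, "LEA1.2"),
            ("LEA1", {"M1.2"}, "LEA1.3"),
            ("LEA2", set(), "LEA2.0"),
            ("LEA2", {"M2.1", "M2.2", "M2.6"}, "LEA2.2"),
            ("LEA2", {"M2.1", "M2.2", "M2.6", "M2.3", "M2.5"}, "LEA2.1"),
            ("LEA2", {"M2.4", "M2.7"}, "LEA2.3"),
            ("LEA2", {"M2.9"}, "LEA2.4"),
            ("LEA2", {"M2.8"}, "LEA2.5"),
            ("LEA3", {"M3.4"}, "LEA3.2"),
            ("LEA3", {"M3.1", "M3.2"}, "LEA3.1"),
            ("LEA4", {"M4.1", "M4.3"}, "LEA4.1"),
            ("LEA4", {"M4.1", "M4.2"}, "LEA4.2"),
            ("LEA4", {"M4.1"}, "LEA4.3"),
            ("DEH", {"M6.1", "M6.3"}, "DEH1"),
            ("DEH", {"M6.1"}, "DEH2"),
            ("SMP", {"M7.1"}, "SMP2"),
            ("SMP", {"M7.1", "M7.2"}, "SMP3"),
        ],
    )
    def test_subgroup_rules(self, family, present, expected):
        assert assign_subgroup(family, present) == expected

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroup("LEA9", set())

    def test_pure_function(self):
        present = {"M6.1", "M6.3"}
        assert assign_subgroup("DEH", present) == assign_subgroup("DEH", set(present))


def test_optional_subsets_enumerates_all_masks():
    pattern = tuple(parse_pattern("A[_B][_C]D"))
    masks = list(_optional_subsets(pattern))
    assert len(masks) == 4  # both optional positions toggled independently
    assert all(mask[0] and mask[3] for mask in masks)
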