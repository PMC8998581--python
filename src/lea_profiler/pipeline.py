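"""End-to-end orchestration: classify, profile, scan, score, summarise.

``run_pipeline`` composes the stage modules over one FASTA (plus a domain
annotation table and an optional DEG table) and writes a report bundle of
TSV/JSON files.  Every table carries a leading ``# config=<sha256>`` comment
so outputs are traceable to the exact threshold set that produced them; the
bundle is byte-identical across runs with identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from lea_profiler._version import __version__
from lea_profiler.deg_analysis import filter_degs, read_deg_table, summarize_degs, summary_as_dict
from lea_profiler.family_classify import (
    DomainAnnotation,
    classify_proteome,
    family_summary,
    read_annotations,
)
from lea_profiler.helix_wheel import is_a_type, scan_best_window, tmh_candidate_scan, wheel_and_faces
from lea_profiler.hrsa import default_hrsa_table, load_hrsa_table, score_hrsa, validate_rank_order
from lea_profiler.motif_engine import detect_dehydrin_segments, load_registry, scan_motif
from lea_profiler.physchem import gly_gravy_table, profile_table
from lea_profiler.seq_io import ProteomeSet, filter_by_length, read_fasta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and selections, serialised into the output bundle."""

    min_length: int = 100
    evalue_max: float = 1e-5
    min_identity: float = 0.8
    fdr_max: float = 0.05
    min_abs_log2fc: float = 2.0
    hydrophilin_gly_min: float = 6.0
    hydrophilin_gravy_max: float = -1.0
    helix_width: int = 11
    tmh_width: int = 19
    tmh_min_mean_kd: float = 1.6
    hrsa_mode: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 1 or not (0 < self.min_identity <= 1):
            raise ValueError("threshold outside documented bounds")
        if self.evalue_max <= 0 or self.fdr_max <= 0 or self.min_abs_log2fc <= 0:
            raise ValueError("threshold outside documented bounds")

    @property
    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: Path, digest: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# config={digest} tool=lea-profiler/{__version__}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    fasta: str | Path,
    domains: str | Path | list[DomainAnnotation],
    outdir: str | Path,
    deg_table: str | Path | pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    registry_path: str | Path | None = None,
    hrsa_table_path: str | Path | None = None,
) -> dict[str, Path]:
    """Run every stage and write the report bundle into ``outdir``.

    Returns a mapping of bundle entry name to written path.  Omitting the
    DEG table skips only ``deg_summary.json``.  Any stage error aborts with
    the stage name and offending record in the exception message.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest
    bundle: dict[str, Path] = {}
    log_lines: list[str] = [f"lea-profiler {__version__} config={digest}"]

    def stage(name: str, func, *args, **kwargs):
        try:
            result = func(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return result

    proteome: ProteomeSet = stage("read_fasta", read_fasta, fasta)
    log_lines.append(f"read_fasta: {len(proteome)} records")
    kept = stage("length_filter", filter_by_length, proteome, config.min_length)
    log_lines.append(
        f"length_filter: kept {len(kept)} (removed {len(proteome) - len(kept)})"
    )

    annotations = (
        domains if isinstance(domains, list) else stage("read_annotations", read_annotations, domains)
    )
    registry = stage("load_registry", load_registry, registry_path)

    assignments = stage(
        "classify",
        classify_proteome,
        kept,
        annotations,
        registry,
        config.evalue_max,
        config.min_length,
        config.min_identity,
    )
    families = pd.DataFrame(
        [
            {
                "protein_id": a.protein,
                "family": a.family,
                "subgroup": a.subgroup,
                "evidence": "; ".join(f"{k}:{v}" for k, v in a.evidence),
            }
            for a in assignments
        ]
    )
    _write_tsv(families, outdir / "families.tsv", digest)
    bundle["families"] = outdir / "families.tsv"
    log_lines.append(f"classify: {len(families)} assignments")

    profiles = stage(
        "physchem", profile_table, kept,
    )
    _write_tsv(profiles, outdir / "physchem.tsv", digest)
    bundle["physchem"] = outdir / "physchem.tsv"

    summary = stage("family_summary", family_summary, assignments, profiles)
    _write_tsv(summary, outdir / "family_summary.tsv", digest)
    bundle["family_summary"] = outdir / "family_summary.tsv"

    fig_data = stage("scatter_table", gly_gravy_table, kept)
    _write_tsv(fig_data, outdir / "fig1_data.tsv", digest)
    bundle["fig1_data"] = outdir / "fig1_data.tsv"

    motif_rows, segment_rows = [], []
    for rec in kept:
        for motif in registry.values():
            for hit in stage(
                f"motifs[{rec.id}]", scan_motif, rec, motif, config.min_identity
            ):
                motif_rows.append(
                    {
                        "protein_id": hit.protein, "motif": hit.motif,
                        "start_1based": hit.start + 1, "end_1based": hit.end,
                        "identity": hit.identity,
                    }
                )
        for seg in stage(f"segments[{rec.id}]", detect_dehydrin_segments, rec):
            segment_rows.append(
                {
                    "protein_id": seg.protein, "segment": seg.kind,
                    "start_1based": seg.start + 1, "end_1based": seg.end,
                    "matched_text": seg.matched_text,
                }
            )
    motif_cols = ["protein_id", "motif", "start_1based", "end_1based", "identity"]
    seg_cols = ["protein_id", "segment", "start_1based", "end_1based", "matched_text"]
    _write_tsv(pd.DataFrame(motif_rows, columns=motif_cols), outdir / "motifs.tsv", digest)
    _write_tsv(pd.DataFrame(segment_rows, columns=seg_cols), outdir / "segments.tsv", digest)
    bundle["motifs"] = outdir / "motifs.tsv"
    bundle["segments"] = outdir / "segments.tsv"
    log_lines.append(f"motifs: {len(motif_rows)} hits; segments: {len(segment_rows)} hits")

    helix_rows = []
    for rec in kept:
        if len(rec) < config.helix_width:
            continue
        window = stage(f"helix[{rec.id}]", scan_best_window, rec.sequence, config.helix_width)
        _, faces = wheel_and_faces(window.residues, delta=window.delta)
        tmh = tmh_candidate_scan(
            rec.sequence, config.tmh_width, config.tmh_min_mean_kd
        ) if len(rec) >= config.tmh_width else []
        helix_rows.append(
            {
                "protein_id": rec.id,
                "start_1based": window.start + 1,
                "end_1based": window.start + config.helix_width,
                "mu_h": window.mu_h,
                "mean_h": window.mean_h,
                "z": window.z,
                "a_type": is_a_type(faces),
                "n_tmh_candidates": len(tmh),
            }
        )
    helix_cols = [
        "protein_id", "start_1based", "end_1based", "mu_h", "mean_h", "z",
        "a_type", "n_tmh_candidates",
    ]
    _write_tsv(pd.DataFrame(helix_rows, columns=helix_cols), outdir / "helix.tsv", digest)
    bundle["helix"] = outdir / "helix.tsv"

    hrsa_table = (
        load_hrsa_table(hrsa_table_path) if hrsa_table_path else default_hrsa_table()
    )
    ok, violations = validate_rank_order(hrsa_table)
    if not ok:
        raise RuntimeError(f"stage 'hrsa' failed: rate table violates rank order: {violations[:5]}")
    hrsa_rows = [
        {
            "protein_id": rec.id,
            "length_aa": len(rec),
            "hrsa": score_hrsa(rec.sequence, hrsa_table, config.hrsa_mode, rec.id).score,
            "mode": config.hrsa_mode,
            "table_name": hrsa_table.name,
        }
        for rec in kept
    ]
    hrsa_cols = ["protein_id", "length_aa", "hrsa", "mode", "table_name"]
    _write_tsv(pd.DataFrame(hrsa_rows, columns=hrsa_cols), outdir / "hrsa.tsv", digest)
    bundle["hrsa"] = outdir / "hrsa.tsv"

    if deg_table is not None:
        table = (
            deg_table if isinstance(deg_table, pd.DataFrame)
            else stage("read_deg", read_deg_table, deg_table)
        )
        significant = stage("filter_degs", filter_degs, table, config.fdr_max, config.min_abs_log2fc)
        deg_summary = stage("summarize_degs", summarize_degs, significant)
        payload = {
            "config": digest,
            "thresholds": {"fdr_max": config.fdr_max, "min_abs_log2fc": config.min_abs_log2fc},
            "summary": summary_as_dict(deg_summary),
        }
        deg_path = outdir / "deg_summary.json"
        deg_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        bundle["deg_summary"] = deg_path
        log_lines.append(
            f"deg: {deg_summary.total} significant ({deg_summary.pct_up}% up)"
        )

    log_path = outdir / "run_log.txt"
    log_path.write_text(
        "\n".join(log_lines + [f"config_json={json.dumps(asdict(config), sort_keys=True)}"]) + "\n"
    )
    bundle["run_log"] = log_path
    return bundle
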