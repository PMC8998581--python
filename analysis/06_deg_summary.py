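#!/usr/bin/env python
"""Summarise differential expression: the packaged 88-gene desiccation DEG
table (direction split, per-subgroup tallies, strict-threshold filtering)
and, if present, the simulated DEG table for comparison.

Writes results/tables/deg_summary.json.
"""

import argparse
import json
from pathlib import Path

from lea_profiler.deg_analysis import (
    filter_degs,
    read_deg_table,
    summarize_degs,
    summary_as_dict,
    table4_fixture,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    published = table4_fixture()
    summary = summarize_degs(published)
    kept = filter_degs(published)
    print(f"published table: {summary.total} genes, {summary.pct_up} % up / "
          f"{summary.pct_down} % down; strict filter retains {len(kept)} "
          f"(drops the printed 1.99 and -2.00 rows)")
    print(f"DEH1 up: {summary.per_group['DEH1'][0]}, DEH2 up: {summary.per_group['DEH2'][0]}")

    payload = {"published": summary_as_dict(summary)}
    synthetic_path = args.indir / "deg.tsv"
    if synthetic_path.exists():
        synthetic = summarize_degs(filter_degs(read_deg_table(synthetic_path)))
        payload["synthetic"] = summary_as_dict(synthetic)
        print(f"synthetic table: {synthetic.total} significant genes, "
              f"{synthetic.pct_up} % up / {synthetic.pct_down} % down")

    out = args.outdir / "deg_summary.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
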