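"""Differential-expression filtering and direction summaries for LEA genes.

Input tables carry one row per gene with ``log2fc`` = log2(DL/HL), the
desiccated-vs-hydrated leaf contrast, and an ``fdr`` column of
Benjamini-Hochberg adjusted p-values.  The packaged reference table is the
published 88-row set of differentially expressed LEA genes; the print omits
the FDR column (every row already passed the screen), so it carries a
``fdr_passed`` sentinel instead of numbers.

Filtering is strict on both bounds: fdr < fdr_max AND |log2fc| > min_abs_log2fc.
One published row (RsLEA49, log2fc 1.99) sits below the stated fold-change
threshold; the table preserves the printed value and the filter drops it -
the discrepancy is reproduced, not corrected.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subgroup", "log2fc")


@dataclass(frozen=True)
class DEGSummary:
    """Direction summary of a DEG table."""

    total: int
    up: int
    down: int
    pct_up: int
    pct_down: int
    per_group: dict[str, tuple[int, int]] = field(default_factory=dict)


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")


def table4_fixture() -> pd.DataFrame:
    """The packaged 88-row desiccation DEG table (verbatim transcription)."""
    with resources.files("lea_profiler.data").joinpath(
        "deg_table_desiccation.tsv"
    ).open() as handle:
        table = pd.read_csv(handle, sep="\t")
    table["fdr_passed"] = True
    return table


def read_deg_table(path) -> pd.DataFrame:
    """Read a DEG TSV with columns rs_id, leap_id, subgroup, log2fc[, fdr]."""
    table = pd.read_csv(path, sep="\t")
    _check_schema(table)
    return table


def filter_degs(
    table: pd.DataFrame, fdr_max: float = 0.05, min_abs_log2fc: float = 2.0
) -> pd.DataFrame:
    """Strict significance filter: fdr < fdr_max and |log2fc| > min_abs_log2fc.

    Rows with a ``fdr_passed`` sentinel (pre-screened tables) satisfy the
    FDR clause; otherwise a numeric ``fdr`` column is required.
    """
    if fdr_max <= 0 or min_abs_log2fc <= 0:
        raise ValueError("thresholds must be positive")
    _check_schema(table)
    fc_ok = table["log2fc"].abs() > min_abs_log2fc
    if "fdr" in table.columns:
        fdr_ok = table["fdr"] < fdr_max
    elif "fdr_passed" in table.columns:
        fdr_ok = table["fdr_passed"].astype(bool)
    else:
        raise ValueError("DEG table needs an 'fdr' (or sentinel 'fdr_passed') column")
    return table[fc_ok & fdr_ok].reset_index(drop=True)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_degs(table: pd.DataFrame) -> DEGSummary:
    """Up/down tallies overall and per subgroup.

    ``up`` counts log2fc > 0, ``down`` log2fc < 0; genes with log2fc exactly
    zero join neither side (a warning is emitted).  Report percentages use
    round-half-up to integers; full precision is available from the counts.
    """
    _check_schema(table)
    if len(table) == 0:
        return DEGSummary(total=0, up=0, down=0, pct_up=0, pct_down=0, per_group={})
    zeros = int((table["log2fc"] == 0).sum())
    if zeros:
        warnings.warn(f"{zeros} gene(s) with log2fc == 0 counted neither up nor down")
    up = int((table["log2fc"] > 0).sum())
    down = int((table["log2fc"] < 0).sum())
    total = up + down
    per_group: dict[str, tuple[int, int]] = {}
    for subgroup, sub in table.groupby("subgroup", sort=True):
        per_group[str(subgroup)] = (
            int((sub["log2fc"] > 0).sum()),
            int((sub["log2fc"] < 0).sum()),
        )
    pct_up = _round_half_up(100.0 * up / total) if total else 0
    pct_down = _round_half_up(100.0 * down / total) if total else 0
    return DEGSummary(total=total, up=up, down=down, pct_up=pct_up, pct_down=pct_down,
                      per_group=per_group)


def summary_as_dict(summary: DEGSummary) -> dict:
    """JSON-ready form of a :class:`DEGSummary`."""
    return {
        "total": summary.total,
        "up": summary.up,
        "down": summary.down,
        "pct_up": summary.pct_up,
        "pct_down": summary.pct_down,
        "per_group": {g: {"up": u, "down": d} for g, (u, d) in summary.per_group.items()},
    }
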