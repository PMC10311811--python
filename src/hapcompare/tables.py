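"""Rendering of comparison results as text tables.

Two flavours: *machine* TSV (plain numbers, no thousands separators) and
*human* tables (counts with thousands separators, percentages to exactly
two decimals, half-up — e.g. ``459/32,150 (1.43%)``).  Excluded cells
render as ``-``; undefined ratios render as ``NA``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .compare import BlockComparison, PairwiseSummary, SwitchMetrics
from .model import BlockSnvSummary


def render_pct(count: int, denominator: int) -> str:
    """Exact percentage of two integers to 2 decimals, rounding half up."""
    pct = Decimal(count * 100) / Decimal(denominator)
    return str(pct.quantize(Decimal("0.01"), ROUND_HALF_UP))


def render_ratio(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return str(
        Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def _human_int(n: int) -> str:
    return f"{n:,}"


def count_pct_cell(
    count: int, denominator: int, human: bool = True
) -> str:
    """A disagreement-matrix cell: ``count/denominator (pct%)``."""
    pct = render_pct(count, denominator)
    if human:
        return f"{_human_int(count)}/{_human_int(denominator)} ({pct}%)"
    return f"{count}/{denominator} ({pct}%)"


def overlap_cell(count: int, denominator: int, human: bool = True) -> str:
    """A gold-standard overlap cell: ``count (pct%)``."""
    pct = render_pct(count, denominator)
    if human:
        return f"{_human_int(count)} ({pct}%)"
    return f"{count} ({pct}%)"


def summary_table(summaries: Sequence[BlockSnvSummary]) -> pd.DataFrame:
    """Block-and-SNV summary table, one row per tool."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "tool": s.tool_name,
                "SNV": s.total_snvs,
                "Block": s.total_blocks,
                "Min": s.min,
                "Q1": s.q1,
                "Median": s.median,
                "Mean": render_ratio(s.mean),
                "Q3": s.q3,
                "Max": s.max,
            }
        )
    return pd.DataFrame(rows)


def disagreement_matrix(
    summaries: Mapping[tuple[str, str], PairwiseSummary],
    names: Sequence[str],
    panel: str = "block",
    human: bool = True,
) -> pd.DataFrame:
    """The block- or SNV-disagreement matrix (rows = HA1, columns = HA2).

    The diagonal is 0 (self-agreement); pairs absent from ``summaries``
    (exclusions) render as ``-``.
    """
    if panel not in ("block", "snv"):
        raise ValueError(f"panel must be 'block' or 'snv', got {panel!r}")
    table: dict[str, dict[str, str]] = {}
    for ha1 in names:
        row: dict[str, str] = {}
        for ha2 in names:
            if ha1 == ha2:
                row[ha2] = "0"
                continue
            summary = summaries.get((ha1, ha2))
            if summary is None:
                row[ha2] = "-"
                continue
            if panel == "block":
                row[ha2] = count_pct_cell(
                    summary.disagree_blocks,
                    summary.ha1_total_blocks,
                    human,
                )
            else:
                row[ha2] = count_pct_cell(
                    summary.disagree_snvs, summary.ha1_total_snvs, human
                )
        table[ha1] = row
    return pd.DataFrame.from_dict(table, orient="index")[list(names)]


def metrics_table(
    summaries: Mapping[tuple[str, str], PairwiseSummary]
) -> pd.DataFrame:
    """Twelve switch metrics, one row per ordered (HA1, HA2) pair."""
    rows = []
    for (ha1, ha2), summary in summaries.items():
        row: dict[str, object] = {"HA1": ha1, "HA2": ha2}
        for name in SwitchMetrics.FIELD_ORDER:
            value = getattr(summary.metrics, name)
            row[name.replace("_w_", ".w.").replace("_", ".")] = (
                "NA" if value is None else value
            )
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(
    comparisons: Sequence[BlockComparison],
) -> pd.DataFrame:
    """Per-block comparison table (block id, SNV counts, match flags,
    switch count)."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "block.ID": c.block_id,
                "HA1.SNV.num": c.ha1_snv_num,
                "HA2.SNV.num": c.ha2_snv_num,
                "SNV.match": "match" if c.snv_match else "-",
                "hap.match": (
                    "-"
                    if c.hap_match is None
                    else ("match" if c.hap_match else "-")
                ),
                "switch.count": (
                    "NA" if c.switch_count is None else c.switch_count
                ),
            }
        )
    return pd.DataFrame(rows)
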