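"""Tier-profile report rendering.

The report mirrors the standard registry presentation: one column per site,
one row per tier, cells as ``n (%)`` with integer percentages rounded
half-away-from-zero.  Percentages always recompute from the printed counts,
so the report is self-consistent.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

TIER_LABELS = {
    "1": "Tier 1  Complete AJCC TNM",
    "2": "Tier 2  RD-Stage",
    "3": "Tier 3  Pathology Stage",
    "unstageable": "Unstageable",
}


def percent(count: int, total: int) -> int:
    """Integer percentage, round-half-away-from-zero (599/999 -> 60)."""
    if total == 0:
        return 0
    return int((Decimal(count) * 100 / Decimal(total))
               .quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def format_cell(count: int, total: int) -> str:
    return f"{count} ({percent(count, total)})"


def render_tier_report(counts: pd.DataFrame) -> str:
    """Render a tier-count table (index: tiers, columns: sites) as text.

    Each column header shows the site and its cohort size; cells are
    ``n (%)`` of the column total.
    """
    totals = counts.sum(axis=0)
    headers = ["Tier"] + [f"{site} (n = {int(totals[site])})"
                          for site in counts.columns]
    body = []
    for tier in counts.index:
        row = [TIER_LABELS.get(tier, tier)]
        for site in counts.columns:
            row.append(format_cell(int(counts.loc[tier, site]),
                                   int(totals[site])))
        body.append(row)
    widths = [max(len(str(r[i])) for r in [headers] + body)
              for i in range(len(headers))]
    lines = []
    for r in [headers, ["-" * w for w in widths]] + body:
        lines.append("  ".join(str(cell).ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"


def report_records(counts: pd.DataFrame) -> list[dict]:
    """Machine-readable form of the rendered report."""
    totals = counts.sum(axis=0)
    out = []
    for tier in counts.index:
        for site in counts.columns:
            n = int(counts.loc[tier, site])
            out.append({
                "tier": tier, "site": site, "count": n,
                "total": int(totals[site]),
                "percent": percent(n, int(totals[site])),
            })
    return out
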