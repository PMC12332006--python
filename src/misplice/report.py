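"""Summary tables: event-category percentages, minor-vs-major enrichment,
and cross-tabulation against an external differential-expression table.

Percentages are computed against the *detected* denominators and rounded
half-up; the number of decimals is a presentation parameter (sources round
inconsistently, e.g. "10%" next to "0.08%").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, decimals: int = 1) -> float:
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * count / total, decimals)


@dataclass
class SummaryTable:
    rows: pd.DataFrame

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SummaryTable":
        return cls(pd.read_csv(path, sep="\t"))


def summarize_categories(
    category_counts: Mapping[str, int], detected_total: int, decimals: int = 1
) -> SummaryTable:
    """Event-category counts as percentages of the detected total.

    ``category_counts`` holds the affected categories (typically ``IR``,
    ``AS``, ``IR_and_AS``); ``affected`` is their sum and ``unaffected`` the
    remainder of the detected total.
    """
    if detected_total <= 0:
        raise ValueError("detected_total must be positive")
    affected = sum(category_counts.values())
    if affected > detected_total:
        raise ValueError("affected categories exceed the detected total")
    rows = []
    for name in sorted(category_counts):
        count = category_counts[name]
        rows.append({"category": name, "count": count, "pct": pct(count, detected_total, decimals)})
    rows.append({"category": "affected", "count": affected, "pct": pct(affected, detected_total, decimals)})
    rows.append(
        {
            "category": "unaffected",
            "count": detected_total - affected,
            "pct": pct(detected_total - affected, detected_total, decimals),
        }
    )
    rows.append({"category": "detected", "count": detected_total, "pct": 100.0})
    return SummaryTable(pd.DataFrame(rows))


def enrichment_ratio(
    minor_retained: int,
    minor_detected: int,
    major_retained: int,
    major_detected: int,
    decimals_minor: int = 1,
    decimals_major: int = 1,
) -> tuple[float, float, float]:
    """(pct_minor, pct_major, ratio) for class-wise retention enrichment.

    Percentages are over each class's detected count, at independently
    chosen precision; the ratio divides the rounded percentages (matching
    how such enrichments are quoted) and is +inf when no major intron is
    retained.
    """
    if minor_detected <= 0 or major_detected <= 0:
        raise ValueError("detected counts must be positive")
    pct_minor = pct(minor_retained, minor_detected, decimals_minor)
    pct_major = pct(major_retained, major_detected, decimals_major)
    ratio = pct_minor / pct_major if pct_major > 0 else math.inf
    return (pct_minor, pct_major, ratio)


def summarize_de_migs(
    de_table: pd.DataFrame,
    mig_list: Iterable[str],
    alpha: float = 0.05,
    decimals_down: int = 1,
    decimals_up: int = 1,
) -> dict[str, float]:
    """Cross-tabulate an external DE table against a MIG list.

    ``de_table`` needs columns gene, log2FC, FDR with unique gene ids.
    Significance is FDR <= alpha with the direction given by the sign of
    log2FC (no fold-change cutoff).  Percentages are over detected MIGs;
    ``fold_propensity`` is pct_down / pct_up on the rounded percentages.
    """
    if de_table["gene"].duplicated().any():
        raise ValueError("DE table gene ids must be unique")
    migs = set(mig_list)
    detected = de_table[de_table["gene"].isin(migs)]
    n_detected = len(detected)
    if n_detected == 0:
        import logging

        logging.getLogger(__name__).warning("no MIGs found in the DE table")
        return {
            "n_detected": 0,
            "n_down": 0,
            "n_up": 0,
            "pct_down": 0.0,
            "pct_up": 0.0,
            "fold_propensity": float("nan"),
        }
    sig = detected[detected["FDR"] <= alpha]
    n_down = int((sig["log2FC"] < 0).sum())
    n_up = int((sig["log2FC"] > 0).sum())
    pct_down = pct(n_down, n_detected, decimals_down)
    pct_up = pct(n_up, n_detected, decimals_up)
    propensity = pct_down / pct_up if pct_up > 0 else math.inf
    return {
        "n_detected": n_detected,
        "n_down": n_down,
        "n_up": n_up,
        "pct_down": pct_down,
        "pct_up": pct_up,
        "fold_propensity": propensity,
    }


def write_text_report(
    summary: SummaryTable,
    enrichment: tuple[float, float, float] | None,
    de_summary: dict[str, float] | None,
    path: str | Path,
) -> Path:
    path = Path(path)
    lines = ["Mis-splicing summary", "====================", ""]
    for row in summary.rows.itertuples():
        lines.append(f"{row.category:>12}: {row.count:6d}  ({row.pct}%)")
    if enrichment is not None:
        pm, pj, ratio = enrichment
        lines += ["", f"minor retained: {pm}%   major retained: {pj}%   enrichment: {ratio:.1f}x"]
    if de_summary is not None:
        lines += [
            "",
            (
                f"MIGs in DE table: {de_summary['n_detected']}  "
                f"down {de_summary['n_down']} ({de_summary['pct_down']}%)  "
                f"up {de_summary['n_up']} ({de_summary['pct_up']}%)  "
                f"propensity {de_summary['fold_propensity']:.1f}x"
            ),
        ]
    path.write_text("\n".join(lines) + "\n")
    return path
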