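"""Cohort-level frequency arithmetic and the combined text report.

All printed percentages are rounded half-up at the requested precision so
that tabulated values match hand arithmetic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .orf_calls import CallSummary


def _round_half_up(value: Decimal, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def isolation_frequency(positives: int, samples: int, decimals: int = 1) -> float:
    """Percent of positive samples, rounded half-up (default one decimal)."""
    if samples < 1:
        raise ValueError("samples must be >= 1")
    if not (0 <= positives <= samples):
        raise ValueError("positives must lie in [0, samples]")
    return _round_half_up(Decimal(100 * positives) / Decimal(samples), decimals)


def marker_presence_fraction(
    marker_table: Union[pd.DataFrame, np.ndarray, Sequence[Sequence[bool]]],
    decimals: int = 0,
) -> float:
    """Percent of strains (rows) carrying at least one marker (any True)."""
    arr = np.asarray(
        marker_table.to_numpy() if isinstance(marker_table, pd.DataFrame) else marker_table,
        dtype=bool,
    )
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 1:
        raise ValueError("marker table needs at least one strain")
    positives = int(arr.any(axis=1).sum())
    return _round_half_up(Decimal(100 * positives) / Decimal(arr.shape[0]), decimals)


@dataclass
class CohortSummary:
    source_frequencies: pd.DataFrame  # source, samples, positives, frequency_pct
    call_summary: Optional[CallSummary] = None
    marker_presence_pct: Optional[float] = None
    thresholds: Dict[str, float] = field(default_factory=dict)


def summarize_sources(sources: Iterable[Tuple[str, int, int]], decimals: int = 1) -> pd.DataFrame:
    """``sources`` yields (name, positives, samples) triples."""
    rows = [
        {
            "source": name,
            "samples": samples,
            "positives": positives,
            "frequency_pct": isolation_frequency(positives, samples, decimals),
        }
        for name, positives, samples in sources
    ]
    return pd.DataFrame(rows, columns=["source", "samples", "positives", "frequency_pct"])


def cohort_report(summary: CohortSummary) -> str:
    """Render a small markdown report of the cohort-level numbers."""
    lines: List[str] = ["# Cohort summary", "", "## Isolation frequencies", ""]
    lines.append(summary.source_frequencies.to_markdown(index=False))
    if summary.call_summary is not None:
        cs = summary.call_summary
        lines += [
            "",
            "## Foreign-ORF calls",
            "",
            f"- union of foreign/heterozygous groups: {len(cs.union)}",
            f"- shared across all strains: {len(cs.shared_core)}",
            f"- heterozygous in >= 1 strain: {len(cs.heterozygous_union)}"
            + (f" ({cs.heterozygous_percent}% of union)" if cs.heterozygous_percent is not None else ""),
            "",
            "Per-strain foreign/heterozygous counts:",
            "",
            cs.to_frame().to_markdown(index=False),
        ]
    if summary.marker_presence_pct is not None:
        lines += ["", f"Marker-region presence: {summary.marker_presence_pct}% of strains"]
    if summary.thresholds:
        lines += ["", "Thresholds: " + ", ".join(f"{k}={v}" for k, v in sorted(summary.thresholds.items()))]
    return "\n".join(lines) + "\n"
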