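"""Read-depth copy-number estimation for tandem gene arrays.

The per-gene statistic is mean depth over the gene interval divided by the
genome median depth; dividing by the same ratio for a single-copy control
gene cancels strain-level depth artifacts. Flanking-gene ratios near 1
distinguish a tandem amplification from a whole-region duplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DepthProfile, HybscanError, IntervalError

Interval = Tuple[str, int, int]  # chrom, start, end (0-based half-open)

CONTROL_TOLERANCE = 0.25  # control ratio must stay within 1 +/- this


class DepthError(HybscanError):
    pass


@dataclass
class CopyNumberEstimate:
    strain: str
    gene: str
    raw_ratio: float
    control_ratio: float
    copy_number: float  # raw_ratio / control_ratio
    pass_control: bool
    flank_up: Optional[float] = None
    flank_down: Optional[float] = None

    def to_row(self) -> dict:
        return {
            "strain": self.strain,
            "gene": self.gene,
            "raw_ratio": self.raw_ratio,
            "control_ratio": self.control_ratio,
            "cn": self.copy_number,
            "pass_control": self.pass_control,
            "flank_up": self.flank_up,
            "flank_down": self.flank_down,
        }


def _mean_depth(profile: DepthProfile, interval: Interval) -> float:
    chrom, start, end = interval
    if chrom not in profile.depths:
        raise IntervalError(f"unknown chromosome {chrom}")
    if end <= start:
        raise IntervalError(f"empty interval {chrom}:{start}-{end}")
    arr = profile.depths[chrom]
    if not (0 <= start < end <= len(arr)):
        raise IntervalError(f"interval {chrom}:{start}-{end} out of bounds")
    return float(arr[start:end].mean())


def estimate_copy_number(
    profile: DepthProfile,
    genes: Mapping[str, Interval],
    control: Interval,
    flanks: Optional[Mapping[str, Tuple[Optional[Interval], Optional[Interval]]]] = None,
) -> List[CopyNumberEstimate]:
    """Depth-ratio copy number for each gene, calibrated by the control."""
    median = profile.median_depth()
    if median <= 0:
        raise DepthError("genome median depth is zero; cannot estimate copy number")
    control_ratio = _mean_depth(profile, control) / median
    pass_control = abs(control_ratio - 1.0) <= CONTROL_TOLERANCE
    estimates = []
    for gene, interval in genes.items():
        raw = _mean_depth(profile, interval) / median
        up_iv, down_iv = (flanks or {}).get(gene, (None, None))
        estimates.append(
            CopyNumberEstimate(
                strain=profile.strain,
                gene=gene,
                raw_ratio=raw,
                control_ratio=control_ratio,
                copy_number=raw / control_ratio,
                pass_control=pass_control,
                flank_up=_mean_depth(profile, up_iv) / median if up_iv else None,
                flank_down=_mean_depth(profile, down_iv) / median if down_iv else None,
            )
        )
    return estimates


def estimates_frame(estimates: Sequence[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.to_row() for e in estimates])


@dataclass
class GroupComparison:
    summary: pd.DataFrame  # group, n, median, q25, q75
    kruskal_statistic: Optional[float]
    kruskal_p: Optional[float]
    dunn: Optional[pd.DataFrame]  # group_a, group_b, z, p, p_adjusted
    excluded_groups: List[str]


def cnv_group_summary(
    values: Mapping[str, Sequence[float]],
) -> GroupComparison:
    """Per-group copy-number distributions plus Kruskal-Wallis omnibus and
    pairwise Dunn tests with Bonferroni correction.

    Groups with fewer than 2 strains are excluded with a warning. With a
    single usable group the omnibus and post hoc steps are skipped.
    """
    usable: Dict[str, np.ndarray] = {}
    excluded: List[str] = []
    for group, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            excluded.append(group)
            warnings.warn(f"group {group!r} has fewer than 2 strains; excluded", UserWarning)
        else:
            usable[group] = arr
    rows = [
        {
            "group": g,
            "n": int(v.size),
            "median": float(np.median(v)),
            "q25": float(np.quantile(v, 0.25)),
            "q75": float(np.quantile(v, 0.75)),
        }
        for g, v in sorted(usable.items())
    ]
    summary = pd.DataFrame(rows, columns=["group", "n", "median", "q25", "q75"])
    if len(usable) < 2:
        return GroupComparison(summary, None, None, None, sorted(excluded))

    samples = [usable[g] for g in sorted(usable)]
    try:
        with np.errstate(invalid="ignore"):
            stat, p = stats.kruskal(*samples)
        if not (np.isfinite(stat) and np.isfinite(p)):
            stat, p = 0.0, 1.0
    except ValueError:  # all values identical across groups
        stat, p = 0.0, 1.0
    dunn = _dunn_bonferroni(usable)
    return GroupComparison(summary, float(stat), float(p), dunn, sorted(excluded))


def _dunn_bonferroni(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum post hoc z tests with a tie correction; two-sided
    p-values multiplied by the number of pairs (capped at 1)."""
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks: Dict[str, float] = {}
    offset = 0
    for g in names:
        size = groups[g].size
        mean_ranks[g] = float(ranks[offset : offset + size].mean())
        offset += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        if variance_base <= 0:  # every observation tied
            z, p = 0.0, 1.0
        else:
            se = np.sqrt(variance_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p": float(p),
                "p_adjusted": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p", "p_adjusted"])
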