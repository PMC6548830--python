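"""Sliding-window divergence of a consensus against a reference and
segmentation of the sub-genome mosaic into conspecific/heterospecific blocks.

Mismatches are counted with pairwise deletion: only positions where both the
consensus and the reference carry a non-N base are compared. Windows with
fewer compared sites than ``min_sites_fraction`` of their span are NO_DATA.
A window is HETEROSPECIFIC when its divergence strictly exceeds the
interspecies threshold (default 10%), CONSPECIFIC otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import Genome, HybscanError, N_CODE

LABEL_CONSPECIFIC = "CONSPECIFIC"
LABEL_HETEROSPECIFIC = "HETEROSPECIFIC"
LABEL_NO_DATA = "NO_DATA"


class AlignmentLengthError(HybscanError):
    pass


@dataclass
class DivergenceProfile:
    strain: str
    window: int
    step: int
    windows: pd.DataFrame  # chrom, start, end, compared, mismatches, divergence, label
    blocks: Optional[pd.DataFrame] = None  # chrom, start, end, label
    foreign_fraction: Optional[float] = None
    threshold: Optional[float] = None


def window_divergence(
    consensus: Genome,
    reference: Genome,
    window: int = 10_000,
    step: int = 10_000,
    strain: Optional[str] = None,
) -> DivergenceProfile:
    """Windowed mismatch fraction, trailing partial window included."""
    if not (1 <= step <= window):
        raise ValueError("require window >= step >= 1")
    rows = []
    for chrom, ref in reference.chroms.items():
        if chrom not in consensus.chroms:
            raise AlignmentLengthError(f"consensus missing chromosome {chrom}")
        con = consensus.chroms[chrom]
        if len(con) != len(ref):
            raise AlignmentLengthError(
                f"{chrom}: consensus length {len(con)} != reference length {len(ref)}"
            )
        both = (con != N_CODE) & (ref != N_CODE)
        mismatch = both & (con != ref)
        # cumulative sums make every window an O(1) range query
        cum_both = np.concatenate([[0], np.cumsum(both)])
        cum_mis = np.concatenate([[0], np.cumsum(mismatch)])
        length = len(ref)
        for start in range(0, length, step):
            end = min(start + window, length)
            compared = int(cum_both[end] - cum_both[start])
            mismatches = int(cum_mis[end] - cum_mis[start])
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "compared": compared,
                    "mismatches": mismatches,
                    "divergence": mismatches / compared if compared else np.nan,
                }
            )
            if end == length:
                break
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "compared", "mismatches", "divergence"])
    return DivergenceProfile(strain=strain or consensus.name, window=window, step=step, windows=frame)


def label_windows(
    profile: DivergenceProfile,
    threshold: float = 0.10,
    min_sites_fraction: float = 0.5,
) -> DivergenceProfile:
    """Label windows, merge same-label runs into blocks and compute the
    heterospecific (foreign) fraction of the labeled genome.

    Divergence exactly at the threshold labels CONSPECIFIC (strict ``>`` for
    heterospecific). ``foreign_fraction`` is None when no window has data.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    win = profile.windows.copy()
    span = win["end"] - win["start"]
    labels = np.where(
        win["compared"] < min_sites_fraction * span,
        LABEL_NO_DATA,
        np.where(win["divergence"].fillna(0.0) > threshold, LABEL_HETEROSPECIFIC, LABEL_CONSPECIFIC),
    )
    win["label"] = labels

    blocks = _merge_blocks(win)
    labeled = win[win["label"] != LABEL_NO_DATA]
    labeled_span = (labeled["end"] - labeled["start"]).sum()
    if labeled_span > 0:
        het = labeled[labeled["label"] == LABEL_HETEROSPECIFIC]
        foreign = float((het["end"] - het["start"]).sum() / labeled_span)
    else:
        foreign = None
    return DivergenceProfile(
        strain=profile.strain,
        window=profile.window,
        step=profile.step,
        windows=win,
        blocks=blocks,
        foreign_fraction=foreign,
        threshold=threshold,
    )


def _merge_blocks(windows: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in windows.itertuples():
        if rows and rows[-1][0] == r.chrom and rows[-1][3] == r.label and rows[-1][2] >= r.start:
            rows[-1][2] = max(rows[-1][2], r.end)
        else:
            rows.append([r.chrom, r.start, r.end, r.label])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
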