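"""Shared data containers used across the pipeline stages.

Sequences are held internally as ``numpy.uint8`` arrays of ASCII codes over
the five-letter alphabet ``{A, C, G, T, N}``; conversion to/from python
strings happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np
import pandas as pd

N_CODE = ord("N")
BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: species labels used by the simulator; the analysis modules accept any labels
SPECIES_A = "spA"
SPECIES_B = "spB"


class HybscanError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(HybscanError):
    """Invalid simulation or analysis configuration."""


class LayoutError(HybscanError):
    """Requested ORF layout cannot fit in the genome."""


class IntervalError(HybscanError):
    """Malformed or out-of-bounds genomic interval."""


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


class OriginState(str, Enum):
    """True per-locus origin in the simulated diploid hybrid.

    CC: both alleles from parent A; PP: both from parent B; CP: one of each.
    """

    CC = "CC"
    PP = "PP"
    CP = "CP"


class OriginCall(str, Enum):
    """Per ortholog-group call emitted by the foreign-ORF caller."""

    REF_ONLY = "REF_ONLY"
    FOREIGN = "FOREIGN"
    HETEROZYGOUS = "HETEROZYGOUS"
    ABSENT = "ABSENT"


@dataclass
class Genome:
    """A named genome: mapping of chromosome name -> uint8 sequence array."""

    name: str
    chroms: Dict[str, np.ndarray]

    def __len__(self) -> int:
        return sum(len(a) for a in self.chroms.values())

    def sequences(self) -> Iterator[Tuple[str, str]]:
        for chrom, arr in self.chroms.items():
            yield chrom, array_to_seq(arr)

    def copy(self) -> "Genome":
        return Genome(self.name, {c: a.copy() for c, a in self.chroms.items()})


@dataclass
class DepthProfile:
    """Per-base read depth aligned to the parent-A coordinate system."""

    strain: str
    depths: Dict[str, np.ndarray]

    def median_depth(self) -> float:
        """Median depth over covered (depth > 0) positions; 0.0 if none."""
        pooled = np.concatenate([d[d > 0] for d in self.depths.values()]) if self.depths else np.array([])
        if pooled.size == 0:
            return 0.0
        return float(np.median(pooled))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, d in self.depths.items():
            rows.append(pd.DataFrame({"chrom": chrom, "pos": np.arange(len(d)), "depth": d}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, strain: str, frame: pd.DataFrame) -> "DepthProfile":
        depths: Dict[str, np.ndarray] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            size = int(sub["pos"].max()) + 1
            arr = np.zeros(size, dtype=float)
            arr[sub["pos"].to_numpy()] = sub["depth"].to_numpy()
            depths[str(chrom)] = arr
        return cls(strain=strain, depths=depths)


@dataclass
class ReadCountTable:
    """Per-strain mapped read counts per (ortholog group, species)."""

    strain: str
    read_length: int
    counts: pd.DataFrame  # columns: group_id, species, count
    total_mapped: int
    median_depth: float

    def __post_init__(self) -> None:
        required = {"group_id", "species", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative read counts")

    def count(self, group_id: str, species: str) -> int:
        sel = self.counts[(self.counts["group_id"] == group_id) & (self.counts["species"] == species)]
        return int(sel["count"].sum())

    def group_counts(self, group_id: str) -> Dict[str, int]:
        sel = self.counts[self.counts["group_id"] == group_id]
        return {str(r.species): int(r.count) for r in sel.itertuples()}


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check the ortholog annotation table (0-based half-open coordinates)."""
    required = {"group_id", "species", "chrom", "start", "end", "strand", "length"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if (annotations["end"] <= annotations["start"]).any():
        raise IntervalError("annotation intervals must satisfy start < end")
    if ((annotations["end"] - annotations["start"]) != annotations["length"]).any():
        raise IntervalError("annotation length column inconsistent with start/end")
    return annotations
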