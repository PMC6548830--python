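"""SNP extraction with a site-occupancy filter, foreign-region masking, and
a neighbor-joining distance tree for cohort-structure checks.

A site enters the matrix when it is polymorphic (at least two distinct non-N
alleles across strains) and callable (non-N) in at least the occupancy
fraction of strains (inclusive, default 85%). Masking foreign blocks before
extraction removes the heterospecific sub-genome from the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .datatypes import Genome, HybscanError, IntervalError, N_CODE, array_to_seq

DEFAULT_OCCUPANCY = 0.85


class DistanceError(HybscanError):
    """A strain pair shares no jointly callable sites."""


@dataclass
class SNPMatrix:
    strains: List[str]  # sorted
    chroms: np.ndarray  # (n_sites,) object array of chromosome names
    positions: np.ndarray  # (n_sites,) int
    alleles: np.ndarray  # (n_strains, n_sites) uint8, N_CODE for missing

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def alignment(self) -> Dict[str, str]:
        """Concatenated SNP alignment, one row per strain."""
        return {s: array_to_seq(self.alleles[i]) for i, s in enumerate(self.strains)}

    def site_table(self) -> pd.DataFrame:
        frame = pd.DataFrame({"chrom": self.chroms, "pos": self.positions})
        for i, s in enumerate(self.strains):
            frame[s] = list(array_to_seq(self.alleles[i]))
        return frame

    def to_phylip(self) -> str:
        lines = [f"{len(self.strains)} {self.n_sites}"]
        for strain, seq in self.alignment().items():
            lines.append(f"{strain}  {seq}")
        return "\n".join(lines) + "\n"


def _stack(consensuses: Mapping[str, Genome], chrom: str) -> np.ndarray:
    return np.vstack([consensuses[s].chroms[chrom] for s in sorted(consensuses)])


def extract_snps(
    consensuses: Mapping[str, Genome],
    occupancy: float = DEFAULT_OCCUPANCY,
) -> SNPMatrix:
    """Retain sites with >= occupancy non-N calls and >= 2 distinct alleles."""
    if len(consensuses) < 2:
        raise ValueError("extract_snps requires at least 2 strains")
    if not (0.0 < occupancy <= 1.0):
        raise ValueError("occupancy must lie in (0, 1]")
    strains = sorted(consensuses)
    n = len(strains)
    chrom_names: List[np.ndarray] = []
    positions: List[np.ndarray] = []
    columns: List[np.ndarray] = []
    ref_chroms = consensuses[strains[0]].chroms
    for chrom in ref_chroms:
        matrix = _stack(consensuses, chrom)
        if matrix.shape[0] != n or len({len(consensuses[s].chroms[chrom]) for s in strains}) != 1:
            raise ValueError(f"consensus lengths differ on {chrom}")
        non_n = matrix != N_CODE
        occupancy_ok = non_n.sum(axis=0) >= occupancy * n - 1e-9
        low = np.where(non_n, matrix, np.uint8(255)).min(axis=0)
        high = np.where(non_n, matrix, np.uint8(0)).max(axis=0)
        polymorphic = (high > low) & non_n.any(axis=0)
        keep = occupancy_ok & polymorphic
        idx = np.flatnonzero(keep)
        chrom_names.append(np.full(idx.size, chrom, dtype=object))
        positions.append(idx)
        columns.append(matrix[:, idx])
    return SNPMatrix(
        strains=strains,
        chroms=np.concatenate(chrom_names) if chrom_names else np.array([], dtype=object),
        positions=np.concatenate(positions) if positions else np.array([], dtype=int),
        alleles=np.hstack(columns) if columns else np.empty((n, 0), dtype=np.uint8),
    )


def mask_foreign(
    consensuses: Mapping[str, Genome],
    blocks: Mapping[str, pd.DataFrame],
) -> Dict[str, Genome]:
    """Set positions inside each strain's foreign blocks to N.

    ``blocks[strain]`` needs columns chrom/start/end; strains without an
    entry pass through unchanged.
    """
    masked: Dict[str, Genome] = {}
    for strain, genome in consensuses.items():
        out = genome.copy()
        for row in blocks.get(strain, pd.DataFrame(columns=["chrom", "start", "end"])).itertuples():
            if row.chrom not in out.chroms:
                raise IntervalError(f"{strain}: unknown chromosome {row.chrom}")
            arr = out.chroms[row.chrom]
            if not (0 <= row.start < row.end <= len(arr)):
                raise IntervalError(
                    f"{strain}: interval {row.chrom}:{row.start}-{row.end} out of bounds"
                )
            arr[row.start : row.end] = N_CODE
        masked[strain] = out
    return masked


def pairwise_distances(matrix: SNPMatrix) -> pd.DataFrame:
    """Mismatch fraction over sites non-N in both strains of each pair."""
    n = len(matrix.strains)
    non_n = matrix.alleles != N_CODE
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = non_n[i] & non_n[j]
            total = int(joint.sum())
            if total == 0:
                raise DistanceError(
                    f"strains {matrix.strains[i]} and {matrix.strains[j]} share no callable sites"
                )
            mism = int((matrix.alleles[i, joint] != matrix.alleles[j, joint]).sum())
            dist[i, j] = dist[j, i] = mism / total
    return pd.DataFrame(dist, index=matrix.strains, columns=matrix.strains)


def distance_tree(matrix: SNPMatrix) -> Tuple[pd.DataFrame, str, TreeNode]:
    """Neighbor-joining tree from pairwise mismatch distances (Newick)."""
    if len(matrix.strains) < 3:
        raise ValueError("distance_tree requires at least 3 strains")
    dist = pairwise_distances(matrix)
    dm = DistanceMatrix(dist.to_numpy(), ids=list(dist.index))
    tree = nj(dm)
    newick = str(tree).strip()
    return dist, newick, tree


def has_bipartition(tree: TreeNode, labels: Iterable[str]) -> bool:
    """True when some edge splits the leaf set into ``labels`` vs the rest."""
    wanted = frozenset(labels)
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    if not wanted or not wanted < all_leaves:
        return wanted == all_leaves
    complement = all_leaves - wanted
    for node in tree.non_tips(include_self=True):
        clade = frozenset(leaf.name for leaf in node.tips())
        if clade == wanted or clade == complement:
            return True
    return False
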