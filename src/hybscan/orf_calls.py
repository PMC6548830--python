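"""Foreign-ORF detection from competitive per-ORF read coverage.

For every ortholog group: species whose ortholog captured at least 25% of
the reads of the best-covered ortholog in the group are retained (spurious
cross-mapping control); a retained ortholog is *present* when its
fold-coverage (reads x read_length / ORF length) reaches one fourth of the
strain's median genome coverage. Presence of the reference ortholog only ->
REF_ONLY; a foreign ortholog only -> FOREIGN; both -> HETEROZYGOUS
(co-existing alleles of the two species); neither -> ABSENT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .datatypes import (
    HybscanError,
    OriginCall,
    ReadCountTable,
    validate_annotations,
)

DEFAULT_PRESENCE_FRACTION = 0.25  # of median genome coverage
DEFAULT_GROUP_READ_FRACTION = 0.25  # of the best ortholog's read count


class UnknownGroupError(HybscanError):
    """Count table refers to ortholog groups absent from the annotations."""

    def __init__(self, group_ids: Sequence[str]):
        self.group_ids = sorted(group_ids)
        super().__init__(f"unknown ortholog groups in count table: {self.group_ids}")


def orf_coverage(count: int, read_length: int, orf_length: int) -> float:
    """Fold-coverage of one ORF: count * read_length / orf_length."""
    if orf_length <= 0:
        raise ValueError(f"orf_length must be > 0 (got {orf_length})")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * read_length / orf_length


def filter_intra_group(
    counts: Mapping[str, int],
    group_read_fraction: float = DEFAULT_GROUP_READ_FRACTION,
) -> Set[str]:
    """Species retained within one group: count >= fraction * max count.

    The comparison is inclusive; an all-zero group retains nothing.
    """
    if not counts:
        return set()
    top = max(counts.values())
    if top <= 0:
        return set()
    return {sp for sp, c in counts.items() if c >= group_read_fraction * top}


@dataclass
class GroupCall:
    call: OriginCall
    ref_coverage: float
    foreign_species: Optional[str]
    foreign_coverage: float


@dataclass
class OriginCallSet:
    strain: str
    ref_species: str
    calls: Dict[str, GroupCall]
    presence_fraction: float
    group_read_fraction: float
    median_depth: float

    def call(self, group_id: str) -> OriginCall:
        return self.calls[group_id].call

    def groups_with(self, *states: OriginCall) -> Set[str]:
        wanted = set(states)
        return {g for g, c in self.calls.items() if c.call in wanted}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strain": self.strain,
                "group_id": g,
                "call": c.call.value,
                "ref_cov": c.ref_coverage,
                "foreign_species": c.foreign_species or "",
                "foreign_cov": c.foreign_coverage,
            }
            for g, c in sorted(self.calls.items())
        ]
        return pd.DataFrame(rows)


def call_origin(
    table: ReadCountTable,
    annotations: pd.DataFrame,
    ref_species: str,
    presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
    group_read_fraction: float = DEFAULT_GROUP_READ_FRACTION,
) -> OriginCallSet:
    """Classify every annotated ortholog group for one strain.

    With more than one foreign species, the call is HETEROZYGOUS only when
    the reference ortholog also passes; otherwise FOREIGN with the
    best-covered passing foreign species recorded.
    """
    validate_annotations(annotations)
    if table.median_depth <= 0:
        raise ValueError("median genome depth must be > 0 to call origins")

    lengths: Dict[Tuple[str, str], int] = {
        (r.group_id, r.species): int(r.length) for r in annotations.itertuples()
    }
    known_groups = set(annotations["group_id"])
    table_groups = set(table.counts["group_id"])
    unknown = table_groups - known_groups
    if unknown:
        raise UnknownGroupError(list(unknown))

    presence_cutoff = presence_fraction * table.median_depth
    calls: Dict[str, GroupCall] = {}
    counts_by_group: Dict[str, Dict[str, int]] = {g: {} for g in known_groups}
    for r in table.counts.itertuples():
        counts_by_group[r.group_id][r.species] = counts_by_group[r.group_id].get(r.species, 0) + int(r.count)

    for group_id in known_groups:
        counts = counts_by_group[group_id]
        retained = filter_intra_group(counts, group_read_fraction)
        passing: Dict[str, float] = {}
        for species in retained:
            length = lengths.get((group_id, species))
            if length is None:
                continue
            cov = orf_coverage(counts.get(species, 0), table.read_length, length)
            if cov >= presence_cutoff:
                passing[species] = cov
        ref_cov = orf_coverage(
            counts.get(ref_species, 0), table.read_length, lengths.get((group_id, ref_species), 1)
        ) if (group_id, ref_species) in lengths else 0.0
        foreign_passing = {sp: cov for sp, cov in passing.items() if sp != ref_species}
        best_foreign = max(foreign_passing, key=foreign_passing.get) if foreign_passing else None
        if ref_species in passing and best_foreign is not None:
            call = OriginCall.HETEROZYGOUS
        elif ref_species in passing:
            call = OriginCall.REF_ONLY
        elif best_foreign is not None:
            call = OriginCall.FOREIGN
        else:
            call = OriginCall.ABSENT
        calls[group_id] = GroupCall(
            call=call,
            ref_coverage=ref_cov,
            foreign_species=best_foreign,
            foreign_coverage=foreign_passing.get(best_foreign, 0.0) if best_foreign else 0.0,
        )
    return OriginCallSet(
        strain=table.strain,
        ref_species=ref_species,
        calls=calls,
        presence_fraction=presence_fraction,
        group_read_fraction=group_read_fraction,
        median_depth=table.median_depth,
    )


@dataclass
class CallSummary:
    per_strain_foreign: Dict[str, int]  # FOREIGN or HETEROZYGOUS groups per strain
    union: Set[str]  # groups FOREIGN/HETEROZYGOUS in >= 1 strain
    shared_core: Set[str]  # groups FOREIGN/HETEROZYGOUS in every strain
    heterozygous_union: Set[str]  # groups HETEROZYGOUS in >= 1 strain
    heterozygous_percent: Optional[float]  # of the union, one decimal

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strain": s, "n_foreign_or_het": n} for s, n in sorted(self.per_strain_foreign.items())
        ]
        return pd.DataFrame(rows)


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_calls(call_sets: Sequence[OriginCallSet]) -> CallSummary:
    """Cohort roll-up: per-strain foreign counts, union, shared core and the
    heterozygous percentage of the union (one decimal, half-up)."""
    if not call_sets:
        raise ValueError("summarize_calls requires at least one strain")
    foreign_states = (OriginCall.FOREIGN, OriginCall.HETEROZYGOUS)
    per_strain_sets = {cs.strain: cs.groups_with(*foreign_states) for cs in call_sets}
    union: Set[str] = set().union(*per_strain_sets.values())
    shared = set.intersection(*per_strain_sets.values()) if per_strain_sets else set()
    het_union: Set[str] = set().union(*(cs.groups_with(OriginCall.HETEROZYGOUS) for cs in call_sets))
    het_pct = _round_half_up(100.0 * len(het_union) / len(union), 1) if union else None
    return CallSummary(
        per_strain_foreign={s: len(g) for s, g in per_strain_sets.items()},
        union=union,
        shared_core=shared,
        heterozygous_union=het_union,
        heterozygous_percent=het_pct,
    )
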