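"""Synthetic homoploid-hybridization + loss-of-heterozygosity simulator.

Generates a pair of diverged parental genomes with shared ortholog
coordinates, diploid hybrid mosaics whose per-ORF origin is CC (both alleles
parent A), PP (both parent B) or CP (one of each), Poisson read counts with a
cross-species misassignment rate, per-base depth profiles with tandem
copy-number expansions, and a truth table for recovery experiments.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical (config, seed) pairs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    BASE_CODES,
    N_CODE,
    SPECIES_A,
    SPECIES_B,
    ConfigError,
    DepthProfile,
    Genome,
    LayoutError,
    OriginState,
    ReadCountTable,
    array_to_seq,
)

_STATES = (OriginState.CC, OriginState.PP, OriginState.CP)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model.

    ``origin_state_probs`` gives the per-ORF (per-block in contiguous mode)
    probabilities of the three diploid origin states. ``foreign_block_mode``
    is ``"per_orf"`` (ORFs draw origins independently; intergenic sequence
    stays parent A) or ``"contiguous"`` (the genome is tiled by blocks with
    exponentially distributed lengths; ORFs and intergenic sequence follow
    the containing block).
    """

    genome_length: int
    n_groups: int
    orf_length_range: Tuple[int, int] = (500, 1500)
    divergence: float = 0.10
    origin_state_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CC": 1.0, "PP": 0.0, "CP": 0.0}
    )
    foreign_block_mode: str = "per_orf"
    mean_block_length: int = 20_000
    depth: float = 20.0
    read_length: int = 250
    seq_error: float = 0.0
    misassign_rate: float = 0.0
    cnv_specs: Tuple[Tuple[str, int], ...] = ()
    n_strains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.state_probs()
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"origin_state_probs must sum to 1 (got {total!r})")
        if any(p < 0 for p in probs.values()):
            raise ConfigError("origin_state_probs must be non-negative")
        if not (0.0 <= self.divergence <= 0.75):
            raise ConfigError("divergence must be in [0, 0.75]")
        if self.depth <= 0:
            raise ConfigError("depth must be > 0")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        if self.genome_length < 1 or self.n_groups < 0:
            raise ConfigError("genome_length must be >= 1 and n_groups >= 0")
        lo, hi = self.orf_length_range
        if not (1 <= lo <= hi):
            raise ConfigError("orf_length_range must satisfy 1 <= min <= max")
        if self.foreign_block_mode not in ("per_orf", "contiguous"):
            raise ConfigError("foreign_block_mode must be 'per_orf' or 'contiguous'")
        if self.mean_block_length < 1:
            raise ConfigError("mean_block_length must be >= 1")
        if not (0.0 <= self.seq_error < 1.0) or not (0.0 <= self.misassign_rate <= 1.0):
            raise ConfigError("seq_error and misassign_rate must be probabilities")
        for gene, copies in self.cnv_specs:
            if int(copies) != copies or copies < 0:
                raise ConfigError(f"copy number for {gene} must be a non-negative integer")
        if self.n_strains < 1:
            raise ConfigError("n_strains must be >= 1")

    def state_probs(self) -> Dict[str, float]:
        probs = {"CC": 0.0, "PP": 0.0, "CP": 0.0}
        probs.update({str(k): float(v) for k, v in dict(self.origin_state_probs).items()})
        extra = set(probs) - {"CC", "PP", "CP"}
        if extra:
            raise ConfigError(f"unknown origin states: {sorted(extra)}")
        return probs

    def copy_number(self, group_id: str) -> int:
        for gene, copies in self.cnv_specs:
            if gene == group_id:
                return int(copies)
        return 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["origin_state_probs"] = dict(self.origin_state_probs)
        d["cnv_specs"] = [list(x) for x in self.cnv_specs]
        d["orf_length_range"] = list(self.orf_length_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["orf_length_range"] = tuple(raw.get("orf_length_range", (500, 1500)))
        raw["cnv_specs"] = tuple(tuple(x) for x in raw.get("cnv_specs", ()))
        return cls(**raw)


@dataclass
class HybridGenome:
    """One simulated hybrid strain: origin mosaic plus derived sequences."""

    strain: str
    origin_states: Dict[str, OriginState]  # group_id -> state
    blocks: pd.DataFrame  # chrom, start, end, origin
    consensus: Genome  # CP sites where parents differ are N-masked

    def haplotypes(self, parent_a: Genome, parent_b: Genome) -> Tuple[Genome, Genome]:
        """The two phased haplotypes implied by the block mosaic."""
        hap1 = {c: a.copy() for c, a in parent_a.chroms.items()}
        hap2 = {c: a.copy() for c, a in parent_a.chroms.items()}
        for row in self.blocks.itertuples():
            seg = slice(row.start, row.end)
            b = parent_b.chroms[row.chrom][seg]
            if row.origin == OriginState.PP.value:
                hap1[row.chrom][seg] = b
                hap2[row.chrom][seg] = b
            elif row.origin == OriginState.CP.value:
                hap2[row.chrom][seg] = b
        return (
            Genome(f"{self.strain}.hap1", hap1),
            Genome(f"{self.strain}.hap2", hap2),
        )


@dataclass
class TruthTable:
    """Ground truth recorded alongside each simulated cohort."""

    origin_states: Dict[str, Dict[str, OriginState]]  # strain -> group -> state
    foreign_fraction: Dict[str, float]  # strain -> fraction of foreign sites
    copy_numbers: Dict[str, Dict[str, int]]  # strain -> gene -> copies
    blocks: Dict[str, pd.DataFrame]  # strain -> (chrom, start, end, origin)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strain, states in self.origin_states.items():
            for group, state in states.items():
                rows.append(
                    {
                        "strain": strain,
                        "group_id": group,
                        "origin": state.value,
                        "copy_number": self.copy_numbers.get(strain, {}).get(group, 1),
                    }
                )
        return pd.DataFrame(rows)


def _rng_for(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def simulate_parents(config: SimulationConfig) -> Tuple[Genome, Genome, pd.DataFrame]:
    """Generate parent A, parent B (i.i.d. per-site substitution at rate
    ``divergence``, uniform over the 3 alternative bases) and the ortholog
    annotation table. Ortholog pairs occupy identical coordinates in both
    parents."""
    rng = _rng_for(config, 0)
    length = config.genome_length
    idx_a = rng.integers(0, 4, size=length)
    parent_a = BASE_CODES[idx_a]

    sub_mask = rng.random(length) < config.divergence
    offsets = rng.integers(1, 4, size=int(sub_mask.sum()))
    idx_b = idx_a.copy()
    idx_b[sub_mask] = (idx_b[sub_mask] + offsets) % 4
    parent_b = BASE_CODES[idx_b]

    annotations = _layout_orfs(config, rng)
    genome_a = Genome("parentA", {"chr1": parent_a})
    genome_b = Genome("parentB", {"chr1": parent_b})
    return genome_a, genome_b, annotations


def _layout_orfs(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.orf_length_range
    n = config.n_groups
    lengths = rng.integers(lo, hi + 1, size=n)
    slack = config.genome_length - int(lengths.sum())
    if slack < 0:
        raise LayoutError(
            f"cannot place {n} ORFs of total length {int(lengths.sum())} "
            f"in a {config.genome_length} bp genome"
        )
    # distribute the slack over the n+1 gaps between/flanking ORFs
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if n >= 0 else []
    starts = np.cumsum(gaps[:n]) + np.concatenate([[0], np.cumsum(lengths[:-1])]) if n else np.array([], dtype=int)
    width = max(4, len(str(max(n, 1))))
    rows = []
    for i in range(n):
        gid = f"g{i + 1:0{width}d}"
        for species in (SPECIES_A, SPECIES_B):
            rows.append(
                {
                    "group_id": gid,
                    "species": species,
                    "chrom": "chr1",
                    "start": int(starts[i]),
                    "end": int(starts[i] + lengths[i]),
                    "strand": "+",
                    "length": int(lengths[i]),
                }
            )
    return pd.DataFrame(rows, columns=["group_id", "species", "chrom", "start", "end", "strand", "length"])


def _draw_states(rng: np.random.Generator, probs: Dict[str, float], n: int) -> List[OriginState]:
    p = np.array([probs["CC"], probs["PP"], probs["CP"]])
    picks = rng.choice(3, size=n, p=p / p.sum())
    return [_STATES[i] for i in picks]


def _blocks_per_orf(annotations: pd.DataFrame, states: Mapping[str, OriginState], length: int) -> pd.DataFrame:
    """Intervals: each ORF with its own state, intergenic gaps stay CC."""
    orfs = annotations[annotations["species"] == SPECIES_A].sort_values("start")
    rows = []
    cursor = 0
    for row in orfs.itertuples():
        if row.start > cursor:
            rows.append(("chr1", cursor, row.start, OriginState.CC.value))
        rows.append(("chr1", row.start, row.end, states[row.group_id].value))
        cursor = row.end
    if cursor < length:
        rows.append(("chr1", cursor, length, OriginState.CC.value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])


def _blocks_contiguous(
    rng: np.random.Generator, config: SimulationConfig, probs: Dict[str, float]
) -> pd.DataFrame:
    length = config.genome_length
    bounds = [0]
    while bounds[-1] < length:
        step = max(1, int(round(rng.exponential(config.mean_block_length))))
        bounds.append(min(length, bounds[-1] + step))
    states = _draw_states(rng, probs, len(bounds) - 1)
    rows = [
        ("chr1", bounds[i], bounds[i + 1], states[i].value)
        for i in range(len(bounds) - 1)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])


def _orf_states_from_blocks(annotations: pd.DataFrame, blocks: pd.DataFrame) -> Dict[str, OriginState]:
    """Each ORF takes the state of the block containing its midpoint."""
    orfs = annotations[annotations["species"] == SPECIES_A]
    starts = blocks["start"].to_numpy()
    states: Dict[str, OriginState] = {}
    for row in orfs.itertuples():
        mid = (row.start + row.end) // 2
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        states[row.group_id] = OriginState(blocks["origin"].iloc[i])
    return states


def _consensus_from_blocks(parent_a: Genome, parent_b: Genome, blocks: pd.DataFrame, strain: str) -> Genome:
    """CC -> parent A bases; PP -> parent B; CP -> N where the parents differ
    (mirrors masking of ambiguous heterozygous calls in a consensus)."""
    chroms: Dict[str, np.ndarray] = {}
    for chrom, a in parent_a.chroms.items():
        out = a.copy()
        b = parent_b.chroms[chrom]
        for row in blocks[blocks["chrom"] == chrom].itertuples():
            seg = slice(row.start, row.end)
            if row.origin == OriginState.PP.value:
                out[seg] = b[seg]
            elif row.origin == OriginState.CP.value:
                diff = a[seg] != b[seg]
                region = out[seg]
                region[diff] = N_CODE
                out[seg] = region
        chroms[chrom] = out
    return Genome(strain, chroms)


def _foreign_fraction(blocks: pd.DataFrame, length: int) -> float:
    """PP intervals count fully, CP intervals half (one foreign allele)."""
    lens = blocks["end"] - blocks["start"]
    pp = lens[blocks["origin"] == OriginState.PP.value].sum()
    cp = lens[blocks["origin"] == OriginState.CP.value].sum()
    return float((pp + 0.5 * cp) / length)


def simulate_hybrid(
    parents: Tuple[Genome, Genome],
    annotations: pd.DataFrame,
    config: SimulationConfig,
) -> Tuple[List[HybridGenome], TruthTable]:
    """Draw ``n_strains`` hybrid mosaics and their truth table."""
    parent_a, parent_b = parents
    probs = config.state_probs()
    hybrids: List[HybridGenome] = []
    truth_states: Dict[str, Dict[str, OriginState]] = {}
    truth_fraction: Dict[str, float] = {}
    truth_cn: Dict[str, Dict[str, int]] = {}
    truth_blocks: Dict[str, pd.DataFrame] = {}

    for s in range(config.n_strains):
        strain = f"strain{s + 1:03d}"
        rng = _rng_for(config, 1, s)
        if config.foreign_block_mode == "contiguous":
            blocks = _blocks_contiguous(rng, config, probs)
            states = _orf_states_from_blocks(annotations, blocks)
        else:
            orf_ids = list(annotations.loc[annotations["species"] == SPECIES_A, "group_id"])
            drawn = _draw_states(rng, probs, len(orf_ids))
            states = dict(zip(orf_ids, drawn))
            blocks = _blocks_per_orf(annotations, states, config.genome_length)
        blocks = _merge_adjacent(blocks)
        consensus = _consensus_from_blocks(parent_a, parent_b, blocks, strain)
        hybrids.append(HybridGenome(strain, states, blocks, consensus))
        truth_states[strain] = states
        truth_fraction[strain] = _foreign_fraction(blocks, config.genome_length)
        truth_cn[strain] = {gene: int(c) for gene, c in config.cnv_specs}
        truth_blocks[strain] = blocks

    truth = TruthTable(truth_states, truth_fraction, truth_cn, truth_blocks)
    return hybrids, truth


def _merge_adjacent(blocks: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in blocks.sort_values(["chrom", "start"]).itertuples():
        if rows and rows[-1][0] == row.chrom and rows[-1][3] == row.origin and rows[-1][2] == row.start:
            rows[-1][2] = row.end
        else:
            rows.append([row.chrom, row.start, row.end, row.origin])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])


# ---------------------------------------------------------------------------
# read-count / depth / read simulation


def _dosages(state: OriginState) -> Tuple[float, float]:
    if state is OriginState.CC:
        return 1.0, 0.0
    if state is OriginState.PP:
        return 0.0, 1.0
    return 0.5, 0.5  # CP: diploid, one allele each


def simulate_read_counts(
    hybrid: HybridGenome,
    annotations: pd.DataFrame,
    config: SimulationConfig,
) -> Tuple[ReadCountTable, DepthProfile]:
    """Per-ORF Poisson counts with mean depth*length*dosage/read_length; a
    fraction ``misassign_rate`` of each ORF's reads is counted toward the
    other species' ortholog. The depth profile is drawn per base at the local
    dosage-weighted rate (copy-number genes scale it by their copy count)."""
    rng = _rng_for(config, 2, _strain_index(hybrid.strain))
    orfs = annotations[annotations["species"] == SPECIES_A].sort_values("start")
    m = config.misassign_rate
    rows = []
    for row in orfs.itertuples():
        state = hybrid.origin_states[row.group_id]
        dos_a, dos_b = _dosages(state)
        copies = config.copy_number(row.group_id)
        lam = config.depth * row.length / config.read_length
        n_a = rng.poisson(lam * dos_a * copies)
        n_b = rng.poisson(lam * dos_b * copies)
        swap_a = rng.binomial(n_a, m) if n_a else 0
        swap_b = rng.binomial(n_b, m) if n_b else 0
        rows.append({"group_id": row.group_id, "species": SPECIES_A, "count": int(n_a - swap_a + swap_b)})
        rows.append({"group_id": row.group_id, "species": SPECIES_B, "count": int(n_b - swap_b + swap_a)})
    counts = pd.DataFrame(rows, columns=["group_id", "species", "count"])

    profile = _depth_profile(hybrid, orfs, config, rng)
    orf_total = int(counts["count"].sum())
    orf_len = int(orfs["length"].sum())
    intergenic = config.genome_length - orf_len
    unplaced = int(rng.poisson(config.depth * intergenic / config.read_length))
    table = ReadCountTable(
        strain=hybrid.strain,
        read_length=config.read_length,
        counts=counts,
        total_mapped=orf_total + unplaced,
        median_depth=profile.median_depth(),
    )
    return table, profile


def _depth_profile(
    hybrid: HybridGenome,
    orfs: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> DepthProfile:
    rate = np.full(config.genome_length, config.depth)
    for row in orfs.itertuples():
        copies = config.copy_number(row.group_id)
        if copies != 1:
            rate[row.start : row.end] *= copies
    depth = rng.poisson(rate).astype(float)
    return DepthProfile(hybrid.strain, {"chr1": depth})


def _strain_index(strain: str) -> int:
    digits = "".join(ch for ch in strain if ch.isdigit())
    return int(digits) if digits else 0


def simulate_reads(
    hybrid: HybridGenome,
    parents: Tuple[Genome, Genome],
    annotations: pd.DataFrame,
    config: SimulationConfig,
) -> List[Tuple[str, str]]:
    """Emit single-end reads drawn uniformly from the two haplotypes.

    Read names encode the parent-A coordinate of the read start
    (``strain|chrom|start|hapX``) so downstream depth profiling can place
    them without alignment. Copy-number genes contribute extra reads from
    the gene interval at rate (copies - 1).
    """
    rng = _rng_for(config, 3, _strain_index(hybrid.strain))
    hap1, hap2 = hybrid.haplotypes(*parents)
    haps = (hap1, hap2)
    length = config.genome_length
    rl = config.read_length
    if rl > length:
        raise ConfigError("read_length exceeds genome length")
    n_reads = int(rng.poisson(config.depth * length / rl))
    starts = rng.integers(0, length - rl + 1, size=n_reads)
    hap_pick = rng.integers(0, 2, size=n_reads)
    reads: List[Tuple[str, str]] = []
    for i in range(n_reads):
        reads.append(_make_read(hybrid.strain, haps[hap_pick[i]], int(starts[i]), int(hap_pick[i]), rl, config, rng, i))
    # extra reads for tandem copy-number genes
    extra_i = n_reads
    orf_rows = annotations[annotations["species"] == SPECIES_A]
    orfs = {r.group_id: r for r in orf_rows.itertuples()}
    for gene, copies in config.cnv_specs:
        if copies <= 1 or gene not in orfs:
            continue
        row = orfs[gene]
        span = max(1, row.end - row.start - rl + 1)
        n_extra = int(rng.poisson(config.depth * (copies - 1) * row.length / rl))
        estarts = rng.integers(row.start, row.start + span, size=n_extra)
        epick = rng.integers(0, 2, size=n_extra)
        for j in range(n_extra):
            reads.append(
                _make_read(hybrid.strain, haps[epick[j]], int(estarts[j]), int(epick[j]), rl, config, rng, extra_i)
            )
            extra_i += 1
    return reads


def _make_read(strain, hap, start, hap_idx, rl, config, rng, i) -> Tuple[str, str]:
    chrom = "chr1"
    arr = hap.chroms[chrom][start : start + rl].copy()
    if config.seq_error > 0:
        err = rng.random(rl) < config.seq_error
        n_err = int(err.sum())
        if n_err:
            idx = np.searchsorted(BASE_CODES, arr[err])
            idx = (idx + rng.integers(1, 4, size=n_err)) % 4
            arr[err] = BASE_CODES[idx]
    name = f"{strain}|{chrom}|{start}|hap{hap_idx + 1}|r{i}"
    return name, array_to_seq(arr)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at ``rate``; N positions are left untouched."""
    out = arr.copy()
    hit = (rng.random(len(arr)) < rate) & (out != N_CODE)
    n_hit = int(hit.sum())
    if n_hit:
        idx = np.searchsorted(BASE_CODES, out[hit])
        out[hit] = BASE_CODES[(idx + rng.integers(1, 4, size=n_hit)) % 4]
    return out


@dataclass
class DescendantCohort:
    """Hybrid descendants of one hybrid ancestor plus parent-A-like strains,
    for cohort-structure (monophyly) recovery experiments."""

    consensuses: Dict[str, Genome]  # strain -> consensus aligned to parent A
    foreign_blocks: Dict[str, pd.DataFrame]  # per-strain heterospecific BED
    hybrid_strains: List[str]
    reference_strains: List[str]


def simulate_descendant_cohort(
    config: SimulationConfig,
    n_hybrids: int = 6,
    n_reference: int = 6,
    ancestor_mut_rate: float = 0.005,
    hybrid_mut_rate: float = 0.002,
    reference_mut_rate: float = 0.004,
) -> DescendantCohort:
    """One hybrid ancestor (mosaic per ``config``) radiates into
    ``n_hybrids`` descendants; ``n_reference`` independent parent-A-like
    strains accumulate private substitutions only."""
    parent_a, parent_b, annotations = simulate_parents(config)
    hybrids, truth = simulate_hybrid((parent_a, parent_b), annotations, config)
    ancestor = hybrids[0]
    rng = _rng_for(config, 4)
    anc_arr = {c: _mutate(a, ancestor_mut_rate, rng) for c, a in ancestor.consensus.chroms.items()}
    blocks = ancestor.blocks
    foreign = blocks[blocks["origin"] == OriginState.PP.value][["chrom", "start", "end"]]

    consensuses: Dict[str, Genome] = {}
    foreign_blocks: Dict[str, pd.DataFrame] = {}
    hybrid_strains: List[str] = []
    reference_strains: List[str] = []
    for i in range(n_hybrids):
        name = f"hyb{i + 1:02d}"
        consensuses[name] = Genome(name, {c: _mutate(a, hybrid_mut_rate, rng) for c, a in anc_arr.items()})
        foreign_blocks[name] = foreign.copy()
        hybrid_strains.append(name)
    for i in range(n_reference):
        name = f"ref{i + 1:02d}"
        consensuses[name] = Genome(
            name, {c: _mutate(a, reference_mut_rate, rng) for c, a in parent_a.chroms.items()}
        )
        foreign_blocks[name] = foreign.iloc[0:0].copy()
        reference_strains.append(name)
    return DescendantCohort(consensuses, foreign_blocks, hybrid_strains, reference_strains)


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: parents, hybrids, per-strain counts/depths, truth."""
    parent_a, parent_b, annotations = simulate_parents(config)
    hybrids, truth = simulate_hybrid((parent_a, parent_b), annotations, config)
    tables: Dict[str, ReadCountTable] = {}
    profiles: Dict[str, DepthProfile] = {}
    for hyb in hybrids:
        table, profile = simulate_read_counts(hyb, annotations, config)
        tables[hyb.strain] = table
        profiles[hyb.strain] = profile
    return parent_a, parent_b, annotations, hybrids, tables, profiles, truth
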