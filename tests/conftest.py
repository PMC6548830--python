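import numpy as np
import pandas as pd
import pytest

from hybscan import Genome, ReadCountTable, SPECIES_A, SPECIES_B, SimulationConfig
from hybscan.datatypes import seq_to_array


def make_count_table(
    counts_by_group: dict,
    strain: str = "s1",
    read_length: int = 250,
    median_depth: float = 20.0,
) -> ReadCountTable:
    """counts_by_group: {group_id: {species: count}}."""
    rows = [
        {"group_id": g, "species": sp, "count": c}
        for g, per_sp in counts_by_group.items()
        for sp, c in per_sp.items()
    ]
    frame = pd.DataFrame(rows, columns=["group_id", "species", "count"])
    return ReadCountTable(
        strain=strain,
        read_length=read_length,
        counts=frame,
        total_mapped=int(frame["count"].sum()),
        median_depth=median_depth,
    )


def make_annotations(lengths_by_group: dict, species=(SPECIES_A, SPECIES_B)) -> pd.DataFrame:
    rows = []
    start = 0
    for g, length in lengths_by_group.items():
        for sp in species:
            rows.append(
                {
                    "group_id": g,
                    "species": sp,
                    "chrom": "chr1",
                    "start": start,
                    "end": start + length,
                    "strand": "+",
                    "length": length,
                }
            )
        start += length + 100
    return pd.DataFrame(rows)


def genome_from_str(name: str, seq: str) -> Genome:
    return Genome(name, {"chr1": seq_to_array(seq)})


@pytest.fixture
def small_config():
    return SimulationConfig(
        genome_length=60_000,
        n_groups=30,
        orf_length_range=(500, 1500),
        origin_state_probs={"CC": 0.6, "PP": 0.25, "CP": 0.15},
        misassign_rate=0.02,
        seed=11,
    )
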