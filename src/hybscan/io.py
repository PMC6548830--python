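"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA handling is delegated to Biopython; tables are pandas TSVs; block and
gene intervals travel as BED3+ (0-based, half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import Genome, IntervalError, array_to_seq, seq_to_array

PathLike = Union[str, Path]


def write_fasta(path: PathLike, records: Iterable[Tuple[str, str]], width: int = 80) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_genome(path: PathLike, genome: Genome) -> None:
    write_fasta(path, genome.sequences())


def read_genome(path: PathLike, name: str | None = None) -> Genome:
    chroms = {rec_id: seq_to_array(seq) for rec_id, seq in read_fasta(path)}
    return Genome(name or Path(path).stem, chroms)


def write_tsv(path: PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(path: PathLike, intervals: pd.DataFrame) -> None:
    """Write BED: chrom, start, end and any extra columns, no header."""
    cols = ["chrom", "start", "end"] + [c for c in intervals.columns if c not in ("chrom", "start", "end")]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: PathLike, extra_names: Iterable[str] = ("name",)) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end"] + list(extra_names)
    frame.columns = names[: frame.shape[1]]
    if (frame["end"] <= frame["start"]).any() or (frame["start"] < 0).any():
        raise IntervalError(f"malformed intervals in {path}")
    return frame


def genome_as_dict(genome: Genome) -> Dict[str, str]:
    return {chrom: array_to_seq(arr) for chrom, arr in genome.chroms.items()}
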