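"""File-format boundaries: FASTA/FASTQ via Biopython, TSV via pandas.

All pipeline intermediates are plain text so every stage is independently
inspectable. TSV outputs may carry ``#``-prefixed provenance headers;
readers here skip them.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError
from .preprocess import MidTable, ReadRecord
from .simulate import SimulatedRead


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write 4-line FASTQ with Phred+33 qualities."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out: list[ReadRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(ReadRecord(
            read_id=rec.id,
            bases=str(rec.seq).upper(),
            quals=tuple(rec.letter_annotations["phred_quality"]),
        ))
    return out


def write_paired_fastq(
    reads: Iterable[SimulatedRead], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write simulator output as a pooled (multiplexed) read-pair run."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r in reads:
            q1 = "".join(chr(int(q) + 33) for q in r.quals1)
            q2 = "".join(chr(int(q) + 33) for q in r.quals2)
            f1.write(f"@{r.read_id}/1\n{r.bases1}\n+\n{q1}\n")
            f2.write(f"@{r.read_id}/2\n{r.bases2}\n+\n{q2}\n")


def write_mid_table(table: MidTable, path: str | Path, header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("individual_id\tsex\tmid\n")
        for ind, sex, mid in table.rows:
            fh.write(f"{ind}\t{sex}\t{mid}\n")


def read_mid_table(path: str | Path) -> MidTable:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"MID table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"individual_id", "sex", "mid"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"MID table {path} must have columns {sorted(required)}")
    return MidTable(tuple(
        (row.individual_id, row.sex, row.mid) for row in df.itertuples()))


def write_tag_catalog(counts: dict[str, int], path: str | Path) -> None:
    """Catalog as (sequence, depth) TSV, gzipped if the path ends in .gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("sequence\tdepth\n")
        for seq in sorted(counts):
            fh.write(f"{seq}\t{counts[seq]}\n")


def read_tag_catalog(path: str | Path) -> dict[str, int]:
    opener = gzip.open if str(path).endswith(".gz") else open
    counts: dict[str, int] = {}
    with opener(str(path), "rt") as fh:
        header = fh.readline()
        assert header.startswith("sequence")
        for line in fh:
            seq, depth = line.rstrip("\n").split("\t")
            counts[seq] = int(depth)
    return counts


def write_tsv(df: pd.DataFrame, path: str | Path, header: list[str] | None = None) -> None:
    """DataFrame to TSV with optional '#'-prefixed provenance lines."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
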