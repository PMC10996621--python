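"""File-format helpers: FASTA, BED6, tab-separated truth/call tables, PAF.

Genomes are held in memory as plain ``dict[str, str]`` of upper-case DNA
strings keyed by sequence name; all coordinates in the package are 0-based,
half-open. Conversion to 1-based conventions happens only here, at format
boundaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TRUTH_COLUMNS = [
    "locus_id",
    "genome_id",
    "chrom",
    "start",
    "end",
    "strand",
    "structure_class",
    "tsd_seq",
    "divergence",
    "gag_intact",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str}, keep_default_na=False)
    df["tsd_seq"] = df["tsd_seq"].fillna("")
    df["gag_intact"] = df["gag_intact"].astype(bool)
    return df


def write_bed6(rows: Iterable[tuple[str, int, int, str, float, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+/BED6 file into a DataFrame (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


@dataclass(frozen=True)
class PafRecord:
    """One line of minimap2-style PAF output (coordinates 0-based, half-open)."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    block_len: int
    mapq: int


def read_paf(path: str | Path) -> list[PafRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                PafRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]),
                    int(f[9]), int(f[10]), int(f[11]),
                )
            )
    return records


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
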