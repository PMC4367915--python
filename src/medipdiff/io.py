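"""Plain-file I/O: FASTA, BED6 and TSV round-trips.

Internal coordinates are 0-based half-open throughout the package; BED shares
that convention so these helpers are straight tabular reads/writes. GFF3
(1-based inclusive) is converted in :mod:`medipdiff.annotation`.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: uppercase sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3-6 columns) into a DataFrame with BED6 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = BED6_COLUMNS[:ncol]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path, extra_columns: list[str] | None = None) -> None:
    """Write BED6 (+ optional extra columns) without header."""
    cols = BED6_COLUMNS + (extra_columns or [])
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
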