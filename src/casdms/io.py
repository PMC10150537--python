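"""File I/O shared across stages: FASTA/FASTQ, TSV tables, JSON diagnostics.

Every table writer is deterministic (stable row order, 6-significant-digit
floats) and stamps a header comment with the tool version and the digest of
the run configuration, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from . import __version__


class ParseError(ValueError):
    pass


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> Iterator[SeqRecord]:
    """Stream FASTQ records (PHRED+33); malformed quadruples raise
    :class:`ParseError` with the approximate record offset."""
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield rec
    except ValueError as exc:
        raise ParseError(
            f"{path}: malformed FASTQ near record {n + 1} (line ~{4 * n + 1}): {exc}"
        ) from exc


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_tsv_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV table (``#`` comment lines skipped), checking that the
    required columns are present."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing required column(s): {missing}")
    return df


def config_digest(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, config: dict | None = None, index: bool = True) -> None:
    """Deterministic TSV writer with a provenance header comment."""
    path = Path(path)
    header = f"# casdms v{__version__} config={config_digest(config)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", float_format="%.6g", index=index)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def counts_to_long(counts: pd.DataFrame) -> pd.DataFrame:
    """Wide count matrix -> long (variant_id, sample, count) interchange form."""
    long = counts.stack().rename("count").reset_index()
    long.columns = ["variant_id", "sample", "count"]
    return long


def counts_from_long(df: pd.DataFrame) -> pd.DataFrame:
    """Long (variant_id, sample, count) TSV -> wide count matrix."""
    for col in ("variant_id", "sample", "count"):
        if col not in df.columns:
            raise ParseError(f"count table missing required column {col!r}")
    wide = df.pivot_table(
        index="variant_id", columns="sample", values="count", fill_value=0, aggfunc="sum"
    )
    wide.columns.name = None
    return wide.astype(int)
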