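"""FASTA / TSV glue shared by the pipeline and CLI."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO


class InputError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read plain or gzipped FASTA into (id, sequence) pairs.

    Ids are the first whitespace-delimited token of each header; duplicate
    ids are an error.  Wrapped and unwrapped records are both accepted.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(path: str | Path, rows: list[dict] | pd.DataFrame, header_note: str = "") -> None:
    """Write a TSV report with an optional ``#``-prefixed provenance line."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
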