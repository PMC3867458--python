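"""File-format plumbing: TSV tables, FASTA transcripts, JSON summaries.

TSV is the interchange dialect for every table (tab-separated, header
row, UTF-8, '.' decimal); FASTA carries sequences; JSON carries summary
objects and ground-truth sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InvalidInputError(f"malformed TSV {path}: {exc}") from exc


def write_fasta(transcripts: pd.DataFrame, path) -> None:
    """Write an (id, sequence) frame as FASTA."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(row["sequence"]), id=row["id"], description="")
               for _, row in transcripts.iterrows()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> pd.DataFrame:
    """Read FASTA into an (id, sequence) frame; ids must be unique."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidInputError(f"no sequences in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InvalidInputError(f"duplicate sequence ids in {path}")
    return pd.DataFrame({"id": ids, "sequence": [str(r.seq) for r in records]})


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def read_count_table(path) -> pd.DataFrame:
    """Gene x condition count TSV with a 'gene' index column."""
    df = read_tsv(path)
    if "gene" not in df.columns:
        raise InvalidInputError(f"count table {path} lacks a 'gene' column")
    return df.set_index("gene")


def read_gene_set(path) -> list[str]:
    """One gene id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
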