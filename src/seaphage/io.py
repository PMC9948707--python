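"""Readers and writers for the plain-text formats used throughout.

Abundance matrices are pandas DataFrames with entities (OTUs, ASVs or viral
contigs) as rows and samples as columns; values are read counts, relative
abundances or absolute densities depending on the pipeline stage. Sequences
travel as plain ``{id: sequence}`` dicts and are serialised with Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV abundance/count matrix (rows entities, header of sample ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
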