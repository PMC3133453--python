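"""Readers and writers for the interchange formats.

FASTA goes through Biopython, tabular data through pandas.  Dataset CSVs use
comma separation, UTF-8 and '.' decimals; Unicode minus signs (common in
tables copied from typeset documents) are normalized to ASCII at load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .dataset import QsarDataset
from .zscales import ZScaleTable

logger = logging.getLogger(__name__)

__all__ = ["read_fasta", "read_dataset_csv", "write_dataset_csv"]

_MINUS_VARIANTS = {ord("−"): "-", ord("–"): "-"}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (identifier, sequence) pairs from a FASTA file.

    Sequences are upper-cased; '*' stop characters are stripped with a
    warning.  An empty file is rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("record %s: stripping %d '*' stop character(s)",
                           rec.id, seq.count("*"))
            seq = seq.replace("*", "")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _normalize_minus(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object:
            cleaned = df[col].astype(str).str.translate(_MINUS_VARIANTS)
            if col == "sequence":
                df[col] = cleaned
                continue
            try:
                df[col] = pd.to_numeric(cleaned)
            except (ValueError, TypeError):
                df[col] = cleaned
    return df


def read_dataset_csv(path: str | Path,
                     table: ZScaleTable | None = None) -> QsarDataset:
    """Read a dipeptide dataset CSV (columns sequence, activity[, z11..z23]).

    Descriptor columns are used when present and complete; otherwise they
    are recomputed from the Z-scale table.  Provenance is "user".
    """
    df = _normalize_minus(pd.read_csv(path))
    return QsarDataset.from_frame(df, provenance="user", table=table)


def write_dataset_csv(dataset: QsarDataset, path: str | Path) -> None:
    dataset.to_csv(path)
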