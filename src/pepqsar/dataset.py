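"""The dipeptide activity dataset and its quality audit.

The benchmark set is 58 ACE-inhibitory dipeptides with activities expressed
as log(1/IC50) and six Z-scale descriptors each.  The printed source table
carries internal inconsistencies (a duplicated "RP" sequence, descriptor rows
that do not match their stated sequences); both the verbatim table
("as-printed") and a re-derived one ("canonical", descriptors recomputed from
the Z-scale table) are available, and :func:`validate_dataset` reports every
discrepancy instead of silently repairing it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .zscales import ZScaleTable, encode_peptide, load_zscales

DESCRIPTOR_COLUMNS = ("z11", "z12", "z13", "z21", "z22", "z23")
INPUT_LABELS = ("Z11", "Z12", "Z13", "Z21", "Z22", "Z23")

__all__ = [
    "DESCRIPTOR_COLUMNS",
    "INPUT_LABELS",
    "DipeptideRecord",
    "QsarDataset",
    "load_reference_dataset",
    "validate_dataset",
    "ValidationReport",
]


@dataclass(frozen=True)
class DipeptideRecord:
    """One dipeptide: sequence, log(1/IC50) activity, 6 Z descriptors."""

    sequence: str
    activity: float
    descriptors: tuple[float, ...]

    def __post_init__(self):
        if len(self.sequence) != 2:
            raise ValueError(f"sequence {self.sequence!r} is not a dipeptide")
        if len(self.descriptors) != 6:
            raise ValueError(
                f"{self.sequence}: expected 6 descriptors, "
                f"got {len(self.descriptors)}")
        object.__setattr__(self, "descriptors",
                           tuple(float(v) for v in self.descriptors))


@dataclass
class QsarDataset:
    """Ordered collection of dipeptide records with provenance.

    ``provenance`` is "as-printed", "canonical", "synthetic" or "user";
    ``metadata`` carries generator parameters for synthetic sets.
    """

    records: list[DipeptideRecord]
    provenance: str = "user"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> DipeptideRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def X(self) -> np.ndarray:
        """Descriptor matrix, shape (n, 6)."""
        return np.array([r.descriptors for r in self.records])

    @property
    def y(self) -> np.ndarray:
        """Activity vector log(1/IC50), shape (n,)."""
        return np.array([r.activity for r in self.records])

    def subset(self, indices: Sequence[int]) -> "QsarDataset":
        return QsarDataset([self.records[i] for i in indices],
                           provenance=self.provenance,
                           metadata=dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        rows = [(r.sequence, r.activity, *r.descriptors) for r in self.records]
        return pd.DataFrame(rows,
                            columns=["sequence", "activity",
                                     *DESCRIPTOR_COLUMNS])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "user",
                   table: ZScaleTable | None = None) -> "QsarDataset":
        """Build a dataset from a frame with at least sequence + activity.

        Descriptor columns are used when all six are present; otherwise they
        are recomputed from the Z-scale table.  Non-dipeptide sequences are
        rejected (the model is dipeptide-only).
        """
        missing = {"sequence", "activity"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        bad = [s for s in df["sequence"] if len(str(s)) != 2]
        if bad:
            raise ValueError(
                f"only dipeptides are supported; offending sequences: {bad}")
        have_desc = all(c in df.columns for c in DESCRIPTOR_COLUMNS)
        if have_desc and df[list(DESCRIPTOR_COLUMNS)].isna().any().any():
            have_desc = False
        records = []
        for row in df.itertuples():
            seq = str(row.sequence)
            if have_desc:
                desc = tuple(getattr(row, c) for c in DESCRIPTOR_COLUMNS)
            else:
                desc = tuple(encode_peptide(seq, table))
            records.append(DipeptideRecord(seq, float(row.activity), desc))
        return cls(records, provenance=provenance)


def load_reference_dataset(mode: str = "as-printed") -> QsarDataset:
    """Load the packaged 58-dipeptide ACE-inhibition benchmark.

    Parameters
    ----------
    mode : {"as-printed", "canonical"}
        "as-printed" reproduces the source table's descriptor cells verbatim,
        including its internal inconsistencies; "canonical" keeps sequences
        and activities but re-derives the descriptors from the Z-scale table.
    """
    if mode not in ("as-printed", "canonical"):
        raise ValueError(f"mode must be 'as-printed' or 'canonical', "
                         f"got {mode!r}")
    ref = resources.files("pepqsar.data").joinpath("dipeptides_as_printed.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if mode == "canonical":
        df = df[["sequence", "activity"]]
    ds = QsarDataset.from_frame(df, provenance=mode)
    if len(ds) != 58:
        raise ValueError(f"corrupted benchmark fixture: expected 58 records, "
                         f"got {len(ds)}")
    return ds


@dataclass
class ValidationReport:
    """Audit of a dataset against the canonical Z-scale encoding."""

    mismatches: list[dict]
    duplicates: list[str]

    @property
    def clean(self) -> bool:
        return not self.mismatches and not self.duplicates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mismatches)


def validate_dataset(dataset: QsarDataset,
                     table: ZScaleTable | None = None,
                     atol: float = 0.005) -> ValidationReport:
    """Compare stored descriptors against canonical encoding; find duplicates.

    Returns a report listing every record whose stored descriptors differ
    from ``encode_peptide(sequence)`` by more than ``atol`` in any entry,
    plus every sequence occurring more than once.
    """
    if table is None:
        table = load_zscales()
    mismatches = []
    for i, rec in enumerate(dataset):
        canon = encode_peptide(rec.sequence, table)
        printed = np.asarray(rec.descriptors)
        if np.any(np.abs(printed - canon) > atol):
            mismatches.append({
                "index": i,
                "sequence": rec.sequence,
                "printed": tuple(printed),
                "canonical": tuple(canon),
            })
    counts = Counter(dataset.sequences)
    duplicates = sorted(s for s, c in counts.items() if c > 1)
    return ValidationReport(mismatches=mismatches, duplicates=duplicates)
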