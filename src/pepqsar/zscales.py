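"""Z-scale amino-acid descriptors and peptide encoding.

The three Z-scales are principal-component-derived physicochemical
descriptors of the 20 standard amino acids: z1 tracks hydrophilicity
(hydrophobic residues score negative), z2 tracks size/shape, and z3
electronic properties.  A peptide of length L is encoded as the
concatenation of its residues' (z1, z2, z3) triples, N-terminal first,
giving a 3L-dimensional descriptor vector — six numbers for a dipeptide.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "ZScaleTable",
    "load_zscales",
    "encode_peptide",
    "ZScaleEncoder",
]


class ZScaleTable:
    """Mapping from 1-letter amino-acid codes to (z1, z2, z3) triples."""

    def __init__(self, entries: Mapping[str, tuple[float, float, float]]):
        self.entries = {str(k): (float(v[0]), float(v[1]), float(v[2]))
                        for k, v in entries.items()}
        for code in self.entries:
            if len(code) != 1 or not code.isalpha():
                raise ValueError(f"invalid amino-acid code {code!r}")

    def __getitem__(self, code: str) -> tuple[float, float, float]:
        return self.entries[code]

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ZScaleTable) and self.entries == other.entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, *z) for c, z in self.entries.items()],
            columns=["code", "z1", "z2", "z3"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ZScaleTable":
        df = pd.read_csv(path, comment="#")
        missing = {"code", "z1", "z2", "z3"} - set(df.columns)
        if missing:
            raise ValueError(f"Z-scale table missing columns: {sorted(missing)}")
        return cls({r.code: (r.z1, r.z2, r.z3) for r in df.itertuples()})


@functools.lru_cache(maxsize=1)
def load_zscales() -> ZScaleTable:
    """Load the packaged 20-residue Z-scale table.

    Raises
    ------
    ValueError
        If the packaged fixture is corrupted (wrong residue set).
    """
    ref = resources.files("pepqsar.data").joinpath("zscales.csv")
    with resources.as_file(ref) as path:
        table = ZScaleTable.from_csv(path)
    if set(table.entries) != set(STANDARD_AMINO_ACIDS):
        raise ValueError("packaged Z-scale table is corrupted: expected the "
                         "20 standard amino acids")
    return table


def encode_peptide(sequence: str,
                   table: ZScaleTable | None = None) -> np.ndarray:
    """Encode a peptide as concatenated per-residue Z-scale triples.

    Parameters
    ----------
    sequence : str
        1-letter-code peptide, N-terminal first.
    table : ZScaleTable, optional
        Descriptor table; defaults to the packaged Z-scales.

    Returns
    -------
    numpy.ndarray of shape (3 * len(sequence),)
    """
    if table is None:
        table = load_zscales()
    if len(sequence) == 0:
        raise ValueError("cannot encode an empty peptide")
    out = np.empty(3 * len(sequence))
    for i, code in enumerate(sequence):
        if code not in table:
            raise ValueError(
                f"unknown residue code {code!r} at position {i + 1} "
                f"in sequence {sequence!r}")
        out[3 * i:3 * i + 3] = table[code]
    return out


class ZScaleEncoder(BaseEstimator, TransformerMixin):
    """Transformer turning equal-length peptide strings into Z-scale matrices.

    Stateless apart from the descriptor table; ``fit`` only records the
    peptide length so that ``transform`` can reject ragged input.
    """

    def __init__(self, table: ZScaleTable | None = None):
        self.table = table

    def fit(self, X: Sequence[str], y=None):
        seqs = list(X)
        if not seqs:
            raise ValueError("empty sequence collection")
        self.peptide_length_ = len(seqs[0])
        self.n_features_out_ = 3 * self.peptide_length_
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        table = self.table if self.table is not None else load_zscales()
        rows = []
        for seq in X:
            if len(seq) != self.peptide_length_:
                raise ValueError(
                    f"sequence {seq!r} has length {len(seq)}, "
                    f"expected {self.peptide_length_}")
            rows.append(encode_peptide(seq, table))
        return np.asarray(rows)
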