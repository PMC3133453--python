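"""Bundled QSAR model: trained network + the normalization it expects.

A network is only meaningful together with the min-max scale its inputs and
target were trained on, so persistence and prediction go through this pair.
The JSON round-trip is exact (weights stored at full double precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import BPNetwork, forward
from .preprocessing import NormalizationParams
from .zscales import ZScaleTable, encode_peptide

__all__ = ["QsarModel"]


@dataclass
class QsarModel:
    """A trained dipeptide-activity predictor."""

    network: BPNetwork
    normalizer: NormalizationParams
    meta: dict = field(default_factory=dict)

    def predict_normalized(self, X: np.ndarray) -> np.ndarray:
        """Predict on already-normalized descriptor rows."""
        return np.atleast_1d(forward(self.network, np.asarray(X, float)))

    def predict_activity(self, sequences,
                         table: ZScaleTable | None = None) -> np.ndarray:
        """Predict log(1/IC50) for peptide sequences on the raw scale."""
        if isinstance(sequences, str):
            sequences = [sequences]
        X = np.array([encode_peptide(s, table) for s in sequences])
        if X.shape[1] != self.normalizer.n_features:
            raise ValueError("peptide descriptor length does not match the "
                             "model's input size")
        yn = self.predict_normalized(self.normalizer.transform_X(X))
        return self.normalizer.inverse_transform_y(yn)

    def to_dict(self) -> dict:
        return {"network": self.network.to_dict(),
                "normalizer": self.normalizer.to_dict(),
                "meta": self.meta}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "QsarModel":
        return cls(network=BPNetwork.from_dict(d["network"]),
                   normalizer=NormalizationParams.from_dict(d["normalizer"]),
                   meta=d.get("meta", {}))

    @classmethod
    def load(cls, path: str | Path) -> "QsarModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
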