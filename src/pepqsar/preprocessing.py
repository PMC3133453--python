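"""Min-max normalization of descriptors and activities.

Every feature (and, by default, the activity target) is rescaled to [0, 1]
by z' = (z - z_min) / (z_max - z_min), with the extrema taken over the
fitting population.  The network trains on the normalized scale; predictions
are mapped back with the exact inverse.  Values outside the fitted range are
passed through (they land outside [0, 1]) and logged, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import INPUT_LABELS, DipeptideRecord, QsarDataset

logger = logging.getLogger(__name__)

__all__ = ["NormalizationParams", "fit_normalizer", "apply_normalizer"]


@dataclass
class NormalizationParams:
    """Fitted per-feature (and optional target) minima and maxima."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float | None = None
    y_max: float | None = None
    feature_names: tuple[str, ...] = field(default=INPUT_LABELS)

    def __post_init__(self):
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max shapes differ")
        if np.any(self.x_max < self.x_min):
            raise ValueError("feature maximum below minimum")

    @property
    def n_features(self) -> int:
        return self.x_min.shape[0]

    @property
    def normalizes_target(self) -> bool:
        return self.y_min is not None

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature-count mismatch: got {X.shape[1]}, "
                f"normalizer fitted on {self.n_features}")
        out = (X - self.x_min) / (self.x_max - self.x_min)
        if np.any(out < 0) or np.any(out > 1):
            logger.info("normalized values fall outside [0, 1] "
                        "(input outside the fitted range); passed through")
        return out

    def inverse_transform_X(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        return Xn * (self.x_max - self.x_min) + self.x_min

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        if not self.normalizes_target:
            return np.asarray(y, dtype=float)
        return (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def inverse_transform_y(self, yn: np.ndarray) -> np.ndarray:
        if not self.normalizes_target:
            return np.asarray(yn, dtype=float)
        return np.asarray(yn, dtype=float) * (self.y_max - self.y_min) + self.y_min

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(x_min=np.asarray(d["x_min"]), x_max=np.asarray(d["x_max"]),
                   y_min=d.get("y_min"), y_max=d.get("y_max"),
                   feature_names=tuple(d.get("feature_names", INPUT_LABELS)))


def fit_normalizer(dataset: QsarDataset,
                   include_target: bool = True) -> NormalizationParams:
    """Fit per-feature min/max over all records of ``dataset``.

    Raises if any feature is constant (max == min), since the rescaling
    would be degenerate.
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    X, y = dataset.X, dataset.y
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    names = INPUT_LABELS if X.shape[1] == 6 else tuple(
        f"x{i}" for i in range(X.shape[1]))
    constant = np.nonzero(x_max == x_min)[0]
    if constant.size:
        raise ValueError("constant feature(s) cannot be normalized: "
                         + ", ".join(names[i] for i in constant))
    y_min = y_max = None
    if include_target:
        y_min, y_max = float(y.min()), float(y.max())
        if y_max == y_min:
            raise ValueError("constant activity target cannot be normalized")
    return NormalizationParams(x_min=x_min, x_max=x_max,
                               y_min=y_min, y_max=y_max, feature_names=names)


def apply_normalizer(params: NormalizationParams,
                     data: QsarDataset | DipeptideRecord):
    """Return a normalized copy of a dataset or a single record."""
    if isinstance(data, DipeptideRecord):
        desc = params.transform_X(np.asarray(data.descriptors))[0]
        act = float(params.transform_y(np.asarray([data.activity]))[0])
        return DipeptideRecord(data.sequence, act, tuple(desc))
    records = [apply_normalizer(params, r) for r in data]
    return QsarDataset(records, provenance=data.provenance,
                       metadata=dict(data.metadata))
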