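"""Back-stepping connection-weight analysis of a trained network.

The procedure reads influence directly off the weight tables, in two steps:

1. rank hidden neurons by the magnitude of their hidden->output weight
   ``lw_j`` — a large |lw_j| means neuron j moves the predicted activity
   strongly;
2. for the top-k neurons, rank inputs by their incoming weights.  The
   qualitative "observe the weights" step is made quantitative here by the
   aggregate score

       score(i) = sum over selected j of |lw_j * iw_{j,i}|,

   i.e. the total unsigned strength of the input->hidden->output paths
   through the selected neurons.  With k = hidden_size this is the classic
   Garson-style unsigned connection-weight ranking (without per-neuron
   normalization).

Scores are on the normalized-input weight scale (the network consumes
min-max-normalized descriptors).  All human-facing indices are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .dataset import INPUT_LABELS
from .network import BPNetwork

__all__ = [
    "ImportanceReport",
    "SignSummary",
    "select_hidden",
    "backstep_importance",
    "sign_analysis",
    "load_reference_network",
]


def _input_labels(network: BPNetwork) -> tuple[str, ...]:
    if network.input_size == 6:
        return INPUT_LABELS
    if network.input_size % 3 == 0:
        return tuple(f"Z{m}{n}" for m in range(1, network.input_size // 3 + 1)
                     for n in (1, 2, 3))
    return tuple(f"x{i + 1}" for i in range(network.input_size))


def _check_k_top(network: BPNetwork, k_top: int) -> None:
    if not 1 <= k_top <= network.hidden_size:
        raise ValueError(f"k_top must be in [1, {network.hidden_size}], "
                         f"got {k_top}")


def select_hidden(network: BPNetwork, k_top: int) -> list[tuple[int, float]]:
    """The k_top hidden neurons with the largest |hidden->output weight|.

    Returns (1-based index, signed weight) pairs in descending magnitude
    order; ties broken toward the lower index.
    """
    _check_k_top(network, k_top)
    order = sorted(range(network.hidden_size),
                   key=lambda j: (-abs(network.lw[j]), j))
    return [(j + 1, float(network.lw[j])) for j in order[:k_top]]


@dataclass
class ImportanceReport:
    """Ranked per-input influence from the back-stepping procedure."""

    selected_hidden: list[tuple[int, float]]
    input_scores: dict[str, float]
    ranking: list[str]
    k_top: int
    weight_table: list[list[float]] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {"selected_hidden": self.selected_hidden,
                "input_scores": self.input_scores,
                "ranking": self.ranking,
                "k_top": self.k_top,
                "weight_table": self.weight_table}

    def format_table(self) -> str:
        """Input->hidden weight table, selected neurons flagged with '*'."""
        labels = list(self.input_scores)
        sel = {j for j, _ in self.selected_hidden}
        lines = ["neuron  " + "  ".join(f"{l:>9s}" for l in labels)]
        for j, row in enumerate(self.weight_table, start=1):
            mark = "*" if j in sel else " "
            lines.append(f"({j}){mark:>3s} "
                         + "  ".join(f"{v:9.5f}" for v in row))
        lines.append("score   "
                     + "  ".join(f"{self.input_scores[l]:9.5f}"
                                 for l in labels))
        lines.append("ranking: " + " > ".join(self.ranking))
        return "\n".join(lines)


def backstep_importance(network: BPNetwork, k_top: int = 2
                        ) -> ImportanceReport:
    """Aggregate input influence through the top-k hidden neurons.

    score(i) = sum_j |lw_j * iw_{j,i}| over the selected neurons j; the
    ranking sorts inputs by descending score, ties toward the lower index.
    """
    selected = select_hidden(network, k_top)
    labels = _input_labels(network)
    scores = np.zeros(network.input_size)
    for j1, w in selected:
        scores += np.abs(w * network.iw[j1 - 1])
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], i))
    return ImportanceReport(
        selected_hidden=selected,
        input_scores={labels[i]: float(scores[i]) for i in range(len(labels))},
        ranking=[labels[i] for i in order],
        k_top=k_top,
        weight_table=network.iw.tolist(),
    )


@dataclass
class SignSummary:
    """Signed input->hidden->output products for one input."""

    input_label: str
    per_neuron: list[tuple[int, float, int]]  # (hidden idx, product, sign)
    signed_sum: float

    @property
    def direction(self) -> str:
        """Net effect of increasing this (normalized) input on activity."""
        if self.signed_sum > 0:
            return "increases"
        if self.signed_sum < 0:
            return "decreases"
        return "neutral"


def sign_analysis(network: BPNetwork, input_index, k_top: int = 2
                  ) -> SignSummary:
    """Signs of lw_j * iw_{j,i} over the selected hidden neurons.

    ``input_index`` may be a label ("Z21") or a 1-based integer index.
    A positive signed sum means increasing that normalized input increases
    the predicted activity (to first order through the selected paths).
    """
    labels = _input_labels(network)
    if isinstance(input_index, str):
        if input_index not in labels:
            raise ValueError(f"unknown input label {input_index!r}; "
                             f"expected one of {labels}")
        i = labels.index(input_index)
    else:
        if not 1 <= int(input_index) <= network.input_size:
            raise ValueError(f"input index out of range: {input_index}")
        i = int(input_index) - 1
    per = []
    total = 0.0
    for j1, w in select_hidden(network, k_top):
        prod = float(w * network.iw[j1 - 1, i])
        per.append((j1, prod, int(np.sign(prod))))
        total += prod
    return SignSummary(input_label=labels[i], per_neuron=per,
                       signed_sum=total)


def load_reference_network() -> BPNetwork:
    """The packaged reference 6-7-1 trained-weight tables.

    Biases in the fixture are zero (unknown in the source tables); the
    network supports the interpretation procedure only and is not a usable
    predictor.
    """
    ref = resources.files("pepqsar.data").joinpath("reference_weights.json")
    return BPNetwork.from_dict(json.loads(ref.read_text()))
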