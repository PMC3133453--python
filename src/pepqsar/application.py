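"""Applied layer: substrate composition analysis and protease screening.

A protein rich in hydrophobic residues is a promising substrate for
ACE-inhibitory peptide production, because dipeptides with a hydrophobic
C-terminal residue tend to have high activity.  This module quantifies
hydrophobic/aromatic content of a protein (from a composition table or a
sequence), encodes protease C-terminal specificities, enumerates the
candidate dipeptides a protease could expose, and ranks proteases by the
QSAR-predicted activity of those candidates.

The digestion model is deliberately minimal: a protease with C-terminal
preference set S can expose any adjacent residue pair (i, i+1) whose second
residue is in S.  No cleavage kinetics are modelled — this is an
illustration layer for prioritizing enzymes, not a hydrolysis simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_weights

from .model import QsarModel
from .zscales import STANDARD_AMINO_ACIDS

logger = logging.getLogger(__name__)

WATER_MASS = 18.0153  # average mass lost per peptide bond

# Hydrophobic set reproducing the wheat-germ composition class totals under
# printed rounding; aromatic = F, Y, W.
HYDROPHOBIC_RESIDUES = frozenset("AVLIPFMWY")
AROMATIC_RESIDUES = frozenset("FYW")

__all__ = [
    "ProteinComposition",
    "ResidueClassSet",
    "ProteaseSpec",
    "DigestRanking",
    "HYDROPHOBIC_RESIDUES",
    "AROMATIC_RESIDUES",
    "load_dwgp_composition",
    "class_fraction",
    "composition_from_sequence",
    "builtin_protease_specs",
    "candidate_dipeptides",
    "rank_proteases",
]


@dataclass
class ProteinComposition:
    """Residue -> g per 100 g protein.

    Keys are 1-letter codes or combined labels like "D+N" (Asx) and "E+Q"
    (Glx) when an analysis cannot distinguish the amide pair.
    """

    content: dict[str, float]

    def __post_init__(self):
        for k, v in self.content.items():
            if v < 0:
                raise ValueError(f"negative content for {k}: {v}")

    def combined_members(self) -> set[str]:
        out = set()
        for key in self.content:
            if "+" in key:
                out.update(key.split("+"))
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProteinComposition":
        df = pd.read_csv(path)
        missing = {"residue", "g_per_100g"} - set(df.columns)
        if missing:
            raise ValueError(f"composition CSV missing columns: "
                             f"{sorted(missing)}")
        return cls({str(r.residue): float(r.g_per_100g)
                    for r in df.itertuples()})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.content.items()),
                     columns=["residue", "g_per_100g"]).to_csv(path,
                                                               index=False)


@dataclass(frozen=True)
class ResidueClassSet:
    """A named residue class, e.g. the hydrophobic amino acids."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("residue class must be non-empty")
        bad = set(self.members) - set(STANDARD_AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residue codes in class "
                             f"{self.name!r}: {sorted(bad)}")
        object.__setattr__(self, "members", frozenset(self.members))


def load_dwgp_composition() -> ProteinComposition:
    """Packaged amino-acid composition of defatted wheat germ protein
    isolate (g/100 g protein), with combined Asx and Glx entries."""
    ref = resources.files("pepqsar.data").joinpath("dwgp_composition.csv")
    with resources.as_file(ref) as path:
        return ProteinComposition.from_csv(path)


def class_fraction(composition: ProteinComposition,
                   class_set: ResidueClassSet) -> float:
    """Summed content (g/100 g) of the class members present.

    Members hidden inside combined entries (e.g. N inside "D+N") cannot be
    attributed and are excluded with a log message.
    """
    combined = composition.combined_members()
    total = 0.0
    for code in sorted(class_set.members):
        if code in composition.content:
            total += composition.content[code]
        elif code in combined:
            logger.info("class %s: residue %s only present in a combined "
                        "entry; excluded from the sum", class_set.name, code)
    return total


def composition_from_sequence(sequence: str) -> ProteinComposition:
    """Mass-fraction composition of a protein sequence.

    Residue masses are average (not monoisotopic) amino-acid masses minus
    one water; fractions are normalized to sum to 100.
    """
    sequence = sequence.upper()
    bad = sorted({c for c in sequence if c not in STANDARD_AMINO_ACIDS})
    if bad:
        raise ValueError(f"unknown residue codes: {bad}")
    if not sequence:
        raise ValueError("empty sequence")
    masses = {}
    for code in set(sequence):
        masses[code] = protein_weights[code] - WATER_MASS
    total = sum(sequence.count(c) * masses[c] for c in masses)
    return ProteinComposition({
        c: 100.0 * sequence.count(c) * masses[c] / total for c in masses})


@dataclass(frozen=True)
class ProteaseSpec:
    """A protease's tendency to leave certain residues at peptide C-termini."""

    name: str
    c_terminal_preference: frozenset[str]
    note: str = ""

    def __post_init__(self):
        if not self.c_terminal_preference:
            raise ValueError("preference set must be non-empty")
        bad = set(self.c_terminal_preference) - set(STANDARD_AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residue codes for {self.name!r}: "
                             f"{sorted(bad)}")
        object.__setattr__(self, "c_terminal_preference",
                           frozenset(self.c_terminal_preference))

    @classmethod
    def from_csv(cls, path: str | Path) -> list["ProteaseSpec"]:
        """Read specs from CSV columns name, preference (residue string)."""
        df = pd.read_csv(path)
        missing = {"name", "preference"} - set(df.columns)
        if missing:
            raise ValueError(f"protease CSV missing columns: "
                             f"{sorted(missing)}")
        return [cls(str(r.name), frozenset(str(r.preference)))
                for r in df.itertuples(index=False)]


def builtin_protease_specs() -> list[ProteaseSpec]:
    """C-terminal specificity fixtures for four candidate proteases.

    The source descriptions use the ambiguous abbreviation "Try"; it is read
    as Trp where Tyr is separately listed in the same description and as Tyr
    where Trp is, as documented in each spec's note.  Override via CSV for
    other readings.
    """
    return [
        ProteaseSpec("Neutrase", frozenset("YWF"),
                     note="hydrophobic C-termini: Tyr, Trp ('Try'), Phe"),
        ProteaseSpec("Alcalase", frozenset("ILVMFYW"),
                     note="large uncharged side chains: Ile, Leu, Val, Met, "
                          "Phe, Tyr, Trp"),
        ProteaseSpec("Proteinase K", frozenset("FYVILWPM"),
                     note="Phe, Tyr ('Try'), Val, Ile, Leu, Trp, Pro, Met"),
        ProteaseSpec("Chymotrypsin C", frozenset("YLWPMEK"),
                     note="Tyr ('Try'), Leu, Trp, Pro, Met, Glu, Lys"),
    ]


@dataclass(frozen=True)
class DipeptideCandidate:
    sequence: str
    position: int  # 1-based position of the first residue in the protein


def candidate_dipeptides(sequence: str,
                         spec: ProteaseSpec) -> list[DipeptideCandidate]:
    """Adjacent residue pairs whose C-terminal residue the protease favours.

    Models "the protease can expose this residue as a C-terminus"; duplicate
    dipeptides are retained, each with its position.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    return [DipeptideCandidate(sequence[i:i + 2], i + 1)
            for i in range(len(sequence) - 1)
            if sequence[i + 1] in spec.c_terminal_preference]


@dataclass
class ProteaseDigest:
    """Scored candidates for one protease."""

    name: str
    candidates: list[DipeptideCandidate]
    predicted: list[float]

    @property
    def count(self) -> int:
        return len(self.candidates)

    @property
    def mean_activity(self) -> float:
        return float(np.mean(self.predicted)) if self.predicted else float("nan")

    @property
    def max_activity(self) -> float:
        return float(np.max(self.predicted)) if self.predicted else float("nan")


@dataclass
class DigestRanking:
    """Proteases ordered by a summary of predicted candidate activity."""

    digests: list[ProteaseDigest]       # ordered, best first
    excluded: list[str]                 # proteases with no candidates
    summary: str = "mean"

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "excluded": self.excluded,
            "ranking": [{
                "protease": d.name,
                "count": d.count,
                "mean_activity": d.mean_activity,
                "max_activity": d.max_activity,
                "candidates": [{"sequence": c.sequence,
                                "position": c.position,
                                "predicted_activity": p}
                               for c, p in zip(d.candidates, d.predicted)],
            } for d in self.digests],
        }


def rank_proteases(sequence: str, specs: list[ProteaseSpec],
                   model: QsarModel, summary: str = "mean") -> DigestRanking:
    """Score each protease's candidate dipeptides with the QSAR model.

    Proteases are ordered by ``summary`` ("mean" or "max") of predicted
    log(1/IC50) over their candidates, descending; name breaks ties so the
    ordering is independent of the input order of ``specs``.  Proteases with
    no candidate are excluded from the ordering and listed separately.
    """
    if summary not in ("mean", "max"):
        raise ValueError("summary must be 'mean' or 'max'")
    digests, excluded = [], []
    for spec in specs:
        cands = candidate_dipeptides(sequence, spec)
        if not cands:
            excluded.append(spec.name)
            continue
        preds = model.predict_activity([c.sequence for c in cands])
        digests.append(ProteaseDigest(spec.name, cands, preds.tolist()))
    key = (lambda d: (-d.mean_activity, d.name)) if summary == "mean" \
        else (lambda d: (-d.max_activity, d.name))
    digests.sort(key=key)
    return DigestRanking(digests=digests, excluded=sorted(excluded),
                         summary=summary)
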