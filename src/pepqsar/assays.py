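"""Wet-lab-side calculators: degree of hydrolysis and ACE inhibition.

Degree of hydrolysis by the pH-stat method: during proteolysis the newly
exposed alpha-amino groups release protons, and the base volume needed to
hold the pH measures the number of cleaved bonds,

    DH (%) = (V_NaOH * N_NaOH) / (alpha * M_p * h_tot) * 100,
    alpha  = 10^(pH - pK) / (1 + 10^(pH - pK)),

with V_NaOH in mL, N_NaOH in mol/L (so the numerator is mmol of base), M_p
the protein mass in g, h_tot the total peptide bonds per gram of protein in
mmol/g (7.69 for wheat germ protein), and pK the average alpha-amino pK
(9.0).  Average peptide chain length follows as PLC = 100 / DH.

ACE inhibition from the chromogenic FAPGG assay at 340 nm: with blank
absorbance decrease A = a1 - a2 and sample decrease B = b1 - b2, the
inhibition is I = (A - B) / A.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

WHEAT_GERM_H_TOT = 7.69   # mmol peptide bonds per g protein
DEFAULT_PK = 9.0          # average alpha-amino pK

__all__ = [
    "DHParams",
    "AssayReading",
    "alpha_dissociation",
    "degree_of_hydrolysis",
    "average_chain_length",
    "ace_inhibition",
    "WHEAT_GERM_H_TOT",
    "DEFAULT_PK",
]


@dataclass(frozen=True)
class DHParams:
    """Inputs to the pH-stat degree-of-hydrolysis formula."""

    v_naoh: float                      # titrant volume, mL
    n_naoh: float                      # titrant concentration, mol/L
    m_protein: float                   # protein mass, g
    h_tot: float = WHEAT_GERM_H_TOT    # peptide bonds, mmol/g
    ph: float = 8.0                    # reaction pH
    pk: float = DEFAULT_PK             # average amino-group pK

    def __post_init__(self):
        for name in ("v_naoh", "n_naoh", "m_protein", "h_tot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AssayReading:
    """340 nm absorbances of the FAPGG ACE-inhibition assay."""

    blank_initial: float   # a1
    blank_final: float     # a2
    sample_initial: float  # b1
    sample_final: float    # b2

    def __post_init__(self):
        vals = (self.blank_initial, self.blank_final,
                self.sample_initial, self.sample_final)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("absorbances must be finite")


def alpha_dissociation(ph: float, pk: float = DEFAULT_PK) -> float:
    """Dissociation degree of alpha-amino groups, in (0, 1).

    alpha = 10^(pH-pK) / (1 + 10^(pH-pK)); strictly increasing in pH and
    equal to 0.5 at pH = pK.
    """
    if not (math.isfinite(ph) and math.isfinite(pk)):
        raise ValueError("ph and pk must be finite")
    t = ph - pk
    # logistic in base-10 units; evaluate in the numerically safe branch
    if t >= 0:
        return 1.0 / (1.0 + 10.0 ** (-t))
    u = 10.0 ** t
    return u / (1.0 + u)


def degree_of_hydrolysis(params: DHParams) -> float:
    """Degree of hydrolysis (%) by pH-stat base consumption.

    mL x mol/L gives mmol of base, matching h_tot in mmol/g; the result is
    linear in v_naoh and inversely proportional to m_protein.
    """
    if params.m_protein <= 0 or params.h_tot <= 0:
        raise ValueError("m_protein and h_tot must be > 0")
    alpha = alpha_dissociation(params.ph, params.pk)
    if alpha <= 0:
        raise ValueError("alpha-dissociation degree is zero at this pH; "
                         "the pH-stat method cannot resolve DH")
    return (params.v_naoh * params.n_naoh) / (
        alpha * params.m_protein * params.h_tot) * 100.0


def average_chain_length(dh: float) -> float:
    """Average peptide chain length in residues, PLC = 100 / DH(%)."""
    if dh <= 0:
        raise ValueError("DH must be > 0")
    return 100.0 / dh


def ace_inhibition(reading: AssayReading) -> float:
    """ACE-inhibition fraction I = (A - B) / A.

    A = a1 - a2 (blank decrease) must be positive for a valid assay.  The
    result depends only on the two decreases A and B; negative values
    (sample accelerates the reaction) are reported as-is with a warning.
    """
    a = reading.blank_initial - reading.blank_final
    b = reading.sample_initial - reading.sample_final
    if a <= 0:
        raise ValueError("invalid blank: absorbance decrease A = a1 - a2 "
                         "must be > 0")
    i = (a - b) / a
    if i < 0:
        logger.warning("negative inhibition (%.4f): sample absorbance fell "
                       "faster than the blank", i)
    return i
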