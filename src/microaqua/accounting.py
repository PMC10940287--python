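"""Stoichiometry and process metrics for intensified biocatalytic cascades.

Covers the bookkeeping side of a decarboxylation/acylation campaign: molar
masses from elemental formulas, the specific catalyst productivity used to
rank all-in runs, product titres, and crude isolated yields.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import DomainError, ParseError

# IUPAC 2021 standard atomic weights, 5 significant figures.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Na": 22.990,
    "Cl": 35.45,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of an elemental formula such as ``C10H10O4``.

    Supports the elements relevant to this chemistry (C, H, N, O, S, Na, Cl).

    Raises
    ------
    ParseError
        If the formula contains an unknown element or stray characters.
    """
    if not formula:
        raise ParseError("empty formula")
    mass = 0.0
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ParseError(f"cannot parse formula {formula!r} at position {pos}")
        element, count = m.group(1), m.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise ParseError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula):
        raise ParseError(f"cannot parse formula {formula!r} at position {pos}")
    return mass


@dataclass(frozen=True)
class ReactionRecord:
    """One batch reaction: substrate loading, outcome, and catalyst dose.

    Parameters
    ----------
    substrate_conc : float
        Nominal substrate concentration in mol/L of reaction volume.
    conversion : float
        Fractional conversion achieved, in [0, 1].
    catalyst_loading : float
        Immobilized-catalyst bead loading in g/L.
    time_h : float
        Elapsed reaction time in hours.
    """

    substrate_conc: float
    conversion: float
    catalyst_loading: float
    time_h: float

    def __post_init__(self):
        if min(self.substrate_conc, self.conversion, self.catalyst_loading, self.time_h) < 0:
            raise DomainError("reaction record fields must be non-negative")
        if self.conversion > 1:
            raise DomainError("conversion is a fraction in [0, 1]")


def specific_productivity(rec: ReactionRecord) -> float:
    """Specific catalyst productivity in mmol_product · g_cat⁻¹ · h⁻¹.

    Product formed per gram of immobilized catalyst per hour:
    ``1000 · c_S · X / (loading · t)``.
    """
    if rec.catalyst_loading <= 0 or rec.time_h <= 0:
        raise DomainError("catalyst loading and time must be positive")
    return 1000.0 * rec.substrate_conc * rec.conversion / (rec.catalyst_loading * rec.time_h)


def titre(concentration: float, molar_mass_g_mol: float) -> float:
    """Product titre in g/L from a molar concentration (mol/L)."""
    return concentration * molar_mass_g_mol


def percent_yield(crude_mass_mg: float, theoretical_mmol: float, molar_mass_g_mol: float) -> float:
    """Crude isolated yield in percent.

    May exceed 100 for impure crudes (co-isolated acid or grease), as is
    common for screening-scale workups.
    """
    if theoretical_mmol <= 0:
        raise DomainError("theoretical amount must be positive")
    return 100.0 * crude_mass_mg / (theoretical_mmol * molar_mass_g_mol)
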