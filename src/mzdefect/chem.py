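"""Monoisotopic mass arithmetic, molecular formulas, and the mass defect.

The mass defect used throughout this package is the fractional (decimal)
part of an observed m/z after its nominal (integer) mass: ``mz - floor(mz)``.
Under this convention heavy-for-their-nominal-mass ions such as Na/K-Cl
salt clusters carry defects near 0.9 and sit far above the defect ceiling
of CHNO compounds, which is what the threshold filter exploits.

Element masses are monoisotopic (most abundant isotope) values taken from
the NIST table shipped with :mod:`pyteomics`; carbon is exactly 12 by
definition of the unified atomic mass unit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from pyteomics import mass as _pt_mass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MONOISOTOPIC",
    "MolecularFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "mass_defect",
]

#: Rest mass of the electron in Da.
ELECTRON_MASS: float = _pt_mass.nist_mass["e*"][0][0]

_ELEMENTS = (
    "H", "C", "N", "O", "Na", "K", "Cl", "S", "P", "I",
    # extras commonly seen in adduct/fragment chemistry
    "F", "Br", "Si", "Se",
)

#: Element symbol -> monoisotopic mass (Da).
MONOISOTOPIC: dict[str, float] = {el: _pt_mass.nist_mass[el][0][0] for el in _ELEMENTS}

#: Mass of H+ (a bare proton): hydrogen atom minus one electron.
PROTON_MASS: float = MONOISOTOPIC["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised when a molecular-formula string cannot be parsed."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element->count map plus a net integer charge.

    ``charge`` is the signed net charge of the species; the electron
    deficit/excess it implies is accounted for in
    :func:`monoisotopic_mass`.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n}
        if not clean:
            raise FormulaError("formula must contain at least one element")
        if any(n < 0 for n in clean.values()):
            raise FormulaError(f"negative element count in {dict(self.counts)!r}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "MolecularFormula":
        return parse_formula(text, charge=charge)

    def __str__(self) -> str:
        # Hill order: C, H, then remaining symbols alphabetically.
        parts = []
        for el in sorted(self.counts, key=lambda e: (e != "C", e != "H", e)):
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged, self.charge + other.charge)

    def mass(self, masses: Mapping[str, float] | None = None) -> float:
        return monoisotopic_mass(self, masses)


def parse_formula(text: str, charge: int = 0) -> MolecularFormula:
    """Parse ``"C6H12O6"``-style text into a :class:`MolecularFormula`.

    Counts for repeated symbols accumulate; an omitted count means 1.
    Malformed input raises :class:`FormulaError` naming the position of
    the offending character.
    """
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"cannot parse formula {text!r}: unexpected character "
                f"{text[pos]!r} at position {pos}"
            )
        symbol, digits = m.group(1), m.group(2)
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts, charge)


def monoisotopic_mass(
    formula: MolecularFormula | str,
    masses: Mapping[str, float] | None = None,
) -> float:
    """Exact monoisotopic mass of a (possibly charged) species in Da.

    For charged species the electron deficit is subtracted
    (``- charge * m_e``), so the return value is the m/z numerator before
    division by ``|charge|``.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = MONOISOTOPIC if masses is None else masses
    total = 0.0
    for el, n in formula.counts.items():
        try:
            total += n * table[el]
        except KeyError:
            raise ValueError(f"unknown element symbol {el!r} in formula") from None
    return total - formula.charge * ELECTRON_MASS


def mass_defect(mz):
    """Fractional part of m/z after the nominal (integer) mass.

    Accepts a scalar or array; always in ``[0, 1)``. Non-positive m/z is
    rejected — an observed m/z below 0 has no nominal-mass reading.
    """
    arr = np.asarray(mz, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("m/z values must be positive")
    defect = arr - np.floor(arr)
    if np.isscalar(mz) or arr.ndim == 0:
        return float(defect)
    return defect
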