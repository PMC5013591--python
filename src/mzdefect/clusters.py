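"""Enumeration and annotation of electrospray salt-cluster ions.

Plasma electrospray data is rich in non-covalent aggregates of sodium
and/or potassium cations with chloride and/or formate anions, e.g.
[Na2Cl]+ or [K3Cl2]+. Because Cl, Na, K and O are heavy relative to
their nominal masses, these ions carry mass defects near 0.9 — far above
anything CHNO metabolites can reach — which is what makes them
enumerable and filterable. Ammonium and acetate building blocks, seen
in some buffer systems, are available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ELECTRON_MASS, MONOISOTOPIC, mass_defect, monoisotopic_mass, parse_formula
from .threshold import DEFAULT_DOMAIN

__all__ = [
    "ClusterUnit",
    "ClusterComposition",
    "DEFAULT_CATIONS",
    "DEFAULT_ANIONS",
    "OPTIONAL_CATIONS",
    "OPTIONAL_ANIONS",
    "enumerate_clusters",
    "annotate_features",
    "clusters_to_frame",
]


@dataclass(frozen=True)
class ClusterUnit:
    """One salt building block: a +1 cation or -1 anion."""

    symbol: str
    formula: str
    sign: int  # +1 cation, -1 anion

    def mass(self, masses: Mapping[str, float] | None = None) -> float:
        """Neutral-atom mass of the unit's formula (charge handled at the ion level)."""
        return monoisotopic_mass(parse_formula(self.formula), masses)


DEFAULT_CATIONS = (
    ClusterUnit("Na", "Na", +1),
    ClusterUnit("K", "K", +1),
)
DEFAULT_ANIONS = (
    ClusterUnit("Cl", "Cl", -1),
    ClusterUnit("HCOO", "CHO2", -1),
)
OPTIONAL_CATIONS = (ClusterUnit("NH4", "NH4", +1),)
OPTIONAL_ANIONS = (ClusterUnit("CH3COO", "C2H3O2", -1),)


@dataclass(frozen=True)
class ClusterComposition:
    """A specific salt-cluster ion: unit counts, net charge, m/z and defect."""

    units: Mapping[str, int]  # unit symbol -> count
    charge: int  # signed net charge
    mz: float
    defect: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", dict(self.units))

    @property
    def total_units(self) -> int:
        return sum(self.units.values())

    @property
    def label(self) -> str:
        body = "".join(
            f"({sym})" + (str(n) if n > 1 else "") if len(sym) > 2 else sym + (str(n) if n > 1 else "")
            for sym, n in sorted(self.units.items())
            if n
        )
        sign = "+" if self.charge > 0 else "-"
        mag = abs(self.charge)
        return f"[{body}]{mag if mag > 1 else ''}{sign}"

    def __str__(self) -> str:
        return f"{self.label} m/z={self.mz:.5f} defect={self.defect:.5f}"


def enumerate_clusters(
    domain: tuple[float, float] = DEFAULT_DOMAIN,
    polarity: str = "+",
    max_units: int = 12,
    cations: Sequence[ClusterUnit] = DEFAULT_CATIONS,
    anions: Sequence[ClusterUnit] = DEFAULT_ANIONS,
    charge_magnitude: int = 1,
    masses: Mapping[str, float] | None = None,
) -> list[ClusterComposition]:
    """All charge-balanced salt clusters with m/z inside ``domain``.

    A composition is kept when (cation count) - (anion count) equals the
    signed charge, the total unit count is between 2 and ``max_units``,
    and its m/z lies inside ``domain``. Results are sorted by m/z with no
    duplicate compositions.

    ``max_units`` defaults to 12: beyond roughly a dozen Cl/K-heavy units
    the accumulated per-unit defects wrap past the next nominal mass,
    producing mid-defect compositions that leave genuine salt-cluster
    space (and are not observed as cluster series in plasma data).
    """
    if polarity not in "+-":
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    if max_units < 2:
        raise ValueError("max_units must be >= 2")
    if charge_magnitude < 1:
        raise ValueError("charge_magnitude must be >= 1")
    lo, hi = domain
    if not lo < hi:
        raise ValueError(f"empty m/z domain {domain!r}")

    charge = charge_magnitude if polarity == "+" else -charge_magnitude
    unit_masses = {u.symbol: u.mass(masses) for u in (*cations, *anions)}
    cat_syms = [u.symbol for u in cations]
    an_syms = [u.symbol for u in anions]

    out: list[ClusterComposition] = []
    seen: set[tuple] = set()
    for n_cat_total in range(0, max_units + 1):
        n_an_total = n_cat_total - charge
        if n_an_total < 0 or n_cat_total + n_an_total > max_units:
            continue
        if n_cat_total + n_an_total < 2:
            continue
        for cat_split in _compositions(n_cat_total, len(cat_syms)):
            for an_split in _compositions(n_an_total, len(an_syms)):
                units = {s: c for s, c in zip(cat_syms, cat_split) if c}
                units.update({s: c for s, c in zip(an_syms, an_split) if c})
                key = tuple(sorted(units.items()))
                if key in seen:
                    continue
                seen.add(key)
                total_mass = sum(unit_masses[s] * c for s, c in units.items())
                # units are stored as neutral atoms/radicals; the ion is the
                # assembly minus `charge` electrons
                ion_mass = total_mass - charge * ELECTRON_MASS
                mz = ion_mass / charge_magnitude
                if lo <= mz <= hi:
                    out.append(
                        ClusterComposition(units, charge, mz, float(mass_defect(mz)))
                    )
    out.sort(key=lambda c: c.mz)
    return out


def _compositions(total: int, k: int):
    """All k-tuples of non-negative ints summing to ``total``."""
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, k - 1):
            yield (first, *rest)


def clusters_to_frame(clusters: Sequence[ClusterComposition]) -> pd.DataFrame:
    """Tabulate enumerated clusters (composition label, unit counts, m/z, defect)."""
    return pd.DataFrame(
        {
            "composition": [c.label for c in clusters],
            "total_units": [c.total_units for c in clusters],
            "charge": [c.charge for c in clusters],
            "mz": [c.mz for c in clusters],
            "defect": [c.defect for c in clusters],
        }
    )


def annotate_features(
    mz_values,
    clusters: Sequence[ClusterComposition],
    tolerance_ppm: float = 5.0,
) -> list[ClusterComposition | None]:
    """Best matching cluster per observed m/z, or None outside tolerance.

    The match minimizes |Δ m/z|; ties break toward fewer total units,
    then lexicographically smaller composition label, making annotation
    deterministic. An empty cluster list yields all-None.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    mz_arr = np.atleast_1d(np.asarray(mz_values, dtype=float))
    if not clusters:
        return [None] * mz_arr.size

    ordered = sorted(clusters, key=lambda c: (c.mz, c.total_units, c.label))
    cmz = np.array([c.mz for c in ordered])
    out: list[ClusterComposition | None] = []
    for mz in mz_arr:
        tol = tolerance_ppm * 1e-6 * mz
        lo = np.searchsorted(cmz, mz - tol, side="left")
        hi = np.searchsorted(cmz, mz + tol, side="right")
        best = None
        best_key = None
        for c in ordered[lo:hi]:
            key = (abs(c.mz - mz), c.total_units, c.label)
            if best_key is None or key < best_key:
                best, best_key = c, key
        out.append(best)
    return out
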