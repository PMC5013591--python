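"""Ionization adducts: neutral mass -> observed m/z, and the library survey.

An adduct definition is the named transformation from a neutral
monoisotopic mass M to the m/z the instrument observes, e.g.
``[M+Na]+ : (M + m_Na - m_e) / 1``. The survey operation asks what
fraction of a compound library would land above the salt-cluster
threshold line under a registry of such adducts — the sanity check that
the filter discards almost no genuine metabolome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ELECTRON_MASS, MONOISOTOPIC, mass_defect
from .threshold import DEFAULT_DOMAIN, ThresholdLine

__all__ = [
    "AdductDefinition",
    "AdductRegistry",
    "DEFAULT_REGISTRY",
    "M_PLUS_H",
    "apply_adduct",
    "SurveyResult",
    "fraction_in_cluster_space",
]


@dataclass(frozen=True)
class AdductDefinition:
    """A named neutral-mass -> m/z transformation.

    ``delta`` maps element symbols to the (possibly negative) number of
    atoms gained relative to ``multimer`` copies of the neutral molecule;
    ``charge`` is the charge magnitude and ``polarity`` its sign.
    """

    name: str
    polarity: str  # "+" or "-"
    delta: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1
    multimer: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in "+-":
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge magnitude must be >= 1")
        if self.multimer < 1:
            raise ValueError("multimer count must be >= 1")
        object.__setattr__(self, "delta", dict(self.delta))

    def mz(self, neutral_mass, masses: Mapping[str, float] | None = None):
        return apply_adduct(neutral_mass, self, masses)


def apply_adduct(
    neutral_mass,
    adduct: AdductDefinition,
    masses: Mapping[str, float] | None = None,
):
    """Observed m/z of ``adduct`` formed from ``neutral_mass`` (scalar or array).

    ``m/z = (multimer * M + sum(delta) -/+ charge * m_e) / charge`` with
    the electron term subtracted for positive and added for negative ions.
    """
    arr = np.asarray(neutral_mass, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("neutral mass must be positive")
    table = MONOISOTOPIC if masses is None else masses
    delta_mass = sum(n * table[el] for el, n in adduct.delta.items())
    electron = -adduct.charge * ELECTRON_MASS if adduct.polarity == "+" else adduct.charge * ELECTRON_MASS
    out = (adduct.multimer * arr + delta_mass + electron) / adduct.charge
    if np.isscalar(neutral_mass) or arr.ndim == 0:
        return float(out)
    return out


M_PLUS_H = AdductDefinition("[M+H]+", "+", {"H": 1})

_POSITIVE = (
    M_PLUS_H,
    AdductDefinition("[M+Na]+", "+", {"Na": 1}),
    AdductDefinition("[M+K]+", "+", {"K": 1}),
    AdductDefinition("[M+NH4]+", "+", {"N": 1, "H": 4}),
)
_NEGATIVE = (
    AdductDefinition("[M-H]-", "-", {"H": -1}),
    AdductDefinition("[M+Cl]-", "-", {"Cl": 1}),
    AdductDefinition("[M+HCOO]-", "-", {"C": 1, "H": 1, "O": 2}),
)


class AdductRegistry:
    """Ordered adduct definitions grouped by polarity, unique by name."""

    def __init__(self, adducts: Iterable[AdductDefinition] = ()) -> None:
        self._by_polarity: dict[str, list[AdductDefinition]] = {"+": [], "-": []}
        self._names: set[str] = set()
        for a in adducts:
            self.add(a)

    def add(self, adduct: AdductDefinition) -> None:
        if adduct.name in self._names:
            raise ValueError(f"duplicate adduct name {adduct.name!r}")
        self._names.add(adduct.name)
        self._by_polarity[adduct.polarity].append(adduct)

    def for_polarity(self, polarity: str) -> list[AdductDefinition]:
        if polarity not in "+-":
            raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
        return list(self._by_polarity[polarity])

    def __iter__(self):
        return iter(self._by_polarity["+"] + self._by_polarity["-"])

    def __len__(self) -> int:
        return len(self._names)

    @classmethod
    def default(cls) -> "AdductRegistry":
        return cls((*_POSITIVE, *_NEGATIVE))

    @classmethod
    def from_json(cls, path: str | Path) -> "AdductRegistry":
        """Load a registry from a JSON list of adduct objects."""
        entries = json.loads(Path(path).read_text())
        reg = cls()
        for e in entries:
            reg.add(
                AdductDefinition(
                    e["name"],
                    e["polarity"],
                    {k: int(v) for k, v in e.get("delta", {}).items()},
                    int(e.get("charge", 1)),
                    int(e.get("multimer", 1)),
                )
            )
        return reg

    def to_json(self, path: str | Path) -> None:
        entries = [
            {
                "name": a.name,
                "polarity": a.polarity,
                "delta": dict(a.delta),
                "charge": a.charge,
                "multimer": a.multimer,
            }
            for a in self
        ]
        Path(path).write_text(json.dumps(entries, indent=2) + "\n")


DEFAULT_REGISTRY = AdductRegistry.default()


@dataclass
class SurveyResult:
    """Outcome of a cluster-space survey over a compound library."""

    percent: float
    n_flagged: int
    n_total: int
    per_adduct: pd.DataFrame
    polarity: str
    per_compound: bool

    def __str__(self) -> str:
        mode = "compound-level" if self.per_compound else "adduct-level"
        return (
            f"{self.percent:.2f} % of {self.n_total} library compounds "
            f"({self.polarity} mode, {mode}) fall in salt-cluster space"
        )


def fraction_in_cluster_space(
    neutral_masses: Sequence[float],
    line: ThresholdLine,
    polarity: str = "+",
    adducts: Sequence[AdductDefinition] | None = None,
    domain: tuple[float, float] = DEFAULT_DOMAIN,
    per_compound: bool = True,
) -> SurveyResult:
    """Percentage of library compounds landing above the threshold line.

    Each compound is projected through every adduct of the requested
    polarity. With ``per_compound=True`` (default) a compound is flagged
    if ANY of its adducts falls inside ``domain`` with a defect above the
    line; compounds with no adduct inside the domain are excluded from
    the denominator. With ``per_compound=False`` counting is per
    (compound, adduct) pair instead.
    """
    masses = np.asarray(neutral_masses, dtype=float)
    if masses.size == 0:
        raise ValueError("compound library is empty")
    if adducts is None:
        adducts = DEFAULT_REGISTRY.for_polarity(polarity)
    adducts = list(adducts)
    if not adducts:
        raise ValueError("no adducts to survey")

    lo, hi = domain
    in_any_domain = np.zeros(masses.size, dtype=bool)
    above_any = np.zeros(masses.size, dtype=bool)
    rows = []
    pair_flagged = pair_total = 0
    for a in adducts:
        mz = np.asarray(apply_adduct(masses, a))
        in_dom = (mz >= lo) & (mz <= hi)
        above = np.zeros_like(in_dom)
        if in_dom.any():
            above[in_dom] = mass_defect(mz[in_dom]) > line.threshold_at(
                mz[in_dom], warn_outside=False
            )
        in_any_domain |= in_dom
        above_any |= above
        pair_flagged += int(above.sum())
        pair_total += int(in_dom.sum())
        rows.append(
            {
                "adduct": a.name,
                "n_in_domain": int(in_dom.sum()),
                "n_above_line": int(above.sum()),
                "percent_above": 100.0 * above.sum() / in_dom.sum() if in_dom.any() else np.nan,
            }
        )

    if per_compound:
        n_total = int(in_any_domain.sum())
        n_flagged = int(above_any.sum())
    else:
        n_total, n_flagged = pair_total, pair_flagged
    if n_total == 0:
        raise ValueError("no library compound projects into the m/z domain")
    return SurveyResult(
        percent=100.0 * n_flagged / n_total,
        n_flagged=n_flagged,
        n_total=n_total,
        per_adduct=pd.DataFrame(rows),
        polarity=polarity,
        per_compound=per_compound,
    )
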