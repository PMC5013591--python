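"""The mass-defect threshold line bounding CHNO compound space.

Compounds built only from C, H, N and O cannot exceed the mass defect of
the saturated alkane of the same nominal mass: hydrogen is the only
element with a large positive per-nominal-unit defect, and C_nH_{2n+2} is
the most hydrogen-rich stoichiometry possible. A straight line fitted
through the protonated-alkane series therefore forms a ceiling in
(m/z, defect) space; ions above it are, in a human-metabolome context,
overwhelmingly electrospray salt clusters or multiply charged species.

The published operating line is ``defect = 0.00112 * mz + 0.01953`` over
50-750 m/z (:data:`PUBLISHED_LINE`). Refitting the alkane series with
full-precision element masses reproduces the slope exactly and the
intercept to four decimals (0.01955 vs 0.01953); the published
coefficients remain the package default so filter output matches the
original report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import MONOISOTOPIC, PROTON_MASS, MolecularFormula, mass_defect, parse_formula

__all__ = [
    "ThresholdLine",
    "PUBLISHED_LINE",
    "DEFAULT_DOMAIN",
    "alkane_series",
    "fit_threshold",
    "fit_threshold_from_library",
]

#: m/z window of the survey figure and of the alkane fit.
DEFAULT_DOMAIN: tuple[float, float] = (50.0, 750.0)

#: Elements excluded when fitting the line from a compound library:
#: S/P/halogen chemistry (sulphates, phosphates, thyroid hormones, ...)
#: legitimately exceeds the CHNO ceiling.
ENVELOPE_EXCLUDED_ELEMENTS = frozenset({"S", "P", "F", "Cl", "Br", "I"})


@dataclass(frozen=True)
class ThresholdLine:
    """``defect = slope * mz + intercept`` with the m/z domain it was fit on."""

    slope: float
    intercept: float
    domain: tuple[float, float] = DEFAULT_DOMAIN

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.intercept < 1:
            raise ValueError("intercept must lie in [0, 1)")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"empty m/z domain {self.domain!r}")

    def threshold_at(self, mz, warn_outside: bool = True):
        """Threshold defect at m/z; extrapolation outside the fit domain warns."""
        arr = np.asarray(mz, dtype=float)
        if np.any(arr < 0):
            raise ValueError("m/z must be non-negative")
        lo, hi = self.domain
        if warn_outside and np.any((arr > 0) & ((arr < lo) | (arr > hi))):
            warnings.warn(
                f"evaluating threshold line outside its fit domain [{lo}, {hi}]",
                stacklevel=2,
            )
        out = self.slope * arr + self.intercept
        if np.isscalar(mz) or arr.ndim == 0:
            return float(out)
        return out

    __call__ = threshold_at

    def is_above(self, mz, warn_outside: bool = False):
        """True where mass_defect(mz) strictly exceeds the line (salt-cluster space)."""
        return mass_defect(mz) > self.threshold_at(mz, warn_outside=warn_outside)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "domain": list(self.domain),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdLine":
        return cls(float(d["slope"]), float(d["intercept"]), tuple(d.get("domain", DEFAULT_DOMAIN)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdLine":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: The published operating line, y = 0.00112 x + 0.01953.
PUBLISHED_LINE = ThresholdLine(0.00112, 0.01953, DEFAULT_DOMAIN)


def alkane_series(
    domain: tuple[float, float] = DEFAULT_DOMAIN,
    masses: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Protonated alkanes [C_nH_{2n+2} + H]+ whose m/z falls inside ``domain``.

    Returns a DataFrame with columns ``n``, ``mz``, ``defect``, sorted by
    ``n``. The series realizes the theoretical mass-defect maximum for
    CHNO compounds. An empty result (domain too narrow to contain any
    alkane) is returned as an empty frame rather than an error.
    """
    lo, hi = domain
    if not lo < hi:
        raise ValueError(f"empty m/z domain {domain!r}")
    if lo <= 0:
        raise ValueError("domain must be positive")
    table = MONOISOTOPIC if masses is None else masses
    m_c, m_h = table["C"], table["H"]
    # mz(n) = 12 n + (2n+2) m_H + m_proton, increasing in n
    step = m_c + 2 * m_h
    base = 2 * m_h + PROTON_MASS
    n_min = max(1, int(np.ceil((lo - base) / step - 1e-9)))
    n_max = int(np.floor((hi - base) / step + 1e-9))
    n = np.arange(n_min, n_max + 1)
    mz = step * n + base
    keep = (mz >= lo) & (mz <= hi)
    n, mz = n[keep], mz[keep]
    return pd.DataFrame({"n": n, "mz": mz, "defect": mz - np.floor(mz)})


def _ols_line(mz: np.ndarray, defect: np.ndarray, domain: tuple[float, float]) -> ThresholdLine:
    design = np.column_stack([mz, np.ones_like(mz)])
    (slope, intercept), *_ = np.linalg.lstsq(design, defect, rcond=None)
    return ThresholdLine(float(slope), float(intercept), domain)


def fit_threshold(
    series: pd.DataFrame,
    domain: tuple[float, float] | None = None,
) -> ThresholdLine:
    """Ordinary least squares of defect on m/z over an alkane (or point) series.

    ``series`` needs columns ``mz`` and ``defect`` with at least two rows.
    ``domain`` defaults to the m/z extent of the series.
    """
    if len(series) < 2:
        raise ValueError(f"need at least 2 points to fit a line, got {len(series)}")
    mz = np.asarray(series["mz"], dtype=float)
    defect = np.asarray(series["defect"], dtype=float)
    if domain is None:
        domain = (float(mz.min()), float(mz.max()))
    return _ols_line(mz, defect, domain)


def fit_threshold_from_library(
    neutral_masses: Sequence[float],
    formulas: Sequence[str | MolecularFormula | None] | None = None,
    domain: tuple[float, float] = DEFAULT_DOMAIN,
    bin_width: float = 50.0,
    min_compounds: int = 10,
) -> ThresholdLine:
    """Fit the line from a compound library's upper mass-defect envelope.

    Compounds are projected to [M+H]+ m/z; those containing S, P or
    halogens are excluded (their chemistry legitimately exceeds the CHNO
    ceiling), the maximum-defect compound is taken per ``bin_width``-wide
    m/z bin, and a line is fit through those envelope points.
    """
    masses = np.asarray(neutral_masses, dtype=float)
    if formulas is not None and len(formulas) != len(masses):
        raise ValueError("formulas and neutral_masses must have equal length")
    if formulas is not None:
        keep = []
        for f in formulas:
            if f is None:
                keep.append(True)
                continue
            if isinstance(f, str):
                f = parse_formula(f)
            keep.append(not (set(f.counts) & ENVELOPE_EXCLUDED_ELEMENTS))
        masses = masses[np.asarray(keep, dtype=bool)]

    mz = masses + PROTON_MASS
    lo, hi = domain
    mz = mz[(mz >= lo) & (mz <= hi)]
    if len(mz) < min_compounds:
        raise ValueError(
            f"need at least {min_compounds} library compounds in domain, got {len(mz)}"
        )
    defect = mz - np.floor(mz)
    bins = np.floor((mz - lo) / bin_width).astype(int)
    env_mz, env_defect = [], []
    for b in np.unique(bins):
        sel = bins == b
        i = np.argmax(defect[sel])
        env_mz.append(mz[sel][i])
        env_defect.append(defect[sel][i])
    if len(env_mz) < 2:
        raise ValueError("too few envelope points to fit a line")
    return _ols_line(np.asarray(env_mz), np.asarray(env_defect), domain)
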