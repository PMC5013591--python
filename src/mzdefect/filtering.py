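"""Mass-defect / retention-time / inclusion-list filtering of feature tables.

A feature table is a pandas DataFrame with at least an m/z column and a
retention-time column (minutes). Three nested rules are applied:

* **md** — remove a feature when its mass defect strictly exceeds the
  threshold line at its m/z (features exactly on the line are kept);
* **md + RT** — additionally require the feature to elute at or before
  an RT cutoff near the void volume, so that late-eluting high-defect
  ions (multiply charged peptides) survive;
* **md + RT + inclusion** — finally exempt any feature whose m/z matches
  a known-compound inclusion list within a ppm tolerance.

Every filter partitions its input: ``kept`` and ``removed`` preserve the
original row order and together contain every input row exactly once.
The :class:`FilterReport` accumulates the per-stage accounting (features
remaining and percent removed) for all stages computed on one input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import mass_defect
from .threshold import PUBLISHED_LINE, ThresholdLine

__all__ = [
    "InclusionList",
    "FilterStage",
    "FilterReport",
    "validate_feature_table",
    "match_inclusion",
    "filter_md",
    "filter_md_rt",
    "filter_full",
    "build_report",
]

MZ_COL = "mz"
RT_COL = "rt"


@dataclass(frozen=True)
class InclusionList:
    """Known-compound m/z values exempted from removal within a ppm window."""

    mz: tuple[float, ...]
    labels: tuple[str, ...] | None = None
    tolerance_ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        if any(m <= 0 for m in self.mz):
            raise ValueError("inclusion-list m/z values must be positive")
        if self.labels is not None and len(self.labels) != len(self.mz):
            raise ValueError("labels must match mz in length")
        object.__setattr__(self, "mz", tuple(float(m) for m in self.mz))

    def __len__(self) -> int:
        return len(self.mz)


def validate_feature_table(
    table: pd.DataFrame, mz_col: str = MZ_COL, rt_col: str | None = RT_COL
) -> None:
    """Check required columns exist and contain finite, in-range values."""
    missing = [c for c in (mz_col, rt_col) if c is not None and c not in table.columns]
    if missing:
        raise ValueError(
            f"feature table lacks column(s) {missing}; available: {list(table.columns)}"
        )
    if len(table):
        if table[mz_col].isna().any() or (table[mz_col] <= 0).any():
            raise ValueError(f"column {mz_col!r} contains NaN or non-positive m/z")
        if rt_col is not None and (table[rt_col].isna().any() or (table[rt_col] < 0).any()):
            raise ValueError(f"column {rt_col!r} contains NaN or negative retention times")


def _above_line(table: pd.DataFrame, line: ThresholdLine, mz_col: str) -> np.ndarray:
    if not len(table):
        return np.zeros(0, dtype=bool)
    mz = table[mz_col].to_numpy(dtype=float)
    return np.asarray(mass_defect(mz)) > line.threshold_at(mz)


def match_inclusion(mz_values, inclusion: InclusionList) -> np.ndarray:
    """Boolean mask: which observed m/z match an inclusion entry within tolerance."""
    mz = np.atleast_1d(np.asarray(mz_values, dtype=float))
    if not len(inclusion):
        return np.zeros(mz.size, dtype=bool)
    targets = np.sort(np.asarray(inclusion.mz))
    tol = inclusion.tolerance_ppm * 1e-6 * mz
    lo = np.searchsorted(targets, mz - tol, side="left")
    hi = np.searchsorted(targets, mz + tol, side="right")
    return hi > lo


def _partition(table: pd.DataFrame, remove: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    keep_mask = ~remove
    return table.loc[keep_mask].copy(), table.loc[remove].copy()


def filter_md(
    table: pd.DataFrame,
    line: ThresholdLine = PUBLISHED_LINE,
    mz_col: str = MZ_COL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mass-defect-only filter: remove features strictly above the line."""
    validate_feature_table(table, mz_col, rt_col=None)
    return _partition(table, _above_line(table, line, mz_col))


def filter_md_rt(
    table: pd.DataFrame,
    rt_cutoff: float,
    line: ThresholdLine = PUBLISHED_LINE,
    mz_col: str = MZ_COL,
    rt_col: str = RT_COL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove features that are above the line AND elute at/before ``rt_cutoff``.

    ``rt_cutoff`` (minutes) has no default: it is instrument- and
    gradient-specific (void time plus a margin) and must be supplied.
    """
    if rt_cutoff is None or rt_cutoff <= 0:
        raise ValueError("rt_cutoff must be a positive number of minutes")
    validate_feature_table(table, mz_col, rt_col)
    early = table[rt_col].to_numpy(dtype=float) <= rt_cutoff if len(table) else np.zeros(0, bool)
    return _partition(table, _above_line(table, line, mz_col) & early)


def filter_full(
    table: pd.DataFrame,
    rt_cutoff: float,
    inclusion: InclusionList | None = None,
    line: ThresholdLine = PUBLISHED_LINE,
    mz_col: str = MZ_COL,
    rt_col: str = RT_COL,
    polarity: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, "FilterReport"]:
    """Full md + RT + inclusion filter, plus the four-stage report.

    The removal rule is that of :func:`filter_md_rt`, overridden to keep
    any feature matching the inclusion list within its ppm tolerance.
    The report contains all stages (none, md, md+RT, md+RT+inclusion)
    computed on the same input table.
    """
    if rt_cutoff is None or rt_cutoff <= 0:
        raise ValueError("rt_cutoff must be a positive number of minutes")
    validate_feature_table(table, mz_col, rt_col)
    above = _above_line(table, line, mz_col)
    early = table[rt_col].to_numpy(dtype=float) <= rt_cutoff if len(table) else np.zeros(0, bool)
    if inclusion is not None and len(inclusion) and len(table):
        included = match_inclusion(table[mz_col].to_numpy(dtype=float), inclusion)
    else:
        included = np.zeros(len(table), dtype=bool)

    remove_full = above & early & ~included
    kept, removed = _partition(table, remove_full)
    report = build_report(
        len(table),
        {
            "md": int((~above).sum()),
            "md + RT": int((~(above & early)).sum()),
            "md + RT + inclusion": int((~remove_full).sum()),
        },
        polarity=polarity,
    )
    return kept, removed, report


@dataclass(frozen=True)
class FilterStage:
    name: str
    remaining: int
    percent_removed: float


@dataclass
class FilterReport:
    """Per-stage accounting: features remaining and percent removed."""

    polarity: str
    initial: int
    stages: list[FilterStage] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("None", self.initial, 0.00)] + [
            (s.name, s.remaining, s.percent_removed) for s in self.stages
        ]
        df = pd.DataFrame(rows, columns=["filter", "features_remaining", "percent_removed"])
        if self.polarity:
            df.insert(0, "ionization_mode", self.polarity)
        return df

    def __str__(self) -> str:
        lines = [f"Ionization mode: {self.polarity or 'n/a'}"]
        lines.append(f"{'Filter':<22}{'Features remaining':>20}{'% removed':>12}")
        lines.append(f"{'None':<22}{self.initial:>20}{0.00:>12.2f}")
        for s in self.stages:
            lines.append(f"{s.name:<22}{s.remaining:>20}{s.percent_removed:>12.2f}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_report(
    initial: int | pd.DataFrame,
    stage_remaining: dict[str, int],
    polarity: str = "",
) -> FilterReport:
    """Assemble a :class:`FilterReport` from per-stage remaining counts.

    Percent removed is ``100 * (1 - remaining / initial)`` rounded to two
    decimals. Stage counts exceeding the initial count indicate the
    stages were not computed on the same input and raise.
    """
    n0 = len(initial) if isinstance(initial, pd.DataFrame) else int(initial)
    if n0 < 0:
        raise ValueError("initial feature count must be non-negative")
    stages = []
    for name, remaining in stage_remaining.items():
        if remaining > n0 or remaining < 0:
            raise ValueError(
                f"stage {name!r} has {remaining} features remaining out of {n0}: "
                "stages must be computed on the same initial table"
            )
        pct = 0.0 if n0 == 0 else round(100.0 * (1.0 - remaining / n0), 2)
        stages.append(FilterStage(name, remaining, pct))
    return FilterReport(polarity=polarity, initial=n0, stages=stages)
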