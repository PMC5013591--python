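"""Labelled synthetic feature tables emulating plasma LC-MS structure.

The generator produces the three feature classes that drive the filter's
design, plus an optional fourth:

* **metabolite** — CHNO-plausible ions: defect sampled uniformly below
  90 % of the threshold line, RT spread across the gradient;
* **cluster** — real enumerated Na/K-Cl/formate cluster ions (with small
  ppm-scale mass jitter), eluting in or near the void volume;
* **peptide** — multiply charged (z = 2-3) tryptic-size peptides whose
  m/z lands above the singly-charged CHNO ceiling, retained on the
  column (late RT);
* **inclusion_metabolite** — genuine high-defect knowns (above the line,
  early-eluting) that only the inclusion list can rescue.

Class counts for the plasma presets mirror the feature accounting of the
original plasma datasets (2227 positive- and 1742 negative-mode
features). All randomness flows through one seeded generator, so a fixed
seed reproduces the table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, mass_defect
from .clusters import enumerate_clusters
from .filtering import InclusionList
from .threshold import DEFAULT_DOMAIN, PUBLISHED_LINE, ThresholdLine

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "write_fixture",
    "synthetic_compound_library",
]

LABEL_METABOLITE = "metabolite"
LABEL_CLUSTER = "cluster"
LABEL_PEPTIDE = "peptide"
LABEL_INCLUSION = "inclusion_metabolite"


@dataclass(frozen=True)
class SyntheticSpec:
    """Counts, m/z domain, per-class RT supports, and the seed."""

    n_metabolites: int
    n_clusters: int
    n_peptides: int
    n_inclusion_metabolites: int = 0
    mz_domain: tuple[float, float] = DEFAULT_DOMAIN
    rt_cluster: tuple[float, float] = (0.2, 1.2)
    rt_metabolite: tuple[float, float] = (1.5, 14.0)
    rt_peptide: tuple[float, float] = (2.0, 14.0)
    polarity: str = "+"
    mz_jitter_ppm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_clusters", "n_peptides", "n_inclusion_metabolites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.mz_domain
        if not (0 < lo < hi):
            raise ValueError(f"infeasible m/z domain {self.mz_domain!r}")
        if hi - lo < 2:
            raise ValueError("m/z domain too narrow to place features")
        for name in ("rt_cluster", "rt_metabolite", "rt_peptide"):
            a, b = getattr(self, name)
            if not (0 <= a < b):
                raise ValueError(f"invalid RT support {name}={getattr(self, name)!r}")
        if self.polarity not in "+-":
            raise ValueError("polarity must be '+' or '-'")

    @property
    def n_total(self) -> int:
        return (
            self.n_metabolites + self.n_clusters + self.n_peptides + self.n_inclusion_metabolites
        )

    # Presets mirroring the plasma datasets' per-class accounting.
    @classmethod
    def plasma_positive(cls, seed: int = 0) -> "SyntheticSpec":
        return cls(1730, 355, 123, n_inclusion_metabolites=19, polarity="+", seed=seed)

    @classmethod
    def plasma_negative(cls, seed: int = 0) -> "SyntheticSpec":
        return cls(1107, 496, 118, n_inclusion_metabolites=21, polarity="-", seed=seed)

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass
class SyntheticDataset:
    """Generated feature table, aligned ground-truth labels, inclusion list."""

    table: pd.DataFrame  # columns: mz, rt, intensity, id
    labels: pd.Series  # class label per feature, same index as table
    inclusion: InclusionList | None
    spec: SyntheticSpec

    @property
    def recommended_rt_cutoff(self) -> float:
        """Midpoint between the cluster RT ceiling and the metabolite RT floor."""
        return 0.5 * (self.spec.rt_cluster[1] + self.spec.rt_metabolite[0])


def generate(spec: SyntheticSpec, line: ThresholdLine = PUBLISHED_LINE) -> SyntheticDataset:
    """Draw a labelled feature table according to ``spec``; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mz_domain
    frames = []

    def block(mz, rt, label, prefix):
        n = len(mz)
        frames.append(
            pd.DataFrame(
                {
                    "mz": mz,
                    "rt": rt,
                    "intensity": rng.lognormal(mean=12.0, sigma=1.0, size=n),
                    "id": [f"{prefix}{i:04d}" for i in range(n)],
                    "label": label,
                }
            )
        )

    # metabolites: defect uniform in [0, 0.9 * threshold(nominal)]
    if spec.n_metabolites:
        nominal = rng.integers(int(np.ceil(lo)), int(np.floor(hi)), size=spec.n_metabolites)
        ceiling = 0.9 * line.threshold_at(nominal.astype(float), warn_outside=False)
        mz = nominal + rng.uniform(0.0, ceiling)
        rt = rng.uniform(*spec.rt_metabolite, size=spec.n_metabolites)
        block(mz, rt, LABEL_METABOLITE, "M")

    # salt clusters: resampled from the enumerated Na/K-Cl/formate ions
    if spec.n_clusters:
        pool = enumerate_clusters(spec.mz_domain, polarity=spec.polarity)
        if not pool:
            raise ValueError(f"no salt cluster falls inside domain {spec.mz_domain!r}")
        picks = rng.integers(0, len(pool), size=spec.n_clusters)
        mz = np.array([pool[i].mz for i in picks])
        mz = mz * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm * 1e-6, size=spec.n_clusters))
        rt = rng.uniform(*spec.rt_cluster, size=spec.n_clusters)
        block(mz, rt, LABEL_CLUSTER, "C")

    # multiply charged peptides: rejection-sampled above the line, in domain
    if spec.n_peptides:
        mz = _sample_peptides(rng, spec, line)
        rt = rng.uniform(*spec.rt_peptide, size=spec.n_peptides)
        block(mz, rt, LABEL_PEPTIDE, "P")

    # high-defect knowns rescued only by the inclusion list
    inclusion = None
    if spec.n_inclusion_metabolites:
        nominal = rng.integers(
            int(np.ceil(lo)), int(np.floor(hi)), size=spec.n_inclusion_metabolites
        )
        floor_defect = line.threshold_at(nominal.astype(float) + 1.0, warn_outside=False) + 0.02
        mz = nominal + rng.uniform(floor_defect, 0.97)
        rt = rng.uniform(*spec.rt_cluster, size=spec.n_inclusion_metabolites)
        block(mz, rt, LABEL_INCLUSION, "L")
        inclusion = InclusionList(tuple(np.sort(mz)), tolerance_ppm=5.0)

    if not frames:
        raise ValueError("spec describes zero features")
    df = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    labels = df.pop("label")
    labels.name = "label"
    return SyntheticDataset(table=df, labels=labels, inclusion=inclusion, spec=spec)


def _sample_peptides(rng, spec: SyntheticSpec, line: ThresholdLine) -> np.ndarray:
    """Rejection-sample multiply charged peptide m/z above the threshold line.

    Peptide monoisotopic masses are drawn uniformly in 800-2100 Da with
    charge 2 or 3 ([M+zH]z+ in positive mode, [M-zH]z- in negative);
    roughly half of the draws exceed the singly-charged CHNO line, so the
    loop terminates quickly.
    """
    lo, hi = spec.mz_domain
    out: list[float] = []
    sign = 1.0 if spec.polarity == "+" else -1.0
    for _ in range(10_000):
        need = spec.n_peptides - len(out)
        if need <= 0:
            break
        mass = rng.uniform(800.0, 2100.0, size=max(8, 4 * need))
        z = rng.choice([2, 3], size=mass.size)
        mz = (mass + sign * z * PROTON_MASS) / z
        ok = (mz >= lo) & (mz <= hi)
        ok &= np.asarray(mass_defect(np.abs(mz))) > line.threshold_at(
            np.clip(mz, lo, hi), warn_outside=False
        ) + 0.01
        out.extend(mz[ok][:need])
    else:
        raise RuntimeError("peptide rejection sampling failed to converge")
    return np.asarray(out[: spec.n_peptides])


def synthetic_compound_library(
    n: int = 2000,
    seed: int = 0,
    high_defect_fraction: float = 0.004,
    mz_domain: tuple[float, float] = DEFAULT_DOMAIN,
    line: ThresholdLine = PUBLISHED_LINE,
) -> np.ndarray:
    """Synthetic neutral monoisotopic masses emulating a metabolome library.

    Most compounds get a CHNO-like mass defect growing roughly linearly
    with mass (per-Da rates up to ~0.00085, below the alkane ceiling). A
    small ``high_defect_fraction`` emulates the rare S/P/halogen
    chemistry (sulphates, phosphates, iodinated hormones) whose
    protonated ions genuinely land above the threshold line. Compounds
    whose masses sit just below an integer can still wrap past the next
    nominal mass under Na/K/Cl adducts, so all-adduct surveys flag more
    compounds than [M+H]-only surveys.
    """
    if n < 1:
        raise ValueError("library size must be positive")
    if not 0 <= high_defect_fraction < 1:
        raise ValueError("high_defect_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = mz_domain
    nominal = rng.integers(int(lo) + 10, int(hi) - 10, size=n).astype(float)
    rate = rng.uniform(0.00012, 0.00085, size=n)
    masses = nominal + nominal * rate
    n_high = int(round(high_defect_fraction * n))
    if n_high:
        idx = rng.choice(n, size=n_high, replace=False)
        target = line.threshold_at(nominal[idx], warn_outside=False) + rng.uniform(
            0.02, 0.12, size=n_high
        )
        # place frac(M) so that [M+H]+ carries the target defect
        masses[idx] = nominal[idx] + target - PROTON_MASS % 1.0
    return masses


def write_fixture(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write features.csv, labels.csv and (if present) inclusion.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"features": outdir / "features.csv", "labels": outdir / "labels.csv"}
    dataset.table.to_csv(paths["features"], index=False)
    pd.DataFrame({"id": dataset.table["id"], "label": dataset.labels}).to_csv(
        paths["labels"], index=False
    )
    if dataset.inclusion is not None:
        paths["inclusion"] = outdir / "inclusion.csv"
        pd.DataFrame({"mz": dataset.inclusion.mz}).to_csv(paths["inclusion"], index=False)
    return paths
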