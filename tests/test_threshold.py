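"""Alkane series generation and the threshold-line fits."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mzdefect.chem import MONOISOTOPIC, PROTON_MASS
from mzdefect.threshold import (
    DEFAULT_DOMAIN,
    PUBLISHED_LINE,
    ThresholdLine,
    alkane_series,
    fit_threshold,
    fit_threshold_from_library,
)


class TestAlkaneSeries:
    def test_default_domain_covers_n_4_to_53(self, alkanes):
        assert alkanes["n"].min() == 4
        assert alkanes["n"].max() == 53
        assert alkanes["mz"].between(*DEFAULT_DOMAIN).all()

    def test_mz_strictly_increasing(self, alkanes):
        assert alkanes["mz"].is_monotonic_increasing
        assert alkanes["mz"].diff().dropna().gt(0).all()

    def test_protonated_decane(self, alkanes):
        # [C10H22 + H]+ hand-summed: 120 + 22*1.00782503 + 1.00727647
        row = alkanes.set_index("n").loc[10]
        assert row["mz"] == pytest.approx(143.17943, abs=1e-5)
        assert row["defect"] == pytest.approx(0.17943, abs=1e-5)

    def test_narrow_domain_yields_empty_series(self):
        assert len(alkane_series((100.0, 100.5))) == 0

    def test_empty_domain_errors(self):
        with pytest.raises(ValueError):
            alkane_series((200.0, 100.0))


class TestFitThreshold:
    def test_two_collinear_points(self):
        series = pd.DataFrame({"mz": [1e-9, 100.0], "defect": [0.1, 0.2]})
        fit = fit_threshold(series)
        assert fit.slope == pytest.approx(0.001, rel=1e-6)
        assert fit.intercept == pytest.approx(0.1, rel=1e-6)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            fit_threshold(pd.DataFrame({"mz": [100.0], "defect": [0.1]}))

    def test_matches_independent_linregress_oracle(self, alkanes):
        fit = fit_threshold(alkanes)
        oracle = stats.linregress(alkanes["mz"], alkanes["defect"])
        assert fit.slope == pytest.approx(oracle.slope, abs=1e-10)
        assert fit.intercept == pytest.approx(oracle.intercept, abs=1e-10)

    def test_matches_normal_equations_on_noisy_series(self):
        rng = np.random.default_rng(3)
        mz = rng.uniform(50, 750, size=40)
        defect = 0.001 * mz + 0.02 + rng.normal(0, 0.01, size=40)
        series = pd.DataFrame({"mz": mz, "defect": defect})
        fit = fit_threshold(series)
        X = np.column_stack([mz, np.ones_like(mz)])
        beta = np.linalg.solve(X.T @ X, X.T @ defect)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_alkane_defects_are_nearly_affine(self, alkanes):
        fit = fit_threshold(alkanes)
        resid = alkanes["defect"] - fit.threshold_at(alkanes["mz"].to_numpy())
        ss_res = float((resid**2).sum())
        ss_tot = float(((alkanes["defect"] - alkanes["defect"].mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot > 0.9999


class TestThresholdLine:
    @pytest.mark.parametrize("mz,expected", [(0.0, 0.01953), (500.0, 0.57953), (750.0, 0.85953)])
    def test_published_line_values(self, mz, expected):
        assert PUBLISHED_LINE.threshold_at(mz, warn_outside=False) == pytest.approx(
            expected, abs=1e-10
        )

    def test_monotone_and_below_one_on_domain(self, line):
        grid = np.linspace(50, 750, 500)
        vals = line.threshold_at(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < 1)

    def test_warns_outside_fit_domain(self, line):
        with pytest.warns(UserWarning, match="outside its fit domain"):
            line.threshold_at(900.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ThresholdLine(-0.001, 0.02)
        with pytest.raises(ValueError):
            ThresholdLine(0.001, 1.2)
        with pytest.raises(ValueError):
            ThresholdLine(0.001, 0.02, (700.0, 50.0))

    def test_json_roundtrip(self, tmp_path, line):
        p = tmp_path / "model.json"
        line.to_json(p)
        again = ThresholdLine.from_json(p)
        assert again == line
        assert set(json.loads(p.read_text())) == {"slope", "intercept", "domain"}


class TestLibraryRoute:
    def test_alkane_library_reproduces_alkane_fit(self, alkanes):
        # neutral alkane masses: protonated library entries recreate the series
        neutral = alkanes["mz"].to_numpy() - PROTON_MASS
        lib_fit = fit_threshold_from_library(neutral)
        alk_fit = fit_threshold(alkanes, domain=DEFAULT_DOMAIN)
        assert lib_fit.slope == pytest.approx(alk_fit.slope, abs=1e-9)
        assert lib_fit.intercept == pytest.approx(alk_fit.intercept, abs=1e-9)

    def test_low_defect_decoys_do_not_move_the_fit(self, alkanes):
        neutral = alkanes["mz"].to_numpy() - PROTON_MASS
        rng = np.random.default_rng(11)
        # decoys strictly dominated by the alkane envelope in every bin
        decoy_nominal = rng.integers(60, 740, size=200)
        decoys = decoy_nominal + rng.uniform(0.0, 0.01, size=200) - PROTON_MASS
        fit_clean = fit_threshold_from_library(neutral)
        fit_decoyed = fit_threshold_from_library(np.concatenate([neutral, decoys]))
        assert fit_decoyed.slope == pytest.approx(fit_clean.slope, abs=1e-9)
        assert fit_decoyed.intercept == pytest.approx(fit_clean.intercept, abs=1e-9)

    def test_sulfur_compound_excluded_from_envelope(self, alkanes):
        neutral = alkanes["mz"].to_numpy() - PROTON_MASS
        formulas = [None] * len(neutral)
        # a fake ultra-high-defect S compound that would tilt the fit if used
        spike_mass = 399.95 - PROTON_MASS
        fit_clean = fit_threshold_from_library(neutral)
        fit_spiked = fit_threshold_from_library(
            np.append(neutral, spike_mass), formulas=formulas + ["C10H20S4"]
        )
        assert fit_spiked.intercept == pytest.approx(fit_clean.intercept, abs=1e-9)
        # and without the formula annotation the spike does tilt the fit
        fit_tilted = fit_threshold_from_library(np.append(neutral, spike_mass))
        assert fit_tilted.intercept != pytest.approx(fit_clean.intercept, abs=1e-6)

    def test_too_few_compounds_errors(self):
        with pytest.raises(ValueError):
            fit_threshold_from_library([100.0, 200.0, 300.0])
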