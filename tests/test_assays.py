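"""Mixture interpolation, viscosity correction, transition detection, groups."""

import numpy as np
import pytest

import nanolever as nl
from nanolever.assays import CorrectedSeries, relative_viscosity


@pytest.fixture
def cal():
    return nl.MixtureCalibration(DR_pure_A=1.8, DR_pure_B=0.9, sd_A=0.02, sd_B=0.02)


def _control_series(noise=0.0, seed=0, slope=-1.0):
    conc = np.array([0.0, 3.5, 7.0, 10.5, 14.0])
    visc = relative_viscosity("glycerin", conc)
    rng = np.random.default_rng(seed)
    dr = 1.0 + slope * (visc - 1.0) + rng.normal(0, noise, size=conc.size)
    return nl.ViscositySeries("glycerin", conc, visc, dr,
                              np.full(conc.size, max(noise, 1e-6)))


class TestMixtureFraction:
    def test_endpoints_and_midpoint(self, cal):
        assert nl.mixture_fraction(1.8, cal)[0] == pytest.approx(1.0)
        assert nl.mixture_fraction(0.9, cal)[0] == pytest.approx(0.0)
        assert nl.mixture_fraction(1.35, cal)[0] == pytest.approx(0.5)

    def test_exactly_linear(self, cal):
        for lam in np.linspace(0, 1, 11):
            dr = lam * cal.DR_pure_A + (1 - lam) * cal.DR_pure_B
            assert nl.mixture_fraction(dr, cal)[0] == pytest.approx(lam, abs=1e-12)

    def test_out_of_range_clipped_with_warning(self, cal):
        with pytest.warns(UserWarning, match="outside"):
            f, _ = nl.mixture_fraction(2.5, cal)
        assert f == 1.0

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError):
            nl.MixtureCalibration(DR_pure_A=1.0, DR_pure_B=1.0)

    def test_monte_carlo_error_below_ten_percent(self):
        # 70:30 mixtures with 3% relative DR noise
        cal = nl.MixtureCalibration(DR_pure_A=1.8, DR_pure_B=0.9)
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(500):
            dr_true = 0.7 * 1.8 + 0.3 * 0.9
            dr = dr_true * (1 + rng.normal(0, 0.03))
            f, _ = nl.mixture_fraction(dr, cal)
            errs.append(abs(f - 0.7))
        assert np.mean(errs) <= 0.10


class TestViscosityCorrect:
    def test_control_corrects_itself_to_zero(self):
        ctrl = _control_series()
        corrected = nl.viscosity_correct(ctrl, ctrl)
        assert np.allclose(corrected.values, 0.0, atol=1e-12)

    def test_matched_series_correct_to_noise(self):
        sample = _control_series(noise=0.005, seed=1)
        control = _control_series(noise=0.005, seed=2)
        corrected = nl.viscosity_correct(sample, control)
        assert np.max(np.abs(corrected.values)) < 0.03

    def test_sigmoid_isolated_from_viscosity_background(self):
        # constructed ground truth: linear viscosity response + sigmoid
        conc = np.linspace(0.0, 4.0, 9)
        visc = relative_viscosity("urea", conc)
        sigmoid = -0.2 / (1.0 + np.exp(-(conc - 1.2) / 0.3))
        sample = nl.ViscositySeries("urea", conc, visc,
                                    1.0 - 1.0 * (visc - 1.0) + sigmoid,
                                    np.full(conc.size, 1e-6))
        ctrl_conc = np.linspace(0.0, 16.0, 9)
        ctrl_visc = relative_viscosity("glycerin", ctrl_conc)
        control = nl.ViscositySeries("glycerin", ctrl_conc, ctrl_visc,
                                     1.0 - 1.0 * (ctrl_visc - 1.0),
                                     np.full(ctrl_conc.size, 1e-6))
        corrected = nl.viscosity_correct(sample, control)
        assert np.allclose(corrected.values, sigmoid, atol=0.02 * 0.2)

    def test_nonlinear_control_rejected(self):
        ctrl = _control_series()
        bad = nl.ViscositySeries(ctrl.agent, ctrl.concentrations,
                                 ctrl.rel_viscosities,
                                 (ctrl.rel_viscosities - 1.0) ** 3,
                                 ctrl.dr_sd)
        with pytest.raises(ValueError, match="linear"):
            nl.viscosity_correct(_control_series(), bad)

    def test_coverage_mismatch_rejected(self):
        sample = _control_series()
        narrow = nl.ViscositySeries("glycerin",
                                    sample.concentrations[:3],
                                    sample.rel_viscosities[:3],
                                    sample.dr[:3], sample.dr_sd[:3])
        with pytest.raises(ValueError, match="coverage"):
            nl.viscosity_correct(sample, narrow)


class TestDetectTransition:
    def _series(self, values, sd=0.01):
        conc = np.linspace(0.0, 4.0, 9)
        return CorrectedSeries(conc, np.ones_like(conc), np.asarray(values),
                               np.full(conc.size, sd))

    def test_flat_series_no_transition(self):
        rng = np.random.default_rng(0)
        res = nl.detect_transition(self._series(rng.normal(0, 0.01, 9)))
        assert not res.detected

    def test_sigmoid_recovered(self):
        conc = np.linspace(0.0, 4.0, 9)
        rng = np.random.default_rng(1)
        clean = 0.25 / (1.0 + np.exp(-(conc - 1.2) / 0.3))
        series = self._series(clean + rng.normal(0, 0.01, 9), sd=0.01)
        res = nl.detect_transition(series)
        assert res.detected
        assert res.midpoint == pytest.approx(1.2, abs=0.2)
        assert res.c_low < res.midpoint < res.c_high

    def test_false_positive_rate_below_five_percent(self):
        # 3-sigma rule on flat noise, many replicates, fixed seed
        rng = np.random.default_rng(2024)
        n_rep, hits = 1000, 0
        for _ in range(n_rep):
            res = nl.detect_transition(self._series(rng.normal(0, 0.01, 9)))
            hits += res.detected
        assert hits / n_rep <= 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nl.detect_transition(CorrectedSeries(
                np.arange(3.0), np.ones(3), np.zeros(3), np.full(3, 0.01)))


class TestGroupComparison:
    def test_identical_groups_not_separated(self):
        g = [1.0, 1.01, 0.99, 1.0, 1.02, 0.98]
        res = nl.compare_dr_groups(g, g)
        assert not res.separated
        assert res.delta == 0.0

    def test_well_separated_groups(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 0.02, 6)
        b = rng.normal(0.7, 0.02, 6)  # ~15 sigma apart at n=6
        res = nl.compare_dr_groups(a, b)
        assert res.separated
        assert res.delta == pytest.approx(0.3, abs=0.05)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            nl.compare_dr_groups([1.0, 1.1], [0.9, 1.0, 1.1])


class TestViscosityTable:
    def test_reference_endpoints(self):
        assert relative_viscosity("urea", 0.0) == 1.0
        assert relative_viscosity("glycerin", 0.0) == 1.0
        assert relative_viscosity("urea", 8.0) > relative_viscosity("urea", 4.0) > 1.0

    def test_unknown_agent_needs_table(self):
        with pytest.raises(KeyError):
            relative_viscosity("sucrose", 1.0)
        assert relative_viscosity("sucrose", 1.0,
                                  table=([0.0, 2.0], [1.0, 1.5])) == 1.25

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            relative_viscosity("urea", 50.0)
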