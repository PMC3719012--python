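"""Lever geometry, free energy and equilibrium distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanolever as nl
from nanolever.model import (
    DEFAULT_STERIC_FLOOR_RAD,
    electrode_potential,
    potential_energy,
)


class TestGeometry:
    def test_default_48bp_lever_length(self):
        g = nl.LeverGeometry()
        assert g.n_bp == 48 and g.b == 0.34
        assert abs(g.L - 16.32) < 1e-9
        assert g.R == 1.3

    def test_inconsistent_length_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            nl.LeverGeometry(n_bp=48, b=0.34, L=15.0)

    @pytest.mark.parametrize("kw", [dict(n_bp=0), dict(b=-0.1), dict(R=0.0)])
    def test_nonpositive_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            nl.LeverGeometry(**kw)


class TestElectricModel:
    def test_tau_is_four_thirds_rc(self):
        e = nl.ElectricModel(RC=0.3e-6)
        assert e.tau == 4.0 * 0.3e-6 / 3.0

    def test_slow_charging_warns(self):
        with pytest.warns(UserWarning, match="half-period"):
            nl.ElectricModel(RC=1e-5, frequency=1e4)  # tau > half-period/10

    def test_charging_starts_at_previous_plateau(self):
        e = nl.ElectricModel(phi_up=-0.3, phi_down=0.3)
        assert electrode_potential(e, 0.0, "up") == pytest.approx(0.3)
        assert electrode_potential(e, 0.0, "down") == pytest.approx(-0.3)

    def test_full_charging_at_long_times(self):
        e = nl.ElectricModel(phi_up=-0.3, phi_down=0.3)
        assert electrode_potential(e, 100 * e.tau, "up") == pytest.approx(-0.3, abs=1e-10)

    def test_one_tau_closed_form(self):
        # Phi(tau) = Phi_target + e^-1 (Phi_start - Phi_target) = -0.3 + 0.6/e
        e = nl.ElectricModel(phi_up=-0.3, phi_down=0.3)
        expected = -0.3 + 0.6 / math.e
        assert electrode_potential(e, e.tau, "up") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.0793, abs=5e-5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            electrode_potential(nl.ElectricModel(), -1e-9, "up")


class TestFreeEnergy:
    def test_purely_entropic_without_field_and_charge(self, bare_system):
        alphas = np.linspace(0.05, 1.5, 20)
        g = nl.free_energy(bare_system, alphas, 0.0)
        assert np.allclose(g, -np.log(np.cos(alphas)), atol=1e-14)

    def test_independent_of_screening_when_uncharged(self):
        alphas = np.linspace(0.05, 1.5, 10)
        out = []
        for gamma, kappa in [(0.016, 0.7), (0.5, 0.7), (0.016, 2.0)]:
            s = nl.LeverSystem(electric=nl.ElectricModel(gamma=gamma, kappa=kappa))
            out.append(nl.free_energy(s, alphas, 0.0))
        assert np.allclose(out[0], out[1]) and np.allclose(out[0], out[2])

    def test_site_sum_matches_brute_force(self, bare_system):
        # closed-form geometric series vs explicit 48-term sum
        import nanolever.constants as c

        alpha, phi = 0.5, 0.25
        kap = bare_system.kappa
        g = bare_system.geometry
        vt = c.thermal_voltage_V(bare_system.env.T)
        brute = -(bare_system.electric.gamma * phi / vt) * sum(
            math.exp(-kap * i * g.b * math.sin(alpha)) for i in range(1, g.n_bp + 1)
        )
        closed = potential_energy(bare_system, alpha, phi)
        assert abs(closed - brute) <= 1e-10 * abs(brute)

    def test_site_sum_brute_force_over_alpha_range(self, bare_system):
        import nanolever.constants as c

        kap = bare_system.kappa
        g = bare_system.geometry
        vt = c.thermal_voltage_V(bare_system.env.T)
        for alpha in np.linspace(0.05, math.pi / 2, 9):
            brute = -(bare_system.electric.gamma * 0.3 / vt) * sum(
                math.exp(-kap * i * g.b * math.sin(alpha)) for i in range(1, 49)
            )
            closed = potential_energy(bare_system, alpha, 0.3)
            assert abs(closed - brute) <= 1e-10 * abs(brute)

    def test_standing_favored_under_repulsion(self, bare_system):
        # negative (repulsive) potential: free energy decreases toward pi/2
        u_low = potential_energy(bare_system, 0.05, -0.3)
        u_high = potential_energy(bare_system, math.pi / 2, -0.3)
        assert u_high < u_low

    def test_linear_in_potential(self, bare_system):
        alpha = 0.7
        u1 = potential_energy(bare_system, alpha, 0.15)
        u2 = potential_energy(bare_system, alpha, 0.30)
        assert u2 == pytest.approx(2.0 * u1, rel=1e-12)

    def test_domain_violation_rejected(self, bare_system):
        with pytest.raises(ValueError, match="domain"):
            nl.free_energy(bare_system, 0.001, 0.0)
        with pytest.raises(ValueError):
            nl.free_energy(bare_system, 2.0, 0.0)

    def test_nonfinite_phi_rejected(self, bare_system):
        with pytest.raises(ValueError):
            nl.free_energy(bare_system, 0.5, math.nan)

    def test_protein_charge_term(self, bare_system):
        charged = bare_system.with_protein(2.0, m=-5.0)
        neutral = bare_system.with_protein(2.0, m=0.0)
        alpha = 0.5
        du = potential_energy(charged, alpha, 0.3) - potential_energy(neutral, alpha, 0.3)
        # negative protein in attractive (positive) field lowers the energy
        assert du < 0


class TestStericFloor:
    def test_bare_lever_numerical_floor(self, bare_system):
        assert nl.steric_floor(bare_system) == DEFAULT_STERIC_FLOOR_RAD

    def test_two_nm_head_closed_form(self, bare_system):
        s = bare_system.with_protein(2.0)
        assert nl.steric_floor(s) == pytest.approx(math.asin(1.0 / 16.32), abs=1e-12)
        assert nl.steric_floor(s) == pytest.approx(0.0613, abs=5e-5)

    def test_monotone_in_diameter(self, bare_system):
        floors = [nl.steric_floor(bare_system.with_protein(d)) for d in (0, 1, 2, 4, 6, 8)]
        assert all(b >= a for a, b in zip(floors, floors[1:]))

    def test_oversized_head_degenerates(self, bare_system):
        with pytest.warns(UserWarning, match="steric floor"):
            s = bare_system.with_protein(2.5 * 16.32)
            assert nl.steric_floor(s) == pytest.approx(math.pi / 2)


class TestEquilibrium:
    def test_uniform_when_flat(self, bare_system, grid192):
        # no field, entropy disabled -> uniform density
        eq = nl.equilibrium_distribution(bare_system, 0.0, grid192, entropy=None)
        expected = 1.0 / (grid192.alpha_max - grid192.alpha_min)
        assert np.allclose(eq.p, expected, rtol=1e-12)

    def test_strong_repulsion_stands_lever_up(self, bare_system, grid192):
        # limiting behavior: large gamma*|phi| product overwhelms entropy
        s = nl.LeverSystem(electric=nl.ElectricModel(gamma=0.5))
        eq = nl.equilibrium_distribution(s, -5.0, nl.default_grid(s, 192))
        assert eq.mean_angle() > 0.95 * (math.pi / 2)

    def test_strong_attraction_lays_lever_down(self, bare_system, grid192):
        eq = nl.equilibrium_distribution(bare_system, 0.3, grid192)
        assert eq.mean_angle() < 0.1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        phi=st.floats(-1.0, 1.0),
        d_h=st.floats(0.0, 7.0),
        gamma=st.floats(0.001, 0.5),
        n=st.integers(64, 512),
    )
    def test_normalization_property(self, phi, d_h, gamma, n):
        s = nl.LeverSystem(
            electric=nl.ElectricModel(gamma=gamma),
            protein=nl.ProteinHead(D_H=d_h),
        )
        eq = nl.equilibrium_distribution(s, phi, nl.default_grid(s, n))
        assert abs(eq.quadrature() - 1.0) <= 1e-10
        assert np.all(eq.p >= 0)

    def test_degenerate_grid_rejected(self, bare_system):
        with pytest.raises(ValueError):
            nl.AngleGrid(alpha_min=0.01, n_points=4)

    def test_grid_below_floor_rejected(self, bare_system):
        s = bare_system.with_protein(4.0)
        bad = nl.AngleGrid(alpha_min=0.01, n_points=64)
        with pytest.raises(ValueError, match="floor"):
            nl.equilibrium_distribution(s, 0.0, bad)
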