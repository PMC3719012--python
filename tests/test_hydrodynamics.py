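"""Rod mobility, Stokes-Einstein inversion and the sizing fit."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanolever as nl
import nanolever.hydrodynamics as h


class TestRodDiffusion:
    def test_48bp_reference_value(self, bare_system):
        # end-tethered 48-bp lever in water at 298 K
        d = nl.rod_rotational_diffusion(bare_system.geometry, bare_system.env)
        assert d == pytest.approx(0.49, rel=0.10)

    def test_inverse_viscosity_scaling(self, bare_system):
        env2 = nl.Environment(eta=2 * bare_system.env.eta)
        d1 = nl.rod_rotational_diffusion(bare_system.geometry, bare_system.env)
        d2 = nl.rod_rotational_diffusion(bare_system.geometry, env2)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_strictly_decreasing_in_length(self, bare_system):
        ds = []
        for L in np.linspace(10.0, 30.0, 11):
            n_bp = 10  # keep L free of the n_bp*b constraint via explicit b
            g = nl.LeverGeometry(n_bp=n_bp, b=L / n_bp, L=L, R=1.3)
            ds.append(nl.rod_rotational_diffusion(g, bare_system.env))
        assert all(b < a for a, b in zip(ds, ds[1:]))

    def test_low_aspect_ratio_rejected(self, bare_system):
        g = nl.LeverGeometry(n_bp=10, b=0.34, R=1.3)  # L=3.4, L/2R < 2
        with pytest.raises(ValueError, match="aspect"):
            nl.rod_rotational_diffusion(g, bare_system.env)


class TestComplexFriction:
    def test_bare_head_reduces_to_dna(self, bare_system):
        z = nl.complex_friction(bare_system.geometry, bare_system.env, 0.0)
        d_dna = nl.rod_rotational_diffusion(bare_system.geometry, bare_system.env)
        assert 1.0 / z == pytest.approx(d_dna, rel=1e-12)

    def test_strictly_increasing_in_diameter(self, bare_system):
        ds = [nl.complex_friction(bare_system.geometry, bare_system.env, d)
              for d in np.linspace(0.0, 8.0, 17)]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_complex_never_faster_than_bare(self, bare_system):
        d_dna = nl.rod_rotational_diffusion(bare_system.geometry, bare_system.env)
        for dh in (0.5, 2.0, 5.0, 8.0):
            d_c = 1.0 / nl.complex_friction(bare_system.geometry, bare_system.env, dh)
            assert d_c <= d_dna


class TestDiameterInversion:
    def test_bare_mobility_maps_to_zero(self, bare_system):
        d_dna = nl.rod_rotational_diffusion(bare_system.geometry, bare_system.env)
        est = nl.diameter_from_Dr(d_dna, bare_system.geometry, bare_system.env)
        assert est.D_H == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("d_true", [0.5, 1.0, 2.0, 4.0, 6.0, 8.0])
    def test_round_trip(self, bare_system, d_true):
        d_r = 1.0 / nl.complex_friction(bare_system.geometry, bare_system.env, d_true)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = nl.diameter_from_Dr(d_r, bare_system.geometry, bare_system.env)
        assert est.D_H == pytest.approx(d_true, abs=1e-4)

    def test_too_fast_complex_rejected(self, bare_system):
        d_dna = nl.rod_rotational_diffusion(bare_system.geometry, bare_system.env)
        with pytest.raises(ValueError, match="cannot speed"):
            nl.diameter_from_Dr(1.1 * d_dna, bare_system.geometry, bare_system.env)

    def test_validity_warning_fires_above_half_length(self, bare_system):
        d_big = bare_system.geometry.L / 2.0 + 0.5
        d_r = 1.0 / nl.complex_friction(bare_system.geometry, bare_system.env, d_big)
        with pytest.warns(UserWarning, match="validity"):
            nl.diameter_from_Dr(d_r, bare_system.geometry, bare_system.env)


class TestProlateEquivalent:
    def test_sphere_limit(self):
        assert nl.prolate_equivalent_diameter(4.0, 4.0, 4.0) == pytest.approx(4.0)

    def test_permutation_invariance(self):
        d = nl.prolate_equivalent_diameter(3.0, 5.0, 2.0)
        for axes in [(5, 3, 2), (2, 3, 5), (3, 2, 5)]:
            assert nl.prolate_equivalent_diameter(*axes) == pytest.approx(d)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(x=st.floats(0.5, 20.0), y=st.floats(0.5, 20.0), z=st.floats(0.5, 20.0))
    def test_between_short_and_long_axis(self, x, y, z):
        lo, mid, hi = sorted((x, y, z))
        b2 = math.sqrt(mid * lo)
        d = nl.prolate_equivalent_diameter(x, y, z)
        assert b2 - 1e-9 <= d <= hi + 1e-9

    def test_nonpositive_axes_rejected(self):
        with pytest.raises(ValueError):
            nl.prolate_equivalent_diameter(1.0, -2.0, 3.0)

    def test_ubiquitin_scale(self):
        # a small globular protein (~3x4x5 nm bounding box region) sizes ~2-4 nm
        d = nl.prolate_equivalent_diameter(2.5, 3.0, 4.5)
        assert 2.0 < d < 4.5


class TestViscosityScaling:
    def test_identity_and_halving(self):
        assert nl.viscosity_scaling(0.49, 0.89e-3, 0.89e-3) == 0.49
        assert nl.viscosity_scaling(0.49, 0.89e-3, 1.78e-3) == pytest.approx(0.245)

    def test_invalid_viscosity_rejected(self):
        with pytest.raises(ValueError):
            nl.viscosity_scaling(0.49, 0.0, 1.0)


class TestTraceFit:
    def test_noise_free_self_consistency(self, bare_system, fast_settings, quenching):
        # forward-simulate at a known D_r, refit: recovery to ~1e-3/us
        from nanolever.fokker_planck import switching_cycle

        d_true = 0.30
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est0 = nl.diameter_from_Dr(d_true, bare_system.geometry, bare_system.env)
            s = bare_system.with_protein(est0.D_H)
        up, _ = switching_cycle(s, d_true, fast_settings, grid=nl.default_grid(s, 192))
        tr = nl.fluorescence_trace(up, s, quenching, "up", normalize="equilibrium")
        est = nl.fit_Dr_from_trace(tr, bare_system, compute_ci=False)
        assert est.D_r_comp == pytest.approx(d_true, abs=1e-3)
        assert est.residual < 1e-5

    def test_slower_trace_yields_positive_diameter(self, bare_system, fast_settings,
                                                   quenching):
        from nanolever.fokker_planck import switching_cycle

        d_slow = 0.20
        s = bare_system.with_protein(4.0)
        up, _ = switching_cycle(s, d_slow, fast_settings, grid=nl.default_grid(s, 192))
        tr = nl.fluorescence_trace(up, s, quenching, "up", normalize="equilibrium")
        est = nl.fit_Dr_from_trace(tr, bare_system, compute_ci=False)
        assert est.D_H > 0.0

    def test_unnormalized_trace_rejected(self, bare_system):
        t = np.arange(0.0, 12.0, 0.032)
        tr = nl.TimeResolvedTrace(t, np.linspace(0, 900, t.size), "up", {})
        with pytest.raises(ValueError, match="normalized"):
            nl.fit_Dr_from_trace(tr, bare_system)
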