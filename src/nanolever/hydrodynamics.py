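"""Rotational hydrodynamics: rod mobility, diameter inversion, trace fitting.

The bare lever's rotational diffusion coefficient about its tethered end,
D_r^DNA, follows the Tirado-Garcia de la Torre cylinder result combined
with the image-rod construction: a rod of length L pivoting on a plane is
the upper half of a rod of length 2L rotating end-over-end about its
center, so

    D_r^DNA = 3 k_B T [ln(L/R) + delta(L/R)] / (4 pi eta L^3),
    delta(p) = -0.662 + 0.917/p - 0.050/p^2,

where the aspect ratio of the doubled rod is 2L/2R = L/R.  This yields
0.493 /us for the default 48-bp lever in water at 298 K.  The prefactor
1/4 (vs 3/(pi eta L^3) for center rotation at aspect L/2R) is the
end-rotation correction: the friction moment of a rod about its end is
four times that about its center.

A protein head of hydrodynamic diameter D_H adds the Stokes drag of a
sphere translating at lever arm (L + D_H/2):

    zeta_comp = zeta_DNA + 3 pi eta D_H (L + D_H/2)^2,

and the modified Stokes-Einstein relation D_r^comp = k_B T / zeta_comp is
inverted numerically for D_H.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import constants as c
from .fluorescence import QuenchingModel, TimeResolvedTrace, fluorescence_trace
from .model import (
    AngleGrid,
    Environment,
    LeverGeometry,
    LeverSystem,
    default_grid,
    equilibrium_distribution,
    rod_entropy,
)

__all__ = [
    "SizeEstimate",
    "rod_rotational_diffusion",
    "complex_friction",
    "diameter_from_Dr",
    "fit_Dr_from_trace",
    "prolate_equivalent_diameter",
    "viscosity_scaling",
]

#: default fitting window (us) and grid size for the sizing pipeline
FIT_WINDOW_US = (0.0, 12.0)
FIT_GRID_POINTS = 192


@dataclass
class SizeEstimate:
    """Result of a hydrodynamic sizing fit/inversion."""

    D_r_comp: float  # 1/us
    D_r_dna: float  # 1/us
    D_H: float  # nm
    residual: Optional[float] = None  # sum of squared trace residuals
    ci: Optional[Tuple[float, float]] = None  # ~95% interval on D_H, nm
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.D_r_comp > self.D_r_dna * (1 + 1e-9):
            raise ValueError("D_r_comp cannot exceed D_r_dna")
        if self.D_H < 0:
            raise ValueError("D_H must be non-negative")


def _end_over_end_correction(p: float) -> float:
    """Tirado-de la Torre end-effect correction for end-over-end rotation."""
    return -0.662 + 0.917 / p - 0.050 / p**2


def rod_rotational_diffusion(geometry: LeverGeometry, env: Environment) -> float:
    """Rotational diffusion coefficient of the end-tethered rod, 1/us."""
    L, R = geometry.L, geometry.R
    if L / (2.0 * R) < 2.0:
        raise ValueError(
            f"aspect ratio L/(2R)={L / (2 * R):.3g} < 2: outside the "
            "validity range of the cylinder formula"
        )
    p = L / R  # aspect ratio of the mirrored rod, 2L/(2R)
    ln_term = math.log(p) + _end_over_end_correction(p)
    L_m = L * c.M_PER_NM
    D_si = 3.0 * c.thermal_energy_J(env.T) * ln_term / (
        4.0 * math.pi * env.eta * L_m**3
    )
    return D_si * c.S_PER_US  # 1/s -> 1/us


def complex_friction(
    geometry: LeverGeometry, env: Environment, D_H: float
) -> float:
    """Rotational friction of the lever-protein complex, in k_B*T*us.

    zeta_comp = zeta_DNA + zeta_head with zeta_head the Stokes drag
    3 pi eta D_H of a sphere of diameter D_H translating on the lever arm
    (L + D_H/2); strictly increasing in D_H.
    """
    if D_H < 0:
        raise ValueError("D_H must be non-negative")
    zeta_dna = 1.0 / rod_rotational_diffusion(geometry, env)  # kT*us
    arm_m = (geometry.L + D_H / 2.0) * c.M_PER_NM
    zeta_head_si = 3.0 * math.pi * env.eta * (D_H * c.M_PER_NM) * arm_m**2  # J*s... N*s*m
    # convert J*s -> kT*us
    zeta_head = zeta_head_si / c.thermal_energy_J(env.T) * c.US_PER_S
    return zeta_dna + zeta_head


def diameter_from_Dr(
    D_r_comp: float,
    geometry: LeverGeometry,
    env: Environment,
    tol: float = 1e-4,
) -> SizeEstimate:
    """Invert the modified Stokes-Einstein relation for D_H (nm).

    Root-finds D_H in [0, L] such that 1/zeta_comp(D_H) = D_r_comp,
    by bracketed Brent iteration to `tol` nm.
    """
    D_dna = rod_rotational_diffusion(geometry, env)
    if D_r_comp <= 0:
        raise ValueError("D_r_comp must be positive")
    if D_r_comp > D_dna * (1 + 1e-9):
        raise ValueError(
            f"D_r_comp={D_r_comp:.4g}/us exceeds D_r_dna={D_dna:.4g}/us: a "
            "bound protein cannot speed up the lever"
        )
    f = lambda d: 1.0 / complex_friction(geometry, env, d) - D_r_comp
    if f(0.0) <= 0.0:  # D_r_comp >= D_dna within tolerance
        d_star = 0.0
    elif f(geometry.L) > 0.0:
        raise ValueError(
            f"D_r_comp={D_r_comp:.4g}/us is slower than a head of diameter "
            f"L={geometry.L} nm allows; no solution in [0, L]"
        )
    else:
        d_star = brentq(f, 0.0, geometry.L, xtol=tol)
    if d_star >= geometry.L / 2.0:
        warnings.warn(
            f"D_H={d_star:.3g} nm >= L/2={geometry.L / 2:.3g} nm: outside "
            "the quantitative sizing validity range",
            stacklevel=2,
        )
    return SizeEstimate(D_r_comp=D_r_comp, D_r_dna=D_dna, D_H=float(d_star))


def _simulated_up_trace(
    system: LeverSystem,
    D_r: float,
    t_end: float,
    settings,
    quenching: QuenchingModel,
    n_points: int,
    output_dt: float,
    entropy,
) -> TimeResolvedTrace:
    from .fokker_planck import evolve  # local import to avoid cycle

    grid = default_grid(system, n_points=n_points)
    p0 = equilibrium_distribution(
        system, system.electric.phi_down, grid, entropy=entropy
    )
    snaps = evolve(p0, system, D_r, "up", t_end, settings, output_dt, entropy=entropy)
    return fluorescence_trace(
        snaps, system, quenching, direction="up", normalize="equilibrium",
        entropy=entropy,
    )


def fit_Dr_from_trace(
    measured: TimeResolvedTrace,
    system: LeverSystem,
    settings=None,
    quenching: Optional[QuenchingModel] = None,
    fit_window: Tuple[float, float] = FIT_WINDOW_US,
    n_points: int = FIT_GRID_POINTS,
    compute_ci: bool = True,
    entropy=rod_entropy,
) -> SizeEstimate:
    """Fit D_r^comp to a measured normalized upward trace; invert to D_H.

    One-parameter least-squares fit: for each candidate D_r the steric
    floor is made self-consistent (D_r -> D_H by Stokes-Einstein inversion
    -> hard-wall floor), the upward half-cycle is simulated from the lying
    equilibrium, converted to normalized fluorescence, and compared with
    the measurement on its own time bins within `fit_window`.  All
    non-D_r parameters (geometry, drive, quenching) stay fixed.
    """
    from .fokker_planck import SolverSettings

    if settings is None:
        settings = SolverSettings.fast()
    if quenching is None:
        quenching = QuenchingModel()
    if not measured.is_normalized:
        raise ValueError("measured trace must be normalized (F_norm)")
    if measured.direction != "up":
        raise ValueError("sizing fit expects an upward half-cycle trace")

    geometry, env = system.geometry, system.env
    D_dna = rod_rotational_diffusion(geometry, env)
    D_lo = 1.0 / complex_friction(geometry, env, geometry.L)

    t_hi = min(fit_window[1], float(measured.times[-1]))
    t_lo = max(fit_window[0], float(measured.times[0]))
    sel = (measured.times >= t_lo) & (measured.times <= t_hi)
    t_obs = measured.times[sel]
    y_obs = measured.values[sel]
    if t_obs.size < 10:
        raise ValueError("fewer than 10 trace points inside the fit window")

    def sse(D_r: float) -> float:
        D_r = min(max(D_r, D_lo), D_dna)
        with warnings.catch_warnings():
            # interior probes near the slow bound trip the validity warning
            warnings.simplefilter("ignore")
            est = diameter_from_Dr(D_r, geometry, env)
            sys_d = system.with_protein(est.D_H)
            sim = _simulated_up_trace(
                sys_d, D_r, t_hi, settings, quenching, n_points,
                measured.bin_width, entropy,
            )
        y_sim = np.interp(t_obs, sim.times, sim.values)
        return float(np.sum((y_sim - y_obs) ** 2))

    res = minimize_scalar(
        sse, bounds=(D_lo, D_dna), method="bounded",
        options={"xatol": 5e-4},
    )
    D_fit = float(res.x)
    converged = bool(res.success)
    message = ""
    span = D_dna - D_lo
    if D_fit - D_lo < 1e-3 * span or D_dna - D_fit < 1e-3 * span:
        warnings.warn(
            f"fitted D_r={D_fit:.4g}/us lies at a parameter bound", stacklevel=2
        )
        message = "fit at parameter bound"
    if not converged:
        message = (message + "; " if message else "") + "optimizer did not converge"
        warnings.warn("sizing fit did not converge: " + str(res), stacklevel=2)

    est = diameter_from_Dr(min(D_fit, D_dna), geometry, env)
    ci = None
    if compute_ci:
        ci = _curvature_ci(sse, D_fit, res.fun, t_obs.size, geometry, env,
                           D_lo, D_dna)
    return SizeEstimate(
        D_r_comp=est.D_r_comp, D_r_dna=est.D_r_dna, D_H=est.D_H,
        residual=float(res.fun), ci=ci, converged=converged, message=message,
    )


def _curvature_ci(sse, D_fit, sse_min, n_obs, geometry, env, D_lo, D_dna):
    """~95% interval on D_H from the local curvature of the SSE profile."""
    delta = max(0.02 * D_fit, 1e-3)
    lo, hi = max(D_fit - delta, D_lo), min(D_fit + delta, D_dna)
    if hi - lo < delta:  # at a bound; one-sided curvature is unreliable
        return None
    s_lo, s_hi = sse(lo), sse(hi)
    curv = (s_lo - 2.0 * sse_min + s_hi) / ((hi - lo) / 2.0) ** 2
    if curv <= 0:
        return None
    sigma2 = sse_min / max(n_obs - 1, 1)
    var_dr = 2.0 * sigma2 / curv
    sd_dr = math.sqrt(var_dr)
    # propagate through the inversion numerically
    step = max(min(sd_dr, 0.05 * D_fit), 1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_ctr = diameter_from_Dr(D_fit, geometry, env).D_H
        d_minus = diameter_from_Dr(min(max(D_fit - step, D_lo), D_dna), geometry, env).D_H
        d_plus = diameter_from_Dr(min(D_fit + step, D_dna), geometry, env).D_H
    slope = abs(d_plus - d_minus) / (2.0 * step)
    half_width = 1.96 * sd_dr * slope
    return (max(d_ctr - half_width, 0.0), d_ctr + half_width)


def prolate_equivalent_diameter(x: float, y: float, z: float) -> float:
    """Perrin translational-equivalent sphere diameter of a prolate ellipsoid.

    The bounding-box dimensions (nm) are sorted; the long semi-axis is
    a = max/2 and the short semi-axis the geometric mean of the two short
    dimensions, b = sqrt(mid*min)/2.  With eccentricity
    xi = sqrt(1 - (b/a)^2):

        D_H = 2 a xi / ln[(1 + xi) / (b/a)],

    reducing to the sphere diameter 2a as b -> a (handled by series).
    """
    if x <= 0 or y <= 0 or z <= 0:
        raise ValueError("axes must be positive")
    lo, mid, hi = sorted((x, y, z))
    a = hi / 2.0
    b = math.sqrt(mid * lo) / 2.0
    q = b / a
    xi2 = 1.0 - q * q
    if xi2 < 1e-8:
        return 2.0 * a * (1.0 - xi2 / 3.0)
    xi = math.sqrt(xi2)
    return 2.0 * a * xi / math.log((1.0 + xi) / q)


def viscosity_scaling(D_r: float, eta_ref: float, eta_new: float) -> float:
    """Rescale a rotational diffusion coefficient to a new viscosity."""
    if eta_ref <= 0 or eta_new <= 0:
        raise ValueError("viscosities must be positive")
    return D_r * eta_ref / eta_new
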