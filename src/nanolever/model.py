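"""Physical model of an electro-switchable DNA nanolever ("lollipop" model).

A short double-stranded DNA lever is end-tethered to a gold microelectrode
and carries an optional globular protein head at its distal end.  The
electrode potential, screened exponentially over the Debye length of the
electrolyte, exerts a torque on the charged lever; together with the
orientational entropy of a rod pivoting on a plane this defines an
angle-dependent free energy

    G(alpha) = U(alpha) - T*S(alpha)

where alpha is the out-of-plane angle (alpha = pi/2 is standing upright).
U sums the screened electrostatic energy of one effective charge site per
base pair plus the protein charge; S(alpha) = k_B ln(cos alpha) is the
solid-angle density of rod orientations on the hemisphere.

All energies are expressed in units of k_B*T, lengths in nm, times in
microseconds (see `constants`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import constants as c

__all__ = [
    "LeverGeometry",
    "ElectricModel",
    "ProteinHead",
    "Environment",
    "LeverSystem",
    "AngleGrid",
    "AngularDistribution",
    "electrode_potential",
    "free_energy",
    "potential_energy",
    "rod_entropy",
    "steric_floor",
    "equilibrium_distribution",
    "default_grid",
]

#: numerical floor (rad) for a bare lever; keeps ln(cos) and the charge-site
#: geometric series away from the exact alpha=0 degeneracy
DEFAULT_STERIC_FLOOR_RAD = 0.01


@dataclass
class LeverGeometry:
    """Rigid-rod geometry of the DNA lever.

    Defaults describe the 48-bp lever: base-pair spacing b = 0.34 nm,
    contour length L = 16.32 nm, hydrodynamic rod radius R = 1.3 nm.
    """

    n_bp: int = 48
    b: float = 0.34  # nm
    L: Optional[float] = None  # nm; defaults to n_bp * b
    R: float = 1.3  # nm

    def __post_init__(self) -> None:
        if self.L is None:
            self.L = self.n_bp * self.b
        if self.n_bp <= 0 or self.b <= 0 or self.L <= 0 or self.R <= 0:
            raise ValueError("all geometry fields must be positive")
        if abs(self.L - self.n_bp * self.b) > 1e-9:
            raise ValueError(
                f"inconsistent geometry: L={self.L} nm but n_bp*b="
                f"{self.n_bp * self.b} nm"
            )


@dataclass
class ElectricModel:
    """Electrode drive: screened surface field and exponential charging.

    Potentials are effective surface potentials relative to the
    potential-of-zero-charge.  The electrode charges exponentially with
    time constant tau = 4*RC/3 (the 4/3 arises from area weighting of the
    circular microelectrode).  gamma is a dimensionless screening/attenuation
    parameter absorbing counterion condensation and field attenuation.
    """

    gamma: float = 0.016
    kappa: Optional[float] = None  # nm^-1; derived from Environment if None
    phi_up: float = -0.3  # V, repulsive plateau (lever standing)
    phi_down: float = +0.3  # V, attractive plateau (lever lying)
    RC: float = 0.3e-6  # s
    frequency: float = 1.0e4  # Hz

    def __post_init__(self) -> None:
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.RC <= 0 or self.frequency <= 0:
            raise ValueError("RC and frequency must be positive")
        if self.half_period < 10.0 * self.tau:
            warnings.warn(
                "half-period {:.3g} s is shorter than 10*tau={:.3g} s; the "
                "electrode does not fully charge within a half-cycle".format(
                    self.half_period, 10.0 * self.tau
                ),
                stacklevel=2,
            )

    @property
    def tau(self) -> float:
        """Charging time constant tau = 4*RC/3, seconds (exact)."""
        return 4.0 * self.RC / 3.0

    @property
    def tau_us(self) -> float:
        return self.tau * c.US_PER_S

    @property
    def half_period(self) -> float:
        """Half-period of the square-wave drive, seconds."""
        return 1.0 / (2.0 * self.frequency)

    @property
    def half_period_us(self) -> float:
        return self.half_period * c.US_PER_S


@dataclass
class ProteinHead:
    """Spherical protein head at the lever tip.

    D_H is the effective hydrodynamic diameter in nm (0 = bare DNA); m is
    the protein charge in multiples of the elementary charge (signed).
    """

    D_H: float = 0.0  # nm
    m: float = 0.0  # elementary charges

    def __post_init__(self) -> None:
        if self.D_H < 0:
            raise ValueError("D_H must be non-negative")


@dataclass
class Environment:
    """Solution conditions: temperature, viscosity, ionic strength."""

    T: float = c.DEFAULT_TEMPERATURE_K  # K
    eta: float = c.DEFAULT_VISCOSITY_PA_S  # Pa*s
    ionic_strength: float = c.DEFAULT_IONIC_STRENGTH_MM  # mM

    def __post_init__(self) -> None:
        if self.T <= 0 or self.eta <= 0 or self.ionic_strength <= 0:
            raise ValueError("T, eta and ionic_strength must be positive")

    @property
    def debye_length_nm(self) -> float:
        return c.debye_length_nm(self.ionic_strength)

    @property
    def kappa_nm(self) -> float:
        """Inverse Debye length, nm^-1."""
        return 1.0 / self.debye_length_nm


@dataclass
class LeverSystem:
    """Complete parameterization: lever + protein head + solution + drive."""

    geometry: LeverGeometry = field(default_factory=LeverGeometry)
    electric: ElectricModel = field(default_factory=ElectricModel)
    protein: ProteinHead = field(default_factory=ProteinHead)
    env: Environment = field(default_factory=Environment)

    def __post_init__(self) -> None:
        if self.protein.D_H >= self.geometry.L / 2.0:
            warnings.warn(
                "protein D_H={:.3g} nm >= L/2={:.3g} nm: outside the "
                "quantitative sizing validity range".format(
                    self.protein.D_H, self.geometry.L / 2.0
                ),
                stacklevel=2,
            )

    @property
    def kappa(self) -> float:
        """Inverse Debye length in nm^-1 (explicit value or derived)."""
        if self.electric.kappa is not None:
            return self.electric.kappa
        return self.env.kappa_nm

    def with_protein(self, D_H: float, m: Optional[float] = None) -> "LeverSystem":
        """Copy of this system with a different protein head."""
        head = ProteinHead(D_H=D_H, m=self.protein.m if m is None else m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return LeverSystem(self.geometry, self.electric, head, self.env)


# ---------------------------------------------------------------------------
# angular grid and distribution containers
# ---------------------------------------------------------------------------


@dataclass
class AngleGrid:
    """Uniform cell-centered grid on [alpha_min, alpha_max=pi/2].

    The domain is divided into n_points equal cells; densities live at the
    cell centers and quadrature is the midpoint rule sum(p)*spacing, which
    is the measure conserved exactly by the finite-volume solver.
    """

    alpha_min: float
    alpha_max: float = math.pi / 2.0
    n_points: int = 256

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_min < self.alpha_max):
            raise ValueError("need 0 <= alpha_min < alpha_max")
        if self.n_points < 8:
            raise ValueError("degenerate grid: need at least 8 points")

    @property
    def spacing(self) -> float:
        return (self.alpha_max - self.alpha_min) / self.n_points

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.alpha_min, self.alpha_max, self.n_points + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class AngularDistribution:
    """Probability density p(alpha) on an AngleGrid, in rad^-1."""

    grid: AngleGrid
    p: np.ndarray
    time: float = 0.0  # us

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.grid.n_points,):
            raise ValueError("density shape does not match grid")
        if np.any(self.p < -1e-12):
            raise ValueError("density has negative values")

    def quadrature(self) -> float:
        """Midpoint-rule integral of p over the grid."""
        return float(np.sum(self.p) * self.grid.spacing)

    def normalized(self) -> "AngularDistribution":
        q = self.quadrature()
        if q <= 0:
            raise ValueError("cannot normalize a zero density")
        return AngularDistribution(self.grid, self.p / q, self.time)

    def mean_angle(self) -> float:
        return float(np.sum(self.grid.centers * self.p) * self.grid.spacing)

    def variance(self) -> float:
        mu = self.mean_angle()
        return float(
            np.sum((self.grid.centers - mu) ** 2 * self.p) * self.grid.spacing
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def electrode_potential(electric: ElectricModel, t, direction: str):
    """Effective electrode potential Phi(t) during one switching half-cycle.

    The square-wave edge at t=0 starts an exponential charging process
    Phi(t) = Phi_target + (Phi_start - Phi_target) * exp(-t/tau) with
    tau = 4*RC/3.  For direction "up" the electrode charges from the
    attractive plateau phi_down toward the repulsive plateau phi_up;
    "down" is the reverse.

    Parameters
    ----------
    t : float or array, seconds since the switching edge (>= 0)
    direction : "up" or "down"
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if direction == "up":
        start, target = electric.phi_down, electric.phi_up
    elif direction == "down":
        start, target = electric.phi_up, electric.phi_down
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    phi = target + (start - target) * np.exp(-t / electric.tau)
    return float(phi) if phi.ndim == 0 else phi


def rod_entropy(alpha) -> np.ndarray:
    """Orientational entropy S(alpha)/k_B = ln(cos alpha) of a pivoting rod.

    Rod orientations uniform on the hemisphere have solid-angle density
    proportional to cos(alpha) in the out-of-plane angle, hence this form.
    Swappable: `free_energy` accepts any callable of the same signature.
    """
    return np.log(np.cos(np.asarray(alpha, dtype=float)))


def _site_sum(n_bp: int, x) -> np.ndarray:
    """Closed form of sum_{i=1..n} exp(-i*x) for x > 0 (geometric series)."""
    x = np.asarray(x, dtype=float)
    # exp(-x) * (1 - exp(-n x)) / (1 - exp(-x)), written with expm1 for
    # stability as x -> 0
    return np.exp(-x) * np.expm1(-n_bp * x) / np.expm1(-x)


def potential_energy(system: LeverSystem, alpha, phi: float):
    """Electrostatic energy U(alpha) in k_B*T units at surface potential phi.

    One effective charge of -e per base pair at height z_i = i*b*sin(alpha),
    each coupled to the screened field gamma*phi*exp(-kappa*z), plus the
    protein charge m*e at the lever tip z = L*sin(alpha).
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    alpha = np.asarray(alpha, dtype=float)
    g = system.geometry
    kappa = system.kappa
    vt = c.thermal_voltage_V(system.env.T)
    s = np.sin(alpha)
    u_dna = -(system.electric.gamma * phi / vt) * _site_sum(g.n_bp, kappa * g.b * s)
    u_prot = (
        system.protein.m
        * (system.electric.gamma * phi / vt)
        * np.exp(-kappa * g.L * s)
    )
    return u_dna + u_prot


def free_energy(
    system: LeverSystem,
    alpha,
    phi: float,
    entropy: Optional[Callable] = rod_entropy,
):
    """Free energy G(alpha) = U(alpha) - T*S(alpha), in k_B*T units.

    `entropy` is a callable alpha -> S/k_B (default: pivoting-rod hemisphere
    entropy); pass None to disable the entropic term.
    """
    alpha_arr = np.asarray(alpha, dtype=float)
    amin = steric_floor(system)
    if np.any(alpha_arr < amin - 1e-12) or np.any(alpha_arr > math.pi / 2 + 1e-12):
        raise ValueError(
            f"alpha outside domain [{amin:.4g}, pi/2] for this system"
        )
    g = potential_energy(system, alpha_arr, phi)
    if entropy is not None:
        g = g - entropy(alpha_arr)
    return float(g) if np.ndim(alpha) == 0 else g


def steric_floor(system: LeverSystem) -> float:
    """Smallest allowed out-of-plane angle (hard-wall exclusion), rad.

    The sphere center at the lever tip must stay at least D_H/2 above the
    surface: sin(alpha) >= (D_H/2)/L.  For a bare lever a small numerical
    floor avoids the alpha=0 degeneracy.  Monotone increasing in D_H.
    """
    d = system.protein.D_H
    if d <= 0:
        return DEFAULT_STERIC_FLOOR_RAD
    ratio = (d / 2.0) / system.geometry.L
    if ratio >= 1.0:
        warnings.warn(
            "protein sphere larger than the lever can lift (D_H/2 >= L); "
            "steric floor degenerates to pi/2",
            stacklevel=2,
        )
        return math.pi / 2.0
    return max(math.asin(ratio), DEFAULT_STERIC_FLOOR_RAD)


def default_grid(system: LeverSystem, n_points: int = 256) -> AngleGrid:
    """Grid spanning the allowed angular domain of `system`."""
    return AngleGrid(alpha_min=steric_floor(system), n_points=n_points)


def equilibrium_distribution(
    system: LeverSystem,
    phi: float,
    grid: AngleGrid,
    entropy: Optional[Callable] = rod_entropy,
) -> AngularDistribution:
    """Boltzmann distribution p(alpha) ~ exp(-G(alpha)/k_B T) on `grid`.

    Normalized so the midpoint-rule quadrature equals 1.  Overflow-safe via
    subtraction of the minimum free energy.
    """
    amin = steric_floor(system)
    if grid.alpha_min < amin - 1e-9:
        raise ValueError(
            f"grid starts at {grid.alpha_min:.4g} rad, below the steric "
            f"floor {amin:.4g} rad"
        )
    G = free_energy(system, grid.centers, phi, entropy=entropy)
    G = np.asarray(G, dtype=float)
    w = np.exp(-(G - G.min()))
    p = w / (w.sum() * grid.spacing)
    return AngularDistribution(grid, p, time=0.0)
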