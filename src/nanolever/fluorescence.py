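"""Fluorescence conversion and the Dynamic Response (DR) statistic.

The Cy3 dye at the lever tip is quenched by near-field energy transfer to
the gold surface; the quantum yield f(z) rises monotonically with the tip
height z = L*sin(alpha).  An angular distribution p(alpha, t) therefore
maps to a fluorescence signal

    F(t) = integral p(alpha, t) * f(L sin alpha) dalpha,

which, after min-max normalization between the lying and standing plateau
levels, yields F_norm(t).  The DR is the area under F_norm during upward
switching (or the area above it during downward switching) within a time
window; it gauges the swiftness of the lever motion and is insensitive to
the absolute fluorescence intensity and to unmodulated background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import AngularDistribution, LeverSystem, equilibrium_distribution, rod_entropy

__all__ = [
    "QuenchingModel",
    "TimeResolvedTrace",
    "DRResult",
    "quantum_yield",
    "fluorescence_trace",
    "normalize_trace_pair",
    "dynamic_response",
    "relative_switching_amplitude",
]

#: default photon-counting bin width, us (32 ns TCSPC resolution)
DEFAULT_BIN_WIDTH_US = 0.032

#: default DR integration windows, us
SIZING_WINDOW = (0.0, 3.0)
MIXTURE_WINDOW = (3.0, 9.0)


@dataclass
class QuenchingModel:
    """Distance dependence of the fluorescence quantum yield near gold.

    Default: f(z) = floor + (1 - floor) * z^n / (z^n + z0^n) with n = 4
    (near-metal energy-transfer scaling) and characteristic distance
    z0 = 6 nm, placing the sensitive range across the 0-16 nm height span
    of a 48-bp lever.  The calibration is instrument-specific; treat these
    as fixed configuration, never co-fitted with D_r.
    """

    model: str = "power-law"
    z0: float = 6.0  # nm
    n: float = 4.0
    floor: float = 0.02

    def __post_init__(self) -> None:
        if self.z0 <= 0 or self.n <= 0:
            raise ValueError("z0 and n must be positive")
        if not (0.0 <= self.floor < 1.0):
            raise ValueError("yield floor must be in [0, 1)")
        if self.model != "power-law":
            raise ValueError(f"unknown quenching model {self.model!r}")


def quantum_yield(q: QuenchingModel, z):
    """Fluorescence quantum yield at height z (nm) above the surface.

    Monotone non-decreasing in z, -> 1 as z -> infinity, -> floor as z -> 0.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("height z must be non-negative")
    with np.errstate(over="ignore"):
        ratio = (z / q.z0) ** q.n
        f = q.floor + (1.0 - q.floor) * ratio / (ratio + 1.0)
    f = np.where(np.isinf(ratio), 1.0, f)
    return float(f) if f.ndim == 0 else f


@dataclass
class TimeResolvedTrace:
    """Time-binned fluorescence of one switching half-cycle.

    times are left bin edges (us, uniform spacing); values are either raw
    counts or normalized fluorescence F_norm.  metadata carries the drive
    parameters (direction is duplicated there when written to file).
    """

    times: np.ndarray  # us, left edges
    values: np.ndarray
    direction: str  # "up" | "down"
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size < 2:
            raise ValueError("trace needs at least two bins")
        widths = np.diff(self.times)
        if not np.allclose(widths, widths[0], rtol=1e-6, atol=1e-12):
            raise ValueError("bin width must be uniform")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        self.metadata.setdefault("bin_width_us", float(widths[0]))

    @property
    def bin_width(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def is_normalized(self) -> bool:
        return bool(self.metadata.get("normalized", False))

    def copy_with(self, values: np.ndarray, **meta) -> "TimeResolvedTrace":
        md = dict(self.metadata)
        md.update(meta)
        return TimeResolvedTrace(self.times.copy(), values, self.direction, md)


@dataclass
class DRResult:
    """Dynamic Response: normalized-height x time area within a window."""

    value: float  # us
    direction: str
    window: Tuple[float, float]  # us
    normalization: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        length = self.window[1] - self.window[0]
        if not (-1e-9 <= self.value <= length + 1e-9):
            raise ValueError(
                f"DR={self.value} us outside [0, {length}] for window {self.window}"
            )
        self.value = float(min(max(self.value, 0.0), length))


def fluorescence_trace(
    dists: Sequence[AngularDistribution],
    system: LeverSystem,
    q: QuenchingModel,
    direction: str = "up",
    normalize: Optional[str] = "equilibrium",
    entropy=rod_entropy,
) -> TimeResolvedTrace:
    """Convert a snapshot sequence to a time-resolved fluorescence trace.

    F(t) = sum_j p_j(t) f(L sin alpha_j) h  (midpoint quadrature).

    normalize:
      - "equilibrium": min-max normalize with the exact Boltzmann plateau
        fluorescence at phi_down (lying, minimum) and phi_up (standing,
        maximum); appropriate for simulated traces.
      - "self": plateaus estimated from the trace itself (mean of the final
        10 % of the half-cycle as the arriving plateau, the t=0 value as
        the departing plateau).
      - None: raw, unnormalized F.
    """
    if not dists:
        raise ValueError("empty snapshot sequence")
    grid = dists[0].grid
    for d in dists:
        if abs(d.quadrature() - 1.0) > 1e-6:
            raise ValueError("snapshot densities must be normalized")
    heights = system.geometry.L * np.sin(grid.centers)
    f_alpha = quantum_yield(q, heights)
    h = grid.spacing
    times = np.array([d.time for d in dists])
    F = np.array([float(np.sum(d.p * f_alpha) * h) for d in dists])

    meta: Dict[str, object] = {
        "frequency_hz": system.electric.frequency,
        "bin_width_us": float(times[1] - times[0]),
    }
    if normalize is None:
        return TimeResolvedTrace(times, F, direction, meta)
    if normalize == "equilibrium":
        F_lo = _plateau_fluorescence(system, q, system.electric.phi_down, grid, f_alpha, entropy)
        F_hi = _plateau_fluorescence(system, q, system.electric.phi_up, grid, f_alpha, entropy)
    elif normalize == "self":
        n_tail = max(2, int(0.1 * F.size))
        tail = float(np.mean(F[-n_tail:]))
        head = float(F[0])
        if direction == "up":
            F_lo, F_hi = head, tail
        else:
            F_lo, F_hi = tail, head
    else:
        raise ValueError(f"unknown normalization mode {normalize!r}")
    if not F_hi > F_lo:
        raise ValueError("degenerate plateaus: F_max <= F_min")
    F_norm = (F - F_lo) / (F_hi - F_lo)
    meta.update(normalized=True, F_min_plateau=F_lo, F_max_plateau=F_hi,
                normalization=normalize)
    return TimeResolvedTrace(times, F_norm, direction, meta)


def _plateau_fluorescence(system, q, phi, grid, f_alpha, entropy) -> float:
    eq = equilibrium_distribution(system, phi, grid, entropy=entropy)
    return float(np.sum(eq.p * f_alpha) * grid.spacing)


def normalize_trace_pair(
    up: TimeResolvedTrace,
    down: TimeResolvedTrace,
    plateau_fraction: float = 0.1,
) -> Tuple[TimeResolvedTrace, TimeResolvedTrace]:
    """Min-max normalize a measured (up, down) half-cycle pair.

    The standing plateau is the mean of the final `plateau_fraction` of the
    upward trace, the lying plateau the same fraction of the downward
    trace.  Because the normalization is affine, any constant unmodulated
    background and any overall intensity scale cancel exactly.
    """
    if up.direction != "up" or down.direction != "down":
        raise ValueError("expected an (up, down) trace pair")
    n_up = max(2, int(plateau_fraction * up.values.size))
    n_dn = max(2, int(plateau_fraction * down.values.size))
    F_hi = float(np.mean(up.values[-n_up:]))
    F_lo = float(np.mean(down.values[-n_dn:]))
    if not F_hi > F_lo:
        raise ValueError("degenerate plateaus: standing level <= lying level")
    scale = F_hi - F_lo
    meta = dict(normalized=True, F_min_plateau=F_lo, F_max_plateau=F_hi,
                normalization="pair-final-{:g}".format(plateau_fraction))
    return (
        up.copy_with((up.values - F_lo) / scale, **meta),
        down.copy_with((down.values - F_lo) / scale, **meta),
    )


def dynamic_response(
    trace: TimeResolvedTrace,
    window: Tuple[float, float] = SIZING_WINDOW,
) -> DRResult:
    """Dynamic Response of a normalized trace over a time window (us).

    Upward: DR = integral of F_norm; downward: DR = integral of
    (1 - F_norm); trapezoidal quadrature on the bin grid.  High DR means
    fast switching in both directions.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must have positive length")
    if t0 < trace.times[0] - 1e-9 or t1 > trace.times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside trace support "
            f"[{trace.times[0]}, {trace.times[-1]}] us"
        )
    inner = trace.times[(trace.times > t0) & (trace.times < t1)]
    ts = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(ts, trace.times, trace.values)
    if trace.direction == "down":
        vals = 1.0 - vals
    area = float(np.trapezoid(vals, ts))
    return DRResult(
        value=min(max(area, 0.0), t1 - t0),
        direction=trace.direction,
        window=(t0, t1),
        normalization=dict(trace.metadata),
    )


def relative_switching_amplitude(F_repulsive: float, F_attractive: float) -> float:
    """Relative switching amplitude dF/F of a static two-potential measurement.

    (F_repulsive - F_attractive) / F_repulsive; close to 1 for freely
    switching dilute layers, close to 0 for sterically blocked dense ones.
    """
    if F_repulsive <= 0:
        raise ValueError("F_repulsive must be positive")
    return (F_repulsive - F_attractive) / F_repulsive
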