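"""Binding kinetics from real-time DR (or amplitude) traces.

A 1:1 Langmuir interaction in the reaction-limited regime gives single
exponentials: during association at analyte concentration c the signal
relaxes as S(t) = S_eq (1 - exp(-k_obs t)) with k_obs = k_on c + k_off;
during dissociation S(t) = S_0 exp(-k_off t).  Rates are obtained by
least-squares exponential fits and combined into K_D = k_off / k_on with
first-order error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PhaseRecord",
    "BindingTrace",
    "ExponentialFit",
    "KineticFit",
    "fit_association",
    "fit_dissociation",
    "dissociation_constant",
    "fit_binding",
    "rates_from_kobs_line",
]


@dataclass
class PhaseRecord:
    """One contiguous phase of a binding experiment."""

    label: str  # "association" | "dissociation"
    start: float  # s
    end: float  # s
    c: float = 0.0  # analyte concentration, mol/L (0 during dissociation)

    def __post_init__(self) -> None:
        if self.label not in ("association", "dissociation"):
            raise ValueError(f"unknown phase label {self.label!r}")
        if self.end <= self.start:
            raise ValueError("phase end must exceed start")
        if self.label == "association" and self.c <= 0:
            raise ValueError("association phase requires c > 0")


@dataclass
class BindingTrace:
    """Real-time binding signal (DR or occupancy) with phase annotations."""

    time: np.ndarray  # s
    signal: np.ndarray
    phases: List[PhaseRecord]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be matching 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(b.start - a.end) > 1e-9 * max(abs(a.end), 1.0):
                raise ValueError("phases must be contiguous")

    def phase_data(self, label: str) -> Tuple[np.ndarray, np.ndarray, PhaseRecord]:
        """Time and signal of the first phase with the given label."""
        for ph in self.phases:
            if ph.label == label:
                sel = (self.time >= ph.start - 1e-12) & (self.time <= ph.end + 1e-12)
                return self.time[sel], self.signal[sel], ph
        raise KeyError(f"no phase labelled {label!r}")


@dataclass
class ExponentialFit:
    """Single-exponential fit of one phase."""

    rate: float  # s^-1 (k_obs or k_off)
    rate_err: float
    amplitude: float  # signal units (S_eq or S_0)
    offset: float
    plateau: float  # asymptotic signal level
    ok: bool = True
    message: str = ""


@dataclass
class KineticFit:
    """Combined rate constants; K_D = k_off / k_on exactly as stored."""

    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1
    K_D: float  # M
    k_on_err: float = 0.0
    k_off_err: float = 0.0
    K_D_err: float = 0.0
    plateaus: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if not math.isclose(self.K_D, self.k_off / self.k_on, rel_tol=1e-12):
            raise ValueError("K_D must equal k_off/k_on")


def _flag_if_flat(t, s, amp, resid, message):
    sd = float(np.std(resid)) if resid.size > 2 else 0.0
    if abs(amp) <= 3.0 * sd or abs(amp) == 0.0:
        return False, message + "no resolvable signal change (amplitude within noise)"
    return True, message


def fit_association(
    t: np.ndarray, s: np.ndarray, c: float, loss: str = "linear"
) -> ExponentialFit:
    """Fit S(t) = offset + amplitude*(1 - exp(-k_obs (t - t0))) to one phase.

    Returns k_obs = k_on c + k_off and the plateau (offset + amplitude).
    The time origin t0 is the first sample, making the fit invariant to
    time shifts; `loss="soft_l1"` enables a robust variant.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size < 10:
        raise ValueError("association fit needs at least 10 points")
    if c <= 0:
        raise ValueError("concentration must be positive")
    tt = t - t[0]
    span = max(s.max() - s.min(), abs(s.max()), 1e-30)
    guess = (s[-1] - s[0], 3.0 / max(tt[-1], 1e-30), s[0])

    def model(x, amp, k, off):
        return off + amp * (1.0 - np.exp(-k * x))

    try:
        popt, pcov = curve_fit(
            model, tt, s, p0=guess,
            bounds=([-10 * span, 1e-12, -np.inf], [10 * span, np.inf, np.inf]),
            method="trf", loss=loss, max_nfev=20000,
        )
    except RuntimeError as exc:
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                              ok=False, message=f"fit failed: {exc}")
    amp, k, off = popt
    k_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    resid = s - model(tt, *popt)
    ok, msg = _flag_if_flat(tt, s, amp, resid, "")
    if k <= 0:
        ok, msg = False, "non-positive rate"
    return ExponentialFit(
        rate=float(k), rate_err=k_err, amplitude=float(amp), offset=float(off),
        plateau=float(off + amp), ok=ok, message=msg,
    )


def fit_dissociation(t: np.ndarray, s: np.ndarray, loss: str = "linear") -> ExponentialFit:
    """Fit S(t) = offset + S_0 exp(-k_off (t - t0)) to a dissociation phase."""
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size < 10:
        raise ValueError("dissociation fit needs at least 10 points")
    tt = t - t[0]
    span = max(s.max() - s.min(), abs(s.max()), 1e-30)
    guess = (s[0] - s[-1], 2.0 / max(tt[-1], 1e-30), s[-1])

    def model(x, amp, k, off):
        return off + amp * np.exp(-k * x)

    try:
        popt, pcov = curve_fit(
            model, tt, s, p0=guess,
            bounds=([-10 * span, 1e-12, -np.inf], [10 * span, np.inf, np.inf]),
            method="trf", loss=loss, max_nfev=20000,
        )
    except RuntimeError as exc:
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                              ok=False, message=f"fit failed: {exc}")
    amp, k, off = popt
    k_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    resid = s - model(tt, *popt)
    ok, msg = _flag_if_flat(tt, s, amp, resid, "")
    if k <= 0:
        ok, msg = False, "non-positive rate"
    return ExponentialFit(
        rate=float(k), rate_err=k_err, amplitude=float(amp), offset=float(off),
        plateau=float(off), ok=ok, message=msg,
    )


def dissociation_constant(
    k_on: float, k_off: float, k_on_err: float = 0.0, k_off_err: float = 0.0
) -> Tuple[float, float]:
    """K_D = k_off / k_on (M) with first-order error propagation."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    kd = k_off / k_on
    err = kd * math.sqrt((k_on_err / k_on) ** 2 + (k_off_err / k_off) ** 2)
    return kd, err


def fit_binding(trace: BindingTrace, loss: str = "linear") -> KineticFit:
    """Full kinetic analysis of an association + dissociation trace.

    k_off comes from the dissociation phase; k_on = (k_obs - k_off)/c from
    the association phase at concentration c.
    """
    ta, sa, pha = trace.phase_data("association")
    td, sd, _ = trace.phase_data("dissociation")
    assoc = fit_association(ta, sa, pha.c, loss=loss)
    dissoc = fit_dissociation(td, sd, loss=loss)
    if not (assoc.ok and dissoc.ok):
        raise RuntimeError(
            f"kinetic fit flagged: association '{assoc.message}', "
            f"dissociation '{dissoc.message}'"
        )
    k_off = dissoc.rate
    k_on = (assoc.rate - k_off) / pha.c
    if k_on <= 0:
        raise RuntimeError(
            f"k_obs={assoc.rate:.3g}/s does not exceed k_off={k_off:.3g}/s: "
            "association too slow for this concentration"
        )
    k_on_err = (
        math.sqrt(assoc.rate_err**2 + dissoc.rate_err**2) / pha.c
        if np.isfinite(assoc.rate_err) and np.isfinite(dissoc.rate_err)
        else 0.0
    )
    kd, kd_err = dissociation_constant(k_on, k_off, k_on_err, dissoc.rate_err)
    return KineticFit(
        k_on=k_on, k_off=k_off, K_D=kd,
        k_on_err=k_on_err, k_off_err=dissoc.rate_err, K_D_err=kd_err,
        plateaus={"association": assoc.plateau, "dissociation": dissoc.plateau},
    )


def rates_from_kobs_line(
    concentrations: Sequence[float], k_obs: Sequence[float]
) -> Tuple[float, float]:
    """(k_on, k_off) from the affine law k_obs(c) = k_on c + k_off."""
    cs = np.asarray(concentrations, dtype=float)
    ks = np.asarray(k_obs, dtype=float)
    if cs.size < 2:
        raise ValueError("need at least two concentrations")
    slope, intercept = np.polyfit(cs, ks, 1)
    return float(slope), float(intercept)
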