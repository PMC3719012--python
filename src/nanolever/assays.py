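"""DR-based assays: mixture quantitation, unfolding transitions, group shifts.

Three higher-level analyses built on the Dynamic Response:

* mixture analysis — the DR of a two-species layer (e.g. whole IgG vs Fab
  fragment) interpolates linearly between the pure-species endpoints, so a
  measured DR maps to a mixing fraction;
* unfolding analysis — the DR of a protein-modified lever decreases with
  solution viscosity; after subtracting the linear viscosity response of a
  non-denaturing control (glycerin), a residual sigmoidal change against
  denaturant concentration (urea) marks the loss of tertiary structure;
* group comparison — replicate DR values of two preparations (e.g.
  phosphorylated vs unmodified kinase) are compared by difference of means
  against the Welch standard error (3-sigma rule; no p-value claims).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MixtureCalibration",
    "ViscositySeries",
    "CorrectedSeries",
    "TransitionResult",
    "GroupComparison",
    "mixture_fraction",
    "viscosity_correct",
    "detect_transition",
    "compare_dr_groups",
    "relative_viscosity",
]

# Relative viscosities of aqueous solutions at 25 C (handbook-level values;
# override via the `table` argument of `relative_viscosity` when measured
# values are available).  Urea in mol/L, glycerin in % v/v.
VISCOSITY_TABLES: Dict[str, Tuple[Tuple[float, ...], Tuple[float, ...]]] = {
    "urea": (
        (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
        (1.000, 1.038, 1.079, 1.125, 1.179, 1.244, 1.322, 1.416, 1.528),
    ),
    "glycerin": (
        (0.0, 3.5, 7.0, 10.5, 14.0, 20.0),
        (1.000, 1.090, 1.192, 1.308, 1.441, 1.662),
    ),
}


def relative_viscosity(
    agent: str,
    concentration,
    table: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
):
    """Relative viscosity eta/eta0 of urea (M) or glycerin (% v/v) at 25 C.

    Linear interpolation in the lookup table; a custom (concentrations,
    relative viscosities) table may be supplied.
    """
    if table is None:
        try:
            table = VISCOSITY_TABLES[agent]
        except KeyError:
            raise KeyError(
                f"no built-in viscosity table for {agent!r}; pass `table`"
            ) from None
    conc_pts, visc_pts = np.asarray(table[0], float), np.asarray(table[1], float)
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < conc_pts[0]) or np.any(conc > conc_pts[-1]):
        raise ValueError("concentration outside table range")
    out = np.interp(conc, conc_pts, visc_pts)
    return float(out) if out.ndim == 0 else out


@dataclass
class MixtureCalibration:
    """Pure-species DR endpoints measured in a common window/conditions."""

    DR_pure_A: float  # us
    DR_pure_B: float  # us
    sd_A: float = 0.0
    sd_B: float = 0.0
    labels: Tuple[str, str] = ("A", "B")
    window: Tuple[float, float] = (3.0, 9.0)

    def __post_init__(self) -> None:
        if self.DR_pure_A == self.DR_pure_B:
            raise ValueError("degenerate calibration: equal endpoints")


@dataclass
class ViscositySeries:
    """Normalized DR versus co-solute concentration and relative viscosity."""

    agent: str  # "urea" | "glycerin" | other
    concentrations: np.ndarray
    rel_viscosities: np.ndarray  # >= 1
    dr: np.ndarray  # normalized to the co-solute-free buffer
    dr_sd: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.rel_viscosities = np.asarray(self.rel_viscosities, float)
        self.dr = np.asarray(self.dr, float)
        self.dr_sd = np.asarray(self.dr_sd, float)
        n = self.concentrations.size
        if not (self.rel_viscosities.size == self.dr.size == self.dr_sd.size == n):
            raise ValueError("all series arrays must have equal length")
        if np.any(self.rel_viscosities < 1.0 - 1e-9):
            raise ValueError("relative viscosities must be >= 1")


@dataclass
class CorrectedSeries:
    """Viscosity-corrected DR residuals versus concentration."""

    concentrations: np.ndarray
    rel_viscosities: np.ndarray
    values: np.ndarray  # sample DR minus control prediction
    sd: np.ndarray
    control_fit: Tuple[float, float] = (0.0, 0.0)  # slope, intercept
    control_r2: float = 1.0


@dataclass
class TransitionResult:
    """Outcome of the sigmoid transition search."""

    detected: bool
    c_low: Optional[float] = None
    c_high: Optional[float] = None
    midpoint: Optional[float] = None
    amplitude: Optional[float] = None
    pooled_sd: Optional[float] = None
    message: str = ""


@dataclass
class GroupComparison:
    """Difference of replicate DR means between two groups."""

    delta: float
    se: float  # Welch standard error of the difference
    pooled_sd: float
    separated: bool
    means: Tuple[float, float] = (0.0, 0.0)
    n: Tuple[int, int] = (0, 0)


def mixture_fraction(
    DR_obs: float, cal: MixtureCalibration, sd_obs: float = 0.0
) -> Tuple[float, float]:
    """Fraction of species A from linear DR interpolation, with error.

    fraction = (DR_obs - DR_B) / (DR_A - DR_B), clipped to [0, 1] with a
    warning outside that range; the uncertainty propagates the replicate
    s.d. of the observation and both calibration endpoints.
    """
    span = cal.DR_pure_A - cal.DR_pure_B
    f = (DR_obs - cal.DR_pure_B) / span
    err = (
        math.sqrt(sd_obs**2 + (f * cal.sd_A) ** 2 + ((1.0 - f) * cal.sd_B) ** 2)
        / abs(span)
    )
    if f < 0.0 or f > 1.0:
        warnings.warn(
            f"interpolated fraction {f:.3g} outside [0, 1]; clipping "
            "(observation outside the calibrated range)",
            stacklevel=2,
        )
        f = min(max(f, 0.0), 1.0)
    return float(f), float(err)


def viscosity_correct(
    sample: ViscositySeries,
    control: ViscositySeries,
    min_r2: float = 0.98,
) -> CorrectedSeries:
    """Subtract the control's linear viscosity response from the sample.

    The control series (non-denaturing co-solute, e.g. glycerin) is fitted
    with a straight line in relative viscosity; the prediction at each
    sample viscosity is subtracted from the sample DR.  Uncertainties are
    combined in quadrature with the control prediction scatter.
    """
    if (
        sample.rel_viscosities.min() < control.rel_viscosities.min() - 1e-9
        or sample.rel_viscosities.max() > control.rel_viscosities.max() + 1e-9
    ):
        raise ValueError(
            "sample viscosities extend beyond the control's coverage; "
            "cannot interpolate the viscosity correction"
        )
    x, y = control.rel_viscosities, control.dr
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < min_r2:
        raise ValueError(
            f"control series is not linear in viscosity (R^2={r2:.3f} < "
            f"{min_r2}); not a valid negative control"
        )
    pred_sd = math.sqrt(ss_res / max(x.size - 2, 1))
    corrected = sample.dr - (slope * sample.rel_viscosities + intercept)
    sd = np.sqrt(sample.dr_sd**2 + pred_sd**2)
    return CorrectedSeries(
        concentrations=sample.concentrations.copy(),
        rel_viscosities=sample.rel_viscosities.copy(),
        values=corrected,
        sd=sd,
        control_fit=(float(slope), float(intercept)),
        control_r2=r2,
    )


def _logistic(cc, base, amp, mid, width):
    arg = np.clip(-(cc - mid) / width, -500.0, 500.0)
    return base + amp / (1.0 + np.exp(arg))


def detect_transition(series: CorrectedSeries, sigma_rule: float = 3.0) -> TransitionResult:
    """Search a corrected series for a sigmoidal transition in concentration.

    Fits a 4-parameter logistic and declares a transition when the fitted
    amplitude exceeds `sigma_rule` times the pooled point s.d. and the
    midpoint lies inside the sampled concentration range.  The reported
    range covers 10-90 % of the fitted amplitude.
    """
    cc = series.concentrations
    vv = series.values
    if cc.size < 5:
        raise ValueError("need at least 5 concentration points")
    pooled_sd = float(np.sqrt(np.mean(series.sd**2)))
    if pooled_sd <= 0:
        pooled_sd = float(np.std(vv - np.polyval(np.polyfit(cc, vv, 1), cc))) or 1e-12
    span = cc.max() - cc.min()
    p0 = (float(vv[0]), float(vv[-1] - vv[0]), float(np.median(cc)), span / 6.0)
    try:
        popt, _ = curve_fit(
            _logistic, cc, vv, p0=p0, max_nfev=20000,
            bounds=(
                [-np.inf, -np.inf, cc.min() - span, 1e-6 * span],
                [np.inf, np.inf, cc.max() + span, 10.0 * span],
            ),
        )
    except RuntimeError as exc:
        return TransitionResult(False, pooled_sd=pooled_sd,
                                message=f"sigmoid fit failed: {exc}")
    base, amp, mid, width = (float(v) for v in popt)
    detected = abs(amp) > sigma_rule * pooled_sd and cc.min() <= mid <= cc.max()
    if not detected:
        return TransitionResult(
            False, midpoint=mid, amplitude=amp, pooled_sd=pooled_sd,
            message="amplitude within noise or midpoint outside data range",
        )
    ln9 = math.log(9.0)
    return TransitionResult(
        True,
        c_low=mid - ln9 * width,
        c_high=mid + ln9 * width,
        midpoint=mid,
        amplitude=amp,
        pooled_sd=pooled_sd,
    )


def compare_dr_groups(
    group_a: Sequence[float], group_b: Sequence[float], sigma_rule: float = 3.0
) -> GroupComparison:
    """Difference of replicate DR means with the Welch standard error.

    `separated` is True when |mean_A - mean_B| exceeds sigma_rule times the
    Welch SE of the difference; raw numbers are reported alongside.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 replicates per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = math.sqrt(va / a.size + vb / b.size)
    pooled = math.sqrt(
        ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    )
    delta = float(a.mean() - b.mean())
    separated = bool(se > 0 and abs(delta) > sigma_rule * se)
    return GroupComparison(
        delta=delta, se=se, pooled_sd=pooled, separated=separated,
        means=(float(a.mean()), float(b.mean())), n=(a.size, b.size),
    )
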