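"""Synthetic data generators for every input the analysis modules consume.

Each generator is seeded (reproducible bit-for-bit from parameters + seed)
and returns a machine-readable truth record next to the data, so every
downstream fit can be tested for parameter recovery without instrument
data.

Noise models: Poisson counting noise for photon histograms (the physically
correct statistic for time-correlated single photon counting), i.i.d.
Gaussian noise for DR-level and assay-level quantities (aggregates of many
photon bins and switching cycles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fluorescence import (
    DEFAULT_BIN_WIDTH_US,
    QuenchingModel,
    TimeResolvedTrace,
    fluorescence_trace,
)
from .fokker_planck import SolverSettings, switching_cycle
from .kinetics import BindingTrace, PhaseRecord
from .model import LeverSystem, default_grid, rod_entropy

__all__ = [
    "AcquisitionSettings",
    "simulate_tr_histogram",
    "simulate_binding_trace",
    "simulate_assay_tables",
]


@dataclass
class AcquisitionSettings:
    """Photon-counting acquisition emulation.

    Defaults emulate a few seconds of integration at the 10 kHz drive:
    5e4 cycles (5 s), 32 ns bins, a mean signal rate of 0.05
    counts/bin/cycle at unit fluorescence and a small unmodulated
    background.
    """

    seed: int
    bin_width: float = DEFAULT_BIN_WIDTH_US  # us
    cycles: int = 50000
    rate: float = 0.05  # counts/bin/cycle at F = 1
    background: float = 0.005  # counts/bin/cycle, unmodulated

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for every stochastic call")
        if self.bin_width <= 0 or self.cycles <= 0:
            raise ValueError("bin width and cycles must be positive")
        if self.rate < 0 or self.background < 0:
            raise ValueError("rates must be non-negative")


def simulate_tr_histogram(
    system: LeverSystem,
    D_r: float,
    acq: AcquisitionSettings,
    settings: Optional[SolverSettings] = None,
    quenching: Optional[QuenchingModel] = None,
    n_points: int = 192,
    entropy=rod_entropy,
) -> Tuple[TimeResolvedTrace, TimeResolvedTrace, Dict]:
    """Forward-simulate one switching period and draw Poisson photon counts.

    Runs the drift-diffusion forward model over a full drive period,
    converts the angular snapshots to raw fluorescence, scales to expected
    counts per bin (F * rate * cycles + background * cycles) and draws
    Poisson counts.  Returns (up_counts, down_counts, truth) where truth
    holds the noise-free traces and all generating parameters.
    """
    if settings is None:
        settings = SolverSettings.fast()
    if quenching is None:
        quenching = QuenchingModel()
    grid = default_grid(system, n_points=n_points)
    up_snaps, down_snaps = switching_cycle(
        system, D_r, settings, grid=grid, output_dt=acq.bin_width,
        entropy=entropy,
    )
    traces = {}
    rng = np.random.default_rng(acq.seed)
    truth: Dict = {
        "D_r": D_r,
        "D_H": system.protein.D_H,
        "acquisition": asdict(acq),
        "n_points": n_points,
        "dt": settings.dt,
    }
    for direction, snaps in (("up", up_snaps), ("down", down_snaps)):
        raw = fluorescence_trace(
            snaps, system, quenching, direction=direction, normalize=None,
            entropy=entropy,
        )
        mu = raw.values * acq.rate * acq.cycles + acq.background * acq.cycles
        counts = rng.poisson(mu).astype(float)
        traces[direction] = raw.copy_with(
            counts, cycles=acq.cycles, direction=direction, kind="counts"
        )
        truth[f"F_raw_{direction}"] = raw
        truth[f"expected_counts_{direction}"] = mu
    return traces["up"], traces["down"], truth


def simulate_binding_trace(
    k_on: float,
    k_off: float,
    c: float,
    noise_sd: float,
    seed: int,
    t_assoc: float = 2500.0,
    t_dissoc: float = 3000.0,
    dt: float = 5.0,
    baseline: float = 1.0,
    amplitude: float = -0.4,
) -> Tuple[BindingTrace, Dict]:
    """Exact 1:1 Langmuir exponential phases plus i.i.d. Gaussian noise.

    Occupancy rises as theta_eq (1 - exp(-k_obs t)) with
    k_obs = k_on c + k_off and theta_eq = c/(c + K_D), then decays with
    k_off; the signal is baseline + amplitude * theta (DR-like units,
    binding slows the lever so amplitude is negative by default).
    """
    if seed is None:
        raise ValueError("a seed is mandatory for every stochastic call")
    if k_on <= 0 or k_off <= 0 or c <= 0:
        raise ValueError("rates and concentration must be positive")
    rng = np.random.default_rng(seed)
    k_obs = k_on * c + k_off
    kd = k_off / k_on
    theta_eq = c / (c + kd)

    t_a = np.arange(0.0, t_assoc, dt)
    theta_a = theta_eq * (1.0 - np.exp(-k_obs * t_a))
    t_d = np.arange(0.0, t_dissoc, dt) + t_assoc
    theta_d = theta_a[-1] * np.exp(-k_off * (t_d - t_assoc))

    time = np.concatenate([t_a, t_d])
    theta = np.concatenate([theta_a, theta_d])
    clean = baseline + amplitude * theta
    signal = clean + rng.normal(0.0, noise_sd, size=clean.size) if noise_sd > 0 else clean.copy()

    trace = BindingTrace(
        time=time,
        signal=signal,
        phases=[
            PhaseRecord("association", 0.0, float(t_a[-1]) + dt / 2.0, c),
            PhaseRecord("dissociation", float(t_a[-1]) + dt / 2.0,
                        float(t_d[-1]) + dt / 2.0, 0.0),
        ],
    )
    truth = {
        "k_on": k_on, "k_off": k_off, "K_D": kd, "k_obs": k_obs, "c": c,
        "theta_eq": theta_eq, "baseline": baseline, "amplitude": amplitude,
        "noise_sd": noise_sd, "seed": seed, "clean_signal": clean,
    }
    return trace, truth


def _simulate_mixture(params: Dict, rng: np.random.Generator):
    fractions = np.asarray(params.get("fractions", [0.0, 0.25, 0.5, 0.75, 1.0]))
    dr_a = float(params.get("DR_pure_A", 1.8))  # us, e.g. fast small species
    dr_b = float(params.get("DR_pure_B", 0.9))
    noise_rel = float(params.get("noise_rel", 0.03))
    n_rep = int(params.get("n_replicates", 1))
    rows = []
    for f in fractions:
        dr_true = f * dr_a + (1.0 - f) * dr_b
        for rep in range(n_rep):
            dr = dr_true * (1.0 + rng.normal(0.0, noise_rel))
            rows.append({"fraction_true": float(f), "replicate": rep, "dr": dr})
    table = pd.DataFrame(rows)
    truth = {"DR_pure_A": dr_a, "DR_pure_B": dr_b,
             "fractions": fractions.tolist(), "noise_rel": noise_rel}
    return table, truth


def _simulate_viscosity(params: Dict, rng: np.random.Generator):
    from .assays import relative_viscosity

    agent = params.get("agent", "urea")
    conc = np.asarray(params.get("concentrations", [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0]))
    visc = relative_viscosity(agent, conc) if "rel_viscosities" not in params \
        else np.asarray(params["rel_viscosities"], float)
    slope = float(params.get("viscosity_slope", -1.0))  # d(DR_norm)/d(eta_rel)
    noise_sd = float(params.get("noise_sd", 0.01))
    amp = float(params.get("sigmoid_amplitude", 0.0))
    mid = float(params.get("sigmoid_midpoint", 1.2))
    width = float(params.get("sigmoid_width", 0.3))
    base = 1.0 + slope * (visc - 1.0)
    sigmoid = amp / (1.0 + np.exp(-(conc - mid) / width)) if amp != 0.0 else 0.0
    clean = base + sigmoid
    dr = clean + rng.normal(0.0, noise_sd, size=conc.size)
    table = pd.DataFrame({
        "concentration": conc, "rel_viscosity": visc,
        "dr": dr, "dr_sd": np.full(conc.size, max(noise_sd, 1e-12)),
    })
    truth = {"agent": agent, "viscosity_slope": slope, "noise_sd": noise_sd,
             "sigmoid_amplitude": amp, "sigmoid_midpoint": mid,
             "sigmoid_width": width, "clean": clean}
    return table, truth


def _simulate_groups(params: Dict, rng: np.random.Generator):
    mean_a = float(params.get("mean_A", 1.0))
    mean_b = float(params.get("mean_B", 1.0))
    sd = float(params.get("sd", 0.05))
    n = int(params.get("n_replicates", 6))
    rows = []
    for label, mean in (("A", mean_a), ("B", mean_b)):
        for rep, v in enumerate(rng.normal(mean, sd, size=n)):
            rows.append({"group": label, "replicate": rep, "dr": float(v)})
    table = pd.DataFrame(rows)
    truth = {"mean_A": mean_a, "mean_B": mean_b, "sd": sd, "n": n}
    return table, truth


def simulate_assay_tables(
    kind: str, params: Optional[Dict] = None, seed: int = None
) -> Tuple[pd.DataFrame, Dict]:
    """Generate a CSV-ready assay table plus its truth record.

    kind: "mixture" (DR linear in mixing fraction + relative noise),
    "viscosity" (linear control, optional sigmoid for the sample) or
    "groups" (Gaussian replicates of two preparations).
    """
    if seed is None:
        raise ValueError("a seed is mandatory for every stochastic call")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "mixture":
        table, truth = _simulate_mixture(params, rng)
    elif kind == "viscosity":
        table, truth = _simulate_viscosity(params, rng)
    elif kind == "groups":
        table, truth = _simulate_groups(params, rng)
    else:
        raise ValueError(f"unknown assay kind {kind!r}")
    truth["seed"] = seed
    truth["kind"] = kind
    return table, truth
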