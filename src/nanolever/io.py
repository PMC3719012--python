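"""File formats and configuration.

* Time-resolved traces: headered TSV — comment lines `# key=value`
  (direction, bin_width_us, ...) followed by two columns
  `time_us<TAB>value`, values formatted %.9g.  The reader also accepts
  comma-delimited data rows.
* Configuration: flat key-value YAML with dotted section prefixes
  (`geometry.b_nm: 0.34`); every key is unit-annotated in its name.
  Unknown keys are rejected.
* Results: JSON records carrying a schema_version field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import yaml

from .fluorescence import QuenchingModel, TimeResolvedTrace
from .fokker_planck import SolverSettings
from .model import ElectricModel, Environment, LeverGeometry, LeverSystem, ProteinHead

__all__ = [
    "read_trace",
    "write_trace",
    "system_to_config",
    "system_from_config",
    "RunConfig",
    "load_config",
    "save_config",
    "result_record",
]

RESULT_SCHEMA_VERSION = 1

#: metadata keys a trace file must carry
REQUIRED_TRACE_KEYS = ("direction", "bin_width_us")


def write_trace(trace: TimeResolvedTrace, path: Union[str, Path]) -> None:
    """Write a trace as headered TSV with bit-stable %.9g formatting."""
    path = Path(path)
    lines = [f"# direction={trace.direction}"]
    for key, val in sorted(trace.metadata.items()):
        if key == "direction":
            continue
        if isinstance(val, float):
            lines.append(f"# {key}={val:.9g}")
        elif isinstance(val, (int, bool, str)):
            lines.append(f"# {key}={val}")
        # non-scalar metadata (dicts from normalization provenance) is dropped
    lines.append("time_us\tvalue")
    for t, v in zip(trace.times, trace.values):
        lines.append(f"{t:.9g}\t{v:.9g}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta_value(raw: str):
    if raw in ("True", "False"):
        return raw == "True"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def read_trace(path: Union[str, Path]) -> TimeResolvedTrace:
    """Read a headered TSV/CSV trace; malformed input errors cite the line."""
    path = Path(path)
    meta: Dict[str, object] = {}
    times, values = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(
                    f"{path}:{lineno}: malformed header line (expected key=value)"
                )
            key, _, raw = body.partition("=")
            meta[key.strip()] = _parse_meta_value(raw.strip())
            continue
        fields = line.replace(",", "\t").split("\t")
        fields = [f for f in (f.strip() for f in fields) if f]
        if fields[0].lower().startswith("time"):
            continue  # column header
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected two columns, got {len(fields)}"
            )
        try:
            times.append(float(fields[0]))
            values.append(float(fields[1]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric data") from None
    for key in REQUIRED_TRACE_KEYS:
        if key not in meta:
            raise ValueError(f"{path}: missing required metadata key '{key}'")
    direction = str(meta.pop("direction"))
    return TimeResolvedTrace(np.array(times), np.array(values), direction, meta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    # key -> (section object attr, field attr)
    "geometry.n_bp": int,
    "geometry.b_nm": float,
    "geometry.L_nm": float,
    "geometry.R_nm": float,
    "electric.gamma": float,
    "electric.kappa_per_nm": float,  # optional, may be null
    "electric.phi_up_V": float,
    "electric.phi_down_V": float,
    "electric.RC_s": float,
    "electric.frequency_hz": float,
    "protein.D_H_nm": float,
    "protein.m_e": float,
    "environment.T_K": float,
    "environment.eta_Pa_s": float,
    "environment.ionic_strength_mM": float,
}


def system_to_config(system: LeverSystem) -> Dict[str, object]:
    """Flat, unit-annotated key-value representation of a LeverSystem."""
    e = system.electric
    return {
        "geometry.n_bp": system.geometry.n_bp,
        "geometry.b_nm": system.geometry.b,
        "geometry.L_nm": system.geometry.L,
        "geometry.R_nm": system.geometry.R,
        "electric.gamma": e.gamma,
        "electric.kappa_per_nm": e.kappa,
        "electric.phi_up_V": e.phi_up,
        "electric.phi_down_V": e.phi_down,
        "electric.RC_s": e.RC,
        "electric.frequency_hz": e.frequency,
        "protein.D_H_nm": system.protein.D_H,
        "protein.m_e": system.protein.m,
        "environment.T_K": system.env.T,
        "environment.eta_Pa_s": system.env.eta,
        "environment.ionic_strength_mM": system.env.ionic_strength,
    }


def system_from_config(cfg: Dict[str, object]) -> LeverSystem:
    """Rebuild a LeverSystem from its flat config dict (lossless)."""
    unknown = set(cfg) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def get(key, default=None):
        val = cfg.get(key, default)
        if val is None:
            return default
        return _CONFIG_FIELDS[key](val)

    geometry = LeverGeometry(
        n_bp=get("geometry.n_bp", 48), b=get("geometry.b_nm", 0.34),
        L=get("geometry.L_nm"), R=get("geometry.R_nm", 1.3),
    )
    electric = ElectricModel(
        gamma=get("electric.gamma", 0.016),
        kappa=get("electric.kappa_per_nm"),
        phi_up=get("electric.phi_up_V", -0.3),
        phi_down=get("electric.phi_down_V", 0.3),
        RC=get("electric.RC_s", 0.3e-6),
        frequency=get("electric.frequency_hz", 1.0e4),
    )
    protein = ProteinHead(D_H=get("protein.D_H_nm", 0.0), m=get("protein.m_e", 0.0))
    env = Environment(
        T=get("environment.T_K", 298.15),
        eta=get("environment.eta_Pa_s", 0.89e-3),
        ionic_strength=get("environment.ionic_strength_mM", 50.0),
    )
    return LeverSystem(geometry, electric, protein, env)


_RUN_KEYS = {
    "solver.dt_us": float,
    "solver.scheme": str,
    "solver.mass_tol": float,
    "solver.metric": str,
    "quenching.model": str,
    "quenching.z0_nm": float,
    "quenching.n": float,
    "quenching.floor": float,
    "acquisition.bin_width_us": float,
    "acquisition.cycles": int,
    "acquisition.rate": float,
    "acquisition.background": float,
    "analysis.dr_window_us": list,
    "analysis.fit_window_us": list,
    "analysis.n_points": int,
    "seed": int,
}


@dataclass
class RunConfig:
    """Fully resolved run configuration for the CLI and pipelines."""

    system: LeverSystem
    solver: SolverSettings
    quenching: QuenchingModel
    acquisition: Dict[str, object] = field(default_factory=dict)
    dr_window: Tuple[float, float] = (0.0, 3.0)
    fit_window: Tuple[float, float] = (0.0, 12.0)
    n_points: int = 192
    seed: Optional[int] = None

    def as_dict(self) -> Dict[str, object]:
        d = system_to_config(self.system)
        d.update({
            "solver.dt_us": self.solver.dt,
            "solver.scheme": self.solver.scheme,
            "solver.mass_tol": self.solver.mass_tol,
            "solver.metric": self.solver.metric,
            "quenching.model": self.quenching.model,
            "quenching.z0_nm": self.quenching.z0,
            "quenching.n": self.quenching.n,
            "quenching.floor": self.quenching.floor,
            "analysis.dr_window_us": list(self.dr_window),
            "analysis.fit_window_us": list(self.fit_window),
            "analysis.n_points": self.n_points,
        })
        for key, val in self.acquisition.items():
            d[f"acquisition.{key}"] = val
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load and validate a YAML run configuration (None -> all defaults)."""
    cfg: Dict[str, object] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        cfg = dict(loaded)
    known = set(_CONFIG_FIELDS) | set(_RUN_KEYS)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    system = system_from_config({k: v for k, v in cfg.items() if k in _CONFIG_FIELDS})
    solver = SolverSettings(
        dt=float(cfg.get("solver.dt_us", 0.004)),
        scheme=str(cfg.get("solver.scheme", "chang-cooper-cn")),
        mass_tol=float(cfg.get("solver.mass_tol", 1e-8)),
        metric=str(cfg.get("solver.metric", "flat")),
    )
    quenching = QuenchingModel(
        model=str(cfg.get("quenching.model", "power-law")),
        z0=float(cfg.get("quenching.z0_nm", 6.0)),
        n=float(cfg.get("quenching.n", 4.0)),
        floor=float(cfg.get("quenching.floor", 0.02)),
    )
    acq = {
        key.split(".", 1)[1]: val
        for key, val in cfg.items()
        if key.startswith("acquisition.")
    }
    dr_window = tuple(cfg.get("analysis.dr_window_us", (0.0, 3.0)))
    fit_window = tuple(cfg.get("analysis.fit_window_us", (0.0, 12.0)))
    return RunConfig(
        system=system, solver=solver, quenching=quenching, acquisition=acq,
        dr_window=(float(dr_window[0]), float(dr_window[1])),
        fit_window=(float(fit_window[0]), float(fit_window[1])),
        n_points=int(cfg.get("analysis.n_points", 192)),
        seed=cfg.get("seed"),
    )


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=True)


def result_record(kind: str, payload: Dict[str, object]) -> Dict[str, object]:
    """JSON-serializable result record with a schema version."""
    def clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, float) and not math.isfinite(v):
            return None
        return v

    return {"schema_version": RESULT_SCHEMA_VERSION, "kind": kind,
            **{k: clean(v) for k, v in payload.items()}}
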