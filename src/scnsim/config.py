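"""Configuration parsing, serialization and run logging.

A run configuration is a YAML document with up to five groups::

    clock:      {k_1: 0.45, ...}        # gene-network overrides
    calcium:    {ca_scale: 1.2, ...}
    membrane:   {C_m: 5.0, ...}
    signaling:  {v_VIP: 0.5, ...}
    simulation: {duration_h: 1440, report_step_h: 0.1667,
                 transient_h: 240, initial_state: {...},
                 perturbation: "nimodipine" | "ca_scale:1.5"}

An empty (or absent) file resolves to the full nominal parameter set and
default simulation settings.  Unknown keys anywhere are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .params import INITIAL_STATE, STATE_NAMES, Parameters
from .simulate import Perturbation, SimulationConfig, Trajectory

__all__ = [
    "load_config",
    "dump_config",
    "write_trajectory",
    "read_trajectory",
    "write_metrics",
    "run_log",
]

_PARAM_GROUPS = ("clock", "calcium", "membrane", "signaling")
_SIM_KEYS = {"duration_h", "report_step_h", "transient_h", "initial_state",
             "perturbation", "rtol", "atol"}


def _build(doc: Mapping[str, Any]) -> SimulationConfig:
    unknown = set(doc) - set(_PARAM_GROUPS) - {"simulation"}
    if unknown:
        raise KeyError(f"unknown configuration group(s): {sorted(unknown)}")
    overrides = {g: dict(doc.get(g) or {}) for g in _PARAM_GROUPS}
    params = Parameters().with_overrides(**overrides)

    sim = dict(doc.get("simulation") or {})
    unknown = set(sim) - _SIM_KEYS
    if unknown:
        raise KeyError(f"unknown simulation key(s): {sorted(unknown)}")

    init = dict(INITIAL_STATE)
    for key, val in dict(sim.pop("initial_state", {}) or {}).items():
        if key not in STATE_NAMES:
            raise KeyError(f"unknown state variable {key!r}")
        if val < 0:
            raise ValueError(f"initial {key} must be non-negative")
        init[key] = float(val)

    pert_raw = sim.pop("perturbation", "none")
    pert = (pert_raw if isinstance(pert_raw, Perturbation)
            else Perturbation.parse(str(pert_raw)))
    return SimulationConfig(
        params=params, initial_state=init, perturbation=pert,
        **{k: float(v) for k, v in sim.items()},
    )


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Load a YAML run configuration; ``None`` yields the nominal setup."""
    if path is None:
        return SimulationConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, Mapping):
        raise TypeError("configuration root must be a mapping")
    return _build(doc)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (round-trips losslessly)."""
    pert = config.perturbation
    pert_text = pert.kind.value
    if pert.magnitude is not None:
        pert_text += f":{pert.magnitude}"
    doc = dict(config.params.to_dict())
    doc["simulation"] = {
        "duration_h": config.duration_h,
        "report_step_h": config.report_step_h,
        "transient_h": config.transient_h,
        "rtol": config.rtol,
        "atol": config.atol,
        "initial_state": dict(config.initial_state),
        "perturbation": pert_text,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


_FLOAT_FMT = "%.10g"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Trajectory CSV: time, the 20 states in canonical order, snapshots."""
    traj.frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metrics(metrics_by_var: Mapping[str, Any], path: str | Path) -> None:
    """Metrics JSON: one record per observable."""
    payload = {
        name: (m.to_dict() if hasattr(m, "to_dict") else m)
        for name, m in metrics_by_var.items()
    }

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=2, default=default))


def run_log(config: SimulationConfig) -> str:
    """Plain-text provenance log: every resolved parameter and solver
    setting needed to reproduce the run bit-for-bit."""
    lines = ["# scnsim run log", ""]
    for group, values in config.params.to_dict().items():
        lines.append(f"[{group}]")
        for key, val in sorted(values.items()):
            lines.append(f"{key} = {val!r}")
        lines.append("")
    lines.append("[simulation]")
    lines.append(f"duration_h = {config.duration_h!r}")
    lines.append(f"report_step_h = {config.report_step_h!r}")
    lines.append(f"transient_h = {config.transient_h!r}")
    lines.append(f"rtol = {config.rtol!r}")
    lines.append(f"atol = {config.atol!r}")
    lines.append(f"integrator = RK23 (adaptive explicit, low order)")
    pert = config.perturbation
    lines.append(f"perturbation = {pert.kind.value}"
                 + (f":{pert.magnitude}" if pert.magnitude is not None else ""))
    lines.append("")
    lines.append("[initial_state]")
    for key in STATE_NAMES:
        lines.append(f"{key} = {config.initial_state[key]!r}")
    return "\n".join(lines) + "\n"
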