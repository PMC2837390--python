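"""Perturbation experiment runner: control vs perturbed rhythm metrics.

A suite is an ordered mapping of run labels to perturbations.  Every run
is integrated with the same base configuration, rhythm metrics are
computed per observable, and percent changes of peak, trough and
amplitude are reported against the control run.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from . import metrics
from .metrics import RhythmMetrics, analyze_series, percent_change
from .simulate import Perturbation, SimulationConfig, Trajectory, simulate

__all__ = [
    "DEFAULT_OBSERVABLES",
    "trajectory_metrics",
    "run_experiment_suite",
]

#: observables summarized by default: gene expression, calcium, firing,
#: synaptic currents and VIP
DEFAULT_OBSERVABLES: tuple[str, ...] = (
    "M_P", "Ca", "f_r", "VIP", "CB",
    "I_K", "I_Na", "I_Ca", "I_KCa", "I_ex", "I_inhib",
)


def trajectory_metrics(
    traj: Trajectory,
    observables: Sequence[str] = DEFAULT_OBSERVABLES,
) -> dict[str, RhythmMetrics]:
    """Rhythm metrics for each observable of one run.

    Current phases are computed on the current magnitude (inward currents
    are negative; their physiological "peak" is the extremum of |I|).
    """
    _, ca = traj.series("Ca")
    out: dict[str, RhythmMetrics] = {}
    for name in observables:
        t, y = traj.series(name)
        if name.startswith("I_"):
            m = analyze_series(name, t, abs(y), ca_series=ca)
            # report signed extrema alongside the magnitude-based phase
            signed = analyze_series(name, t, y)
            m = RhythmMetrics(
                variable=name, period_h=m.period_h, peak_CT=m.peak_CT,
                peak=signed.peak, trough=signed.trough,
                amplitude=signed.amplitude, is_rhythmic=m.is_rhythmic,
            )
        else:
            m = analyze_series(name, t, y, ca_series=ca)
        out[name] = m
    return out


def run_experiment_suite(
    perturbations: Mapping[str, Perturbation],
    base_config: SimulationConfig | None = None,
    observables: Sequence[str] = DEFAULT_OBSERVABLES,
) -> pd.DataFrame:
    """Run control + perturbations; return one metrics row per observable.

    The returned frame has columns: run, variable, period_h, peak_CT,
    peak, trough, amplitude, is_rhythmic, pct_peak, pct_trough,
    pct_amplitude (percent change vs the control run; NaN for the control
    itself and for zero-control metrics).  An empty suite yields only the
    control rows.
    """
    base = base_config or SimulationConfig()
    control_traj = simulate(replace(base, perturbation=Perturbation()))
    control = trajectory_metrics(control_traj, observables)

    rows: list[dict] = []

    def add_rows(label: str, mm: dict[str, RhythmMetrics]) -> None:
        for name, m in mm.items():
            row = m.to_dict()
            row["run"] = label
            for which in ("peak", "trough", "amplitude"):
                ctrl_val = getattr(control[name], which)
                pert_val = getattr(m, which)
                if label == "control" or ctrl_val == 0:
                    row[f"pct_{which}"] = float("nan")
                else:
                    row[f"pct_{which}"] = percent_change(ctrl_val, pert_val)
            rows.append(row)

    add_rows("control", control)
    for label, pert in perturbations.items():
        traj = simulate(replace(base, perturbation=pert))
        add_rows(label, trajectory_metrics(traj, observables))

    cols = ["run", "variable", "period_h", "peak_CT", "peak", "trough",
            "amplitude", "is_rhythmic", "pct_peak", "pct_trough",
            "pct_amplitude"]
    return pd.DataFrame(rows, columns=cols)
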