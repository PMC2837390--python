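"""Coupling of the four model layers into one 20-ODE system.

The slow state is ``(Ca, Ca_store, 16 clock species, CB, VIP)``.  At every
right-hand-side evaluation the electrophysiology layer is computed
algebraically from the current slow state (conductances -> GHK resting
potential -> resistance -> firing rate) before the VIP production term is
evaluated, making the full system a semi-explicit DAE integrated as an
ODE.  The model is fully deterministic.

Perturbations reproduce the pharmacological/electrical experiments:
store blockades, nimodipine, GABA dose changes, VIP blockade/application,
calcium output scaling, current injection and voltage clamp.  Exactly one
perturbation applies per run and is resolved once at simulation start
(constitutive application).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import calcium, core_clock, electro, signaling
from .params import INITIAL_STATE, STATE_NAMES, Parameters

__all__ = [
    "PerturbationKind",
    "Perturbation",
    "SimulationConfig",
    "Trajectory",
    "full_rhs",
    "simulate",
]


class PerturbationKind(str, Enum):
    NONE = "none"
    IP3_BLOCK = "ip3_block"
    RYANODINE_BLOCK = "ryanodine_block"
    NIMODIPINE = "nimodipine"
    GABA_REDUCE = "gaba_reduce"      # magnitude: percent reduction in [0, 100]
    GABA_ADD = "gaba_add"            # magnitude: added GABA, nM
    VIP_BLOCK = "vip_block"
    VIP_ADD = "vip_add"              # magnitude: added VIP, nM (default 1)
    CA_SCALE = "ca_scale"            # magnitude: scaling factor in [0.5, 1.5]
    CURRENT_INJECT = "current_inject"  # magnitude: injected current, pA
    VOLTAGE_CLAMP = "voltage_clamp"


@dataclass(frozen=True)
class Perturbation:
    """One constitutive perturbation, applied for the whole run."""

    kind: PerturbationKind = PerturbationKind.NONE
    magnitude: float | None = None

    def __post_init__(self) -> None:
        kind = PerturbationKind(self.kind)
        object.__setattr__(self, "kind", kind)
        mag = self.magnitude
        if kind is PerturbationKind.GABA_REDUCE:
            if mag is None or not 0.0 <= mag <= 100.0:
                raise ValueError("gaba_reduce needs a percent in [0, 100]")
        elif kind is PerturbationKind.CA_SCALE:
            if mag is None or not 0.5 <= mag <= 1.5:
                raise ValueError("ca_scale needs a factor in [0.5, 1.5]")
        elif kind is PerturbationKind.VIP_ADD:
            if mag is None:
                object.__setattr__(self, "magnitude", 1.0)
        elif kind in (PerturbationKind.GABA_ADD, PerturbationKind.CURRENT_INJECT):
            if mag is None:
                raise ValueError(f"{kind.value} needs a magnitude")

    @classmethod
    def parse(cls, text: str) -> "Perturbation":
        """Parse ``kind`` or ``kind:magnitude`` (CLI syntax)."""
        if ":" in text:
            name, raw = text.split(":", 1)
            return cls(PerturbationKind(name), float(raw))
        return cls(PerturbationKind(text))


@dataclass(frozen=True)
class _ResolvedPerturbation:
    """Flags consumed by the right-hand side, resolved once per run."""

    blockade: calcium.CalciumBlockade = calcium.CalciumBlockade.NONE
    nimodipine: bool = False
    gaba_scale: float = 1.0
    gaba_add: float = 0.0
    vip_blocked: bool = False
    vip_add: float = 0.0
    I_app: float = 0.0
    voltage_clamp: bool = False


def _resolve(
    perturbation: Perturbation, params: Parameters
) -> tuple[_ResolvedPerturbation, Parameters]:
    k, m = perturbation.kind, perturbation.magnitude
    if k is PerturbationKind.NONE:
        return _ResolvedPerturbation(), params
    if k is PerturbationKind.IP3_BLOCK:
        return _ResolvedPerturbation(blockade=calcium.CalciumBlockade.IP3_BLOCK), params
    if k is PerturbationKind.RYANODINE_BLOCK:
        return (_ResolvedPerturbation(blockade=calcium.CalciumBlockade.RYANODINE_BLOCK),
                params)
    if k is PerturbationKind.NIMODIPINE:
        return _ResolvedPerturbation(nimodipine=True), params
    if k is PerturbationKind.GABA_REDUCE:
        return _ResolvedPerturbation(gaba_scale=1.0 - m / 100.0), params
    if k is PerturbationKind.GABA_ADD:
        return _ResolvedPerturbation(gaba_add=m), params
    if k is PerturbationKind.VIP_BLOCK:
        return _ResolvedPerturbation(vip_blocked=True), params
    if k is PerturbationKind.VIP_ADD:
        return _ResolvedPerturbation(vip_add=m), params
    if k is PerturbationKind.CA_SCALE:
        return (_ResolvedPerturbation(),
                params.with_overrides(calcium={"ca_scale": m}))
    if k is PerturbationKind.CURRENT_INJECT:
        return _ResolvedPerturbation(I_app=m), params
    if k is PerturbationKind.VOLTAGE_CLAMP:
        return _ResolvedPerturbation(voltage_clamp=True), params
    raise ValueError(f"unknown perturbation kind: {k}")  # pragma: no cover


def _snapshot_from_state(
    y: np.ndarray, params: Parameters, flags: _ResolvedPerturbation,
    clamp_ca: float | None,
) -> electro.ElectroSnapshot:
    Ca = clamp_ca if clamp_ca is not None else y[0]
    MP, CC, BC = y[2], y[6], y[13]
    Ca_eff = calcium.scaled_output(max(Ca, 0.0), params.calcium)
    VIP = max(y[19], 0.0)
    VIP_eff = 0.0 if flags.vip_blocked else VIP + flags.vip_add
    snap = electro.snapshot(
        max(MP, 0.0), max(CC, 0.0), max(BC, 0.0), Ca_eff, VIP_eff,
        params.membrane,
        nimodipine=flags.nimodipine,
        gaba_scale=flags.gaba_scale,
        gaba_add=flags.gaba_add,
        I_app=flags.I_app,
    )
    if flags.voltage_clamp:
        # membrane held hyperpolarized: the neuron is silent
        snap = dataclasses.replace(snap, f_r=0.0)
    return snap


def full_rhs(
    t: float,
    y: np.ndarray,
    params: Parameters,
    flags: _ResolvedPerturbation = _ResolvedPerturbation(),
    clamp_ca: float | None = None,
) -> np.ndarray:
    """Time derivative of the 20-component cell state.

    The electrophysiology snapshot is evaluated first; its firing rate
    drives VIP release.  Under voltage clamp the firing-rate drive is
    frozen at zero and calcium is held constant at ``clamp_ca``.
    """
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    snap = _snapshot_from_state(y, params, flags, clamp_ca)
    if not np.isfinite(snap.f_r) or not np.isfinite(snap.V_rest):
        raise FloatingPointError(
            f"non-finite membrane snapshot at t={t:.2f} h "
            f"(f_r={snap.f_r}, V_rest={snap.V_rest})"
        )

    Ca, Ca_store = y[0], y[1]
    clock_state = y[2:18]
    CB = min(y[18], params.signaling.CB_T)
    VIP = y[19]

    if flags.voltage_clamp:
        dCa, dCa_store = 0.0, 0.0
        Ca_for_kinase = calcium.scaled_output(clamp_ca, params.calcium)
        f_r_drive = 0.0
    else:
        dCa, dCa_store = calcium.calcium_derivatives(
            Ca, Ca_store, clock_state[4], clock_state[11],
            params.calcium, flags.blockade,
        )
        Ca_for_kinase = calcium.scaled_output(Ca, params.calcium)
        f_r_drive = snap.f_r

    VIP_eff = 0.0 if flags.vip_blocked else VIP + flags.vip_add
    v_k = signaling.kinase_rate(Ca_for_kinase, VIP_eff, params.signaling)
    dCB = signaling.creb_derivative(CB, v_k, params.signaling)
    per_drive = signaling.per_transcription_rate(
        CB, params.signaling, params.clock.v_sP0)
    dclock = core_clock.clock_derivatives(clock_state, params.clock, per_drive)
    dVIP = signaling.vip_derivative(f_r_drive, VIP, params.signaling)

    out = np.empty(20)
    out[0], out[1] = dCa, dCa_store
    out[2:18] = dclock
    out[18], out[19] = dCB, dVIP
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation run: parameters, horizon, report grid, perturbation."""

    params: Parameters = field(default_factory=Parameters)
    initial_state: Mapping[str, float] = field(
        default_factory=lambda: dict(INITIAL_STATE))
    duration_h: float = 1440.0        # 60 simulated days
    report_step_h: float = 1.0 / 6.0  # 10-minute grid
    transient_h: float = 240.0        # discarded before metrics
    perturbation: Perturbation = field(default_factory=Perturbation)
    rtol: float = 1e-6
    atol: float = 1e-9

    def initial_vector(self) -> np.ndarray:
        missing = set(STATE_NAMES) - set(self.initial_state)
        if missing:
            raise ValueError(f"initial state missing {sorted(missing)}")
        return np.array([self.initial_state[k] for k in STATE_NAMES])


@dataclass
class Trajectory:
    """Sampled model output: slow states plus the membrane snapshot."""

    times: np.ndarray                 # hours
    states: pd.DataFrame              # one column per state variable
    snapshots: pd.DataFrame           # one column per snapshot quantity
    config: SimulationConfig

    @property
    def post_transient(self) -> np.ndarray:
        return self.times >= self.config.transient_h

    def series(self, name: str, *, settled: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for one observable, post-transient by default."""
        if name in self.states.columns:
            vals = self.states[name].to_numpy()
        elif name in self.snapshots.columns:
            vals = self.snapshots[name].to_numpy()
        else:
            raise KeyError(f"unknown observable {name!r}")
        if settled:
            keep = self.post_transient
            return self.times[keep], vals[keep]
        return self.times, vals

    def frame(self) -> pd.DataFrame:
        """Single table: time, 20 states, snapshot quantities."""
        out = pd.DataFrame({"time_h": self.times})
        out = pd.concat(
            [out, self.states.reset_index(drop=True),
             self.snapshots.reset_index(drop=True)], axis=1)
        return out


def simulate(config: SimulationConfig) -> Trajectory:
    """Integrate the coupled model and sample it on the report grid.

    Uses an adaptive explicit low-order Runge-Kutta pair (RK23); the
    report grid is fixed at the configured step regardless of the internal
    step sizes, keeping the quasi-static membrane assumption explicit.
    """
    flags, params = _resolve(config.perturbation, config.params)
    y0 = config.initial_vector()
    clamp_ca = float(y0[0]) if flags.voltage_clamp else None

    n_steps = int(round(config.duration_h / config.report_step_h))
    t_eval = np.linspace(0.0, config.duration_h, n_steps + 1)
    sol = solve_ivp(
        full_rhs, (0.0, config.duration_h), y0,
        t_eval=t_eval, method="RK23",
        rtol=config.rtol, atol=config.atol,
        args=(params, flags, clamp_ca),
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"integration failed at t={last_t:.2f} h: {sol.message}")

    yt = np.maximum(sol.y.T, 0.0)
    if flags.voltage_clamp:
        yt[:, 0] = clamp_ca
    states = pd.DataFrame(yt, columns=list(STATE_NAMES))
    snaps = [
        _snapshot_from_state(row, params, flags, clamp_ca) for row in yt
    ]
    snapshots = pd.DataFrame(
        {name: [getattr(s, name) for s in snaps]
         for name in electro.SNAPSHOT_FIELDS})
    return Trajectory(times=sol.t, states=states, snapshots=snapshots,
                      config=config)
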