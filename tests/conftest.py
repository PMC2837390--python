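"""Shared fixtures: expensive simulations run once per session."""

from __future__ import annotations

import pytest

from scnsim import Parameters, Perturbation, SimulationConfig, simulate


@pytest.fixture(scope="session")
def nominal_params() -> Parameters:
    return Parameters()


@pytest.fixture(scope="session")
def control_traj():
    """Control run long enough for rhythm metrics (25 days, 12.5 discarded)."""
    return simulate(SimulationConfig(duration_h=600.0, transient_h=300.0))


@pytest.fixture(scope="session")
def long_control_traj():
    """41-day control run with 12 days of transient discarded."""
    return simulate(SimulationConfig(duration_h=984.0, transient_h=288.0))


def perturbed(kind: str, duration_h: float = 600.0, transient_h: float = 300.0):
    return simulate(SimulationConfig(
        duration_h=duration_h, transient_h=transient_h,
        perturbation=Perturbation.parse(kind)))


@pytest.fixture(scope="session")
def perturbed_factory():
    """Memoized runner for perturbation simulations."""
    cache: dict[str, object] = {}

    def run(kind: str):
        if kind not in cache:
            cache[kind] = perturbed(kind)
        return cache[kind]

    return run
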