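"""Synthetic oscillation generator (test oracle for the rhythm metrics).

The model itself is deterministic; the only randomness in the package is
the optional measurement noise here, which is seed-controlled.
"""

from __future__ import annotations

import numpy as np

__all__ = ["synthetic_oscillation"]


def synthetic_oscillation(
    period: float,
    amplitude: float = 1.0,
    mean: float = 0.0,
    phase: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    duration: float = 240.0,
    dt: float = 1.0 / 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine oscillation sampled on a uniform grid.

    The peak of the noiseless signal falls at ``t = phase (mod period)``.
    Returns ``(times, values)``; deterministic for a given seed.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if dt >= period / 4.0:
        raise ValueError(
            f"dt = {dt} undersamples a period-{period} oscillation "
            "(need dt < period/4)")
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    values = mean + amplitude * np.cos(2.0 * np.pi * (times - phase) / period)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    return times, values
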