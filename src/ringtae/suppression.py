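"""Adaptation-induced firing-rate suppression with exponential recovery.

After an adapter switches off at t0, each unit's rate is reduced by an
amount proportional (gain beta) to its own mean rate during the adaptation
period, and the reduction decays exponentially with time constant rho:

    R_adapt(t) = R(t) - beta * <R> * exp(-(t - t0) / rho),   t >= t0,

clipped at zero (rates cannot be negative).  The suppression is a post-hoc
correction of the readout rates; it is not fed back into the recurrent
input.  Because the suppression is tuned to the adapter response, it pushes
the decoded population orientation away from the adapter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import RateTrajectory


@dataclass(frozen=True)
class SuppressionParams:
    """Gain beta (fraction), recovery time constant rho (ms), adapter offset
    time t0 (ms), and the [start, end] window (ms) over which the per-unit
    mean adapter rate is taken.  The window must end at t0."""

    beta: float
    rho: float
    t0: float
    adaptation_window: tuple[float, float]

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.rho <= 0:
            raise ValueError("rho must be > 0 ms")
        start, end = self.adaptation_window
        if end <= start:
            raise ValueError("adaptation window must have positive length")
        if abs(end - self.t0) > 1e-9:
            raise ValueError("adaptation window must end at t0")


#: Named suppression regimes: gain and recovery for brief ("weak") and
#: prolonged ("strong") adapter exposure, plus the plasticity-free model.
PRESETS: dict[str, tuple[float, float]] = {
    "none": (0.0, 100.0),
    "weak": (0.20, 100.0),
    "strong": (0.50, 500.0),
}


def preset(name: str, t0: float, adaptation_window: tuple[float, float]) -> SuppressionParams:
    """Build SuppressionParams from a named preset."""
    try:
        beta, rho = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown suppression preset {name!r}; "
                         f"choose from {sorted(PRESETS)}") from None
    return SuppressionParams(beta=beta, rho=rho, t0=t0,
                             adaptation_window=tuple(adaptation_window))


def mean_adapter_rate(traj: RateTrajectory, window: tuple[float, float]) -> np.ndarray:
    """Per-unit time-averaged rate <R> (Hz) over ``window`` = [start, end] ms.

    Uses the trapezoidal time average over the trajectory samples falling in
    the window; requires at least two samples inside it.
    """
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    if start < traj.times[0] - 1e-9 or end > traj.times[-1] + 1e-9:
        raise ValueError("window must lie within the trajectory times")
    mask = (traj.times >= start - 1e-9) & (traj.times <= end + 1e-9)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    t = traj.times[mask]
    return np.trapezoid(traj.rates[mask], t, axis=0) / (t[-1] - t[0])


def apply_suppression(traj: RateTrajectory, mean_rates: np.ndarray,
                      p: SuppressionParams) -> RateTrajectory:
    """Return a trajectory with rate suppression applied for t >= t0.

    Rates before t0 are untouched; from t0 on, each unit's rate is reduced
    by beta * <R> * exp(-(t - t0)/rho) and clipped at zero.  Voltages are
    dropped from the result since the linear rate-voltage relation no longer
    holds.  With beta = 0 the rates are returned unchanged.
    """
    mean_rates = np.asarray(mean_rates, dtype=float)
    if mean_rates.shape != (traj.rates.shape[1],):
        raise ValueError("mean_rates must have one value per unit")
    if p.beta == 0.0:
        return RateTrajectory(times=traj.times, preferred=traj.preferred,
                              rates=traj.rates, voltages=None)
    if not np.any(traj.times >= p.t0 - 1e-9):
        raise ValueError("no samples at or after t0")

    dt = traj.times - p.t0
    decay = np.where(dt >= -1e-9, np.exp(-np.maximum(dt, 0.0) / p.rho), 0.0)
    correction = p.beta * decay[:, None] * mean_rates[None, :]
    rates = np.maximum(traj.rates - correction, 0.0)
    return RateTrajectory(times=traj.times, preferred=traj.preferred,
                          rates=rates, voltages=None)
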