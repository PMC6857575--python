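"""Recurrent ring network of orientation-tuned V1 units.

The model is a bank of ``n_units`` rate units evenly tiling orientation
space [0°, 180°).  Each unit is a single passive compartment whose membrane
potential follows

    tau dV/dt = -V + V_lgn + V_cortex,

where ``V_lgn`` is a weakly orientation-tuned feedforward (thalamic) drive
and ``V_cortex`` the recurrent input through a Mexican-hat profile built
from the difference of an excitatory and a broader inhibitory von Mises
function.  Firing rates are a rectified-linear function of voltage,
``R = alpha * max(V, 0)``.  Orientation is circular with period 180°, so all
von Mises functions use doubled angles.

Interfaces take degrees; radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import i0


class IntegrationError(RuntimeError):
    """The adaptive solver failed to advance; carries the failing time."""

    def __init__(self, message: str, t_ms: float | None = None):
        super().__init__(message)
        self.t_ms = t_ms


class NumericError(IntegrationError):
    """Non-finite values appeared in the simulated state."""


@dataclass(frozen=True)
class NetworkParams:
    """Constants of the recurrent ring model.

    Defaults are the parameter set fitted to tuning-curve shifts in
    anesthetized macaque V1; they were fitted with exactly 256 units, so the
    raw recurrent sum (no density normalization) makes the effective
    coupling depend on ``n_units``.

    Attributes
    ----------
    tau : float
        Membrane time constant, ms.
    alpha : float
        Rate gain, Hz per mV of suprathreshold potential.
    j_lgn : float
        Strength of the feedforward (LGN) drive, mV-scaled.
    kappa_lgn : float
        Concentration of the feedforward orientation tuning.
    j_cortex : float
        Strength of the recurrent connections, mV per Hz.
    r_ie : float
        Ratio of inhibitory to excitatory recurrent strength.
    kappa_e, kappa_i : float
        Concentrations of the excitatory and inhibitory recurrent profiles
        (excitation narrower than inhibition gives the Mexican hat).
    n_units : int
        Number of model neurons tiling [0°, 180°).
    """

    tau: float = 8.0
    alpha: float = 3.88
    j_lgn: float = 11.04
    kappa_lgn: float = 0.47
    j_cortex: float = 2.84
    r_ie: float = 1.24
    kappa_e: float = 1.12
    kappa_i: float = 0.56
    n_units: int = 256

    def __post_init__(self):
        for name in ("tau", "alpha", "j_lgn", "kappa_lgn", "j_cortex",
                     "r_ie", "kappa_e", "kappa_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_units < 8:
            raise ValueError("n_units must be at least 8")

    @property
    def preferred_orientations(self) -> np.ndarray:
        """Unit preferred orientations θ_i = i·180/n, degrees in [0, 180)."""
        return np.arange(self.n_units) * (180.0 / self.n_units)

    @property
    def unit_spacing(self) -> float:
        """Angular spacing between neighboring units, degrees."""
        return 180.0 / self.n_units


@dataclass(frozen=True)
class StimulusEpoch:
    """One constant-stimulus interval: orientation ω (deg), contrast c, duration (ms)."""

    orientation: float
    contrast: float = 1.0
    duration: float = 200.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0 ms")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        object.__setattr__(self, "orientation", float(self.orientation) % 180.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus epochs; the drive switches instantaneously between them."""

    epochs: tuple[StimulusEpoch, ...]
    label: str = ""

    def __post_init__(self):
        if len(self.epochs) == 0:
            raise ValueError("protocol needs at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    @classmethod
    def adapt_test(cls, adapter_deg: float, adapter_ms: float = 200.0,
                   test_deg: float = 0.0, test_ms: float = 500.0,
                   contrast: float = 1.0) -> "StimulusProtocol":
        """Back-to-back adapter followed immediately by a test stimulus."""
        return cls(
            epochs=(StimulusEpoch(adapter_deg, contrast, adapter_ms),
                    StimulusEpoch(test_deg, contrast, test_ms)),
            label=f"adapt{adapter_deg:+g}_test{test_deg:g}",
        )

    def rotated(self, delta_deg: float) -> "StimulusProtocol":
        """Same protocol with every epoch orientation rotated by delta."""
        return StimulusProtocol(
            epochs=tuple(replace(e, orientation=(e.orientation + delta_deg) % 180.0)
                         for e in self.epochs),
            label=self.label,
        )


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive Runge-Kutta (Dormand-Prince) settings and output grid."""

    rtol: float = 1e-6
    atol: float = 1e-9
    dt_out: float = 1.0       # output grid step, ms
    method: str = "RK45"
    keep_voltages: bool = True


@dataclass(frozen=True)
class RateTrajectory:
    """Per-unit firing rates on a regular time grid.

    ``rates[k, i]`` is the rate (Hz) of unit ``i`` (preferred orientation
    ``preferred[i]`` degrees) at time ``times[k]`` ms.  ``voltages`` is the
    matching membrane potential (mV) when retained; it is dropped by
    post-hoc transformations (e.g. rate suppression) that break the
    ``rate = alpha * max(V, 0)`` relation.
    """

    times: np.ndarray
    preferred: np.ndarray
    rates: np.ndarray
    voltages: np.ndarray | None = None

    def __post_init__(self):
        if self.rates.shape != (len(self.times), len(self.preferred)):
            raise ValueError("rates must be (n_times, n_units)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def final_rates(self) -> np.ndarray:
        return self.rates[-1]

    def index_at(self, t_ms: float) -> int:
        """Index of the grid sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def to_frame(self):
        """Long-format table (time_ms, preferred_deg, rate_hz)."""
        import pandas as pd

        t = np.repeat(self.times, len(self.preferred))
        p = np.tile(self.preferred, len(self.times))
        return pd.DataFrame({"time_ms": t, "preferred_deg": p,
                             "rate_hz": self.rates.ravel()})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tuning and connectivity
# ---------------------------------------------------------------------------

def von_mises_density(x, mu, kappa):
    """Orientation-domain von Mises density, period 180°.

    f(x | mu, kappa) = exp(kappa * cos(2(x - mu))) / (2 pi I0(kappa)),
    with x, mu in degrees (converted to radians internally) and I0 the
    modified Bessel function of order zero.  kappa = 0 gives the uniform
    circular density 1/(2 pi).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    d = np.radians(np.asarray(x, dtype=float) - np.asarray(mu, dtype=float))
    return np.exp(kappa * np.cos(2.0 * d)) / (2.0 * np.pi * i0(kappa))


def lgn_drive(theta, omega, c, params: NetworkParams):
    """Feedforward potential V_lgn = c * J_lgn * f(omega | theta, kappa_lgn), mV.

    theta is the unit's preferred orientation, omega the stimulus
    orientation (both degrees), c the stimulus contrast (>= 0).
    """
    if np.any(np.asarray(c, dtype=float) < 0):
        raise ValueError("contrast must be nonnegative")
    return c * params.j_lgn * von_mises_density(omega, theta, params.kappa_lgn)


def connection_profile(params: NetworkParams, phi_minus_theta):
    """Recurrent weight as a function of the preferred-orientation difference.

    F(d) = J_cortex * (f(d | 0, kappa_E) - r_IE * f(d | 0, kappa_I)), mV/Hz:
    narrow excitation minus broader inhibition (Mexican hat), even in d and
    180°-periodic.
    """
    return params.j_cortex * (
        von_mises_density(phi_minus_theta, 0.0, params.kappa_e)
        - params.r_ie * von_mises_density(phi_minus_theta, 0.0, params.kappa_i)
    )


def connection_matrix(params: NetworkParams) -> np.ndarray:
    """Recurrent weight matrix W[i, j] = F(theta_j - theta_i) * dphi.

    The recurrent input sum_j W[i, j] * R_j is the Riemann approximation of
    the integral of F against the population rate over orientation space,
    with dphi = pi / n_units (the profile F is a difference of angular
    densities, per radian of doubled-angle space).  This keeps the loop gain
    independent of the unit count: the dominant Fourier mode of the
    recurrence has gain just below one with the default constants, which is
    what makes the hill of activity drift slowly.  An unnormalized sum
    would multiply the gain by n_units/pi and the network would diverge.
    """
    theta = params.preferred_orientations
    dphi = np.pi / params.n_units
    return connection_profile(params, theta[None, :] - theta[:, None]) * dphi


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _output_grid(total_ms: float, dt: float) -> np.ndarray:
    n = int(round(total_ms / dt))
    grid = np.arange(n + 1) * dt
    if grid[-1] < total_ms - 1e-9:
        grid = np.append(grid, total_ms)
    else:
        grid[-1] = total_ms
    return grid


def simulate(protocol: StimulusProtocol,
             params: NetworkParams | None = None,
             solver: SolverSettings | None = None) -> RateTrajectory:
    """Integrate the network through a stimulus protocol from rest (V = 0).

    Each epoch applies a constant feedforward drive; the drive switches
    instantaneously at epoch boundaries.  Each epoch is integrated
    separately (the previous final state seeds the next) so the adaptive
    solver never steps across a discontinuity.  Output is sampled on a
    regular grid of step ``solver.dt_out`` spanning the whole protocol.
    """
    params = params or NetworkParams()
    solver = solver or SolverSettings()
    theta = params.preferred_orientations
    w = connection_matrix(params)
    tau, alpha = params.tau, params.alpha

    t_out = _output_grid(protocol.total_duration, solver.dt_out)
    volts = np.empty((len(t_out), params.n_units))
    volts[0] = 0.0

    state = np.zeros(params.n_units)
    t_start = 0.0
    for epoch in protocol.epochs:
        t_end = t_start + epoch.duration
        drive = lgn_drive(theta, epoch.orientation, epoch.contrast, params)

        def rhs(t, v, drive=drive):
            return (-v + drive + w @ (alpha * np.maximum(v, 0.0))) / tau

        in_epoch = (t_out > t_start + 1e-9) & (t_out <= t_end + 1e-9)
        t_eval = np.unique(np.append(t_out[in_epoch], t_end))
        sol = solve_ivp(rhs, (t_start, t_end), state, method=solver.method,
                        rtol=solver.rtol, atol=solver.atol, t_eval=t_eval)
        if not sol.success:
            raise IntegrationError(
                f"solver failed in epoch '{epoch.orientation:g} deg': "
                f"{sol.message}", t_ms=float(sol.t[-1]) if len(sol.t) else t_start)
        if not np.all(np.isfinite(sol.y)):
            raise NumericError("non-finite state during integration",
                               t_ms=float(sol.t[-1]))
        state = sol.y[:, -1].copy()
        # map the evaluated samples back onto the output grid
        idx = np.nonzero(in_epoch)[0]
        eval_pos = np.searchsorted(sol.t, t_out[in_epoch])
        volts[idx] = sol.y[:, np.clip(eval_pos, 0, len(sol.t) - 1)].T
        t_start = t_end

    rates = alpha * np.maximum(volts, 0.0)
    return RateTrajectory(times=t_out, preferred=theta, rates=rates,
                          voltages=volts if solver.keep_voltages else None)
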