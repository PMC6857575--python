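"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the Bessel function is
summed from its power series instead of calling scipy.special.i0, and the
network is integrated with a fixed-step forward-Euler loop instead of the
adaptive solver.
"""

import math

import numpy as np


def bessel_i0_series(x: float, n_terms: int = 40) -> float:
    """Modified Bessel function of order zero from its power series:
    I0(x) = sum_m ((x/2)^(2m) / (m!)^2)."""
    total = 0.0
    for m in range(n_terms):
        total += (x / 2.0) ** (2 * m) / math.factorial(m) ** 2
    return total


def von_mises_ref(x_deg: float, mu_deg: float, kappa: float) -> float:
    """Period-180° von Mises density via the series Bessel oracle."""
    d = math.radians(x_deg - mu_deg)
    return math.exp(kappa * math.cos(2.0 * d)) / (2.0 * math.pi * bessel_i0_series(kappa))


def euler_simulate(protocol, params, dt: float = 0.01, out_dt: float = 1.0):
    """Fixed-step forward-Euler integration of the ring network.

    Returns (times, rates) on an ``out_dt`` grid.  Written as an explicit
    loop over scalar weights so it shares no code with the package's
    simulator beyond numpy primitives.
    """
    n = params.n_units
    theta = np.arange(n) * (180.0 / n)
    dphi = math.pi / n
    w = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            w[i, j] = params.j_cortex * (
                von_mises_ref(theta[j], theta[i], params.kappa_e)
                - params.r_ie * von_mises_ref(theta[j], theta[i], params.kappa_i)
            ) * dphi

    total = sum(e.duration for e in protocol.epochs)
    n_out = int(round(total / out_dt)) + 1
    times = np.arange(n_out) * out_dt
    rates_out = np.zeros((n_out, n))

    per_out = int(round(out_dt / dt))  # steps per output sample
    v = np.zeros(n)
    step = 0
    for epoch in protocol.epochs:
        drive = np.array([
            epoch.contrast * params.j_lgn
            * von_mises_ref(epoch.orientation, th, params.kappa_lgn)
            for th in theta])
        n_steps = int(round(epoch.duration / dt))
        for _ in range(n_steps):
            r = params.alpha * np.maximum(v, 0.0)
            v = v + dt * (-v + drive + w @ r) / params.tau
            step += 1
            if step % per_out == 0:
                rates_out[step // per_out] = params.alpha * np.maximum(v, 0.0)
    return times, rates_out
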