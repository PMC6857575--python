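"""Model-predicted tilt aftereffect (TAE) from paired adapter simulations.

The TAE prediction mirrors the behavioral definition: the network is run
through two protocols that differ only in the adapter orientation (+Δ and
-Δ around the 0° test), the population is decoded with the labeled-line
readout, and the TAE at each time after test onset is the difference of the
two decoded orientations.  Positive values mean the percept is attracted
toward the adapter.  Rate suppression (a named preset or explicit
parameters) is applied to the readout rates with onset at the test onset
and gain set by the mean adapter-epoch response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import suppression as supp
from .decoder import decode_timecourse, orientation_difference
from .network import NetworkParams, SolverSettings, StimulusProtocol, simulate

#: Sentinel returned by :func:`tae_decay_time` when the TAE never settles
#: below threshold within the simulated window.
NOT_REACHED = math.inf


@dataclass(frozen=True)
class TAEPrediction:
    """TAE time course after test onset.

    ``tae[k]`` (degrees) is decoded(+Δ adapter) − decoded(−Δ adapter) at
    ``time_since_test_onset[k]`` ms; positive = attractive (percept pulled
    toward the adapter).
    """

    time_since_test_onset: np.ndarray
    tae: np.ndarray
    variant: str
    adapter_offset: float
    adapter_duration: float
    metadata: dict = field(default_factory=dict)

    def tae_at(self, t_ms: float, mode: str = "instantaneous") -> float:
        """TAE at ``t_ms`` after test onset.

        ``mode="instantaneous"`` interpolates the time course at t_ms;
        ``mode="averaged"`` averages the time course over [0, t_ms], a proxy
        for an observer integrating over the whole test presentation.
        """
        t = self.time_since_test_onset
        if mode == "instantaneous":
            return float(np.interp(t_ms, t, self.tae))
        if mode == "averaged":
            mask = t <= t_ms + 1e-9
            if mask.sum() < 2:
                return float(np.interp(t_ms, t, self.tae))
            return float(np.trapezoid(self.tae[mask], t[mask]) / (t[mask][-1] - t[mask][0]))
        raise ValueError("mode must be 'instantaneous' or 'averaged'")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.time_since_test_onset,
                             "tae_deg": self.tae})


def _decode_condition(adapter_deg: float, test_deg: float, adapter_ms: float,
                      window_ms: float, contrast: float, variant,
                      params: NetworkParams, solver: SolverSettings):
    """Simulate one adapter->test protocol, apply suppression, decode."""
    protocol = StimulusProtocol.adapt_test(adapter_deg, adapter_ms=adapter_ms,
                                           test_deg=test_deg, test_ms=window_ms,
                                           contrast=contrast)
    traj = simulate(protocol, params, solver)
    sp = _suppression_params(variant, adapter_ms)
    if sp.beta > 0:
        mean_rates = supp.mean_adapter_rate(traj, sp.adaptation_window)
        traj = supp.apply_suppression(traj, mean_rates, sp)
    return traj, decode_timecourse(traj)


def _suppression_params(variant, adapter_ms: float) -> supp.SuppressionParams:
    if isinstance(variant, supp.SuppressionParams):
        return variant
    if isinstance(variant, str):
        return supp.preset(variant, t0=adapter_ms,
                           adaptation_window=(0.0, adapter_ms))
    beta, rho = variant  # arbitrary (beta, rho) pair
    return supp.SuppressionParams(beta=beta, rho=rho, t0=adapter_ms,
                                  adaptation_window=(0.0, adapter_ms))


def predict_tae(params: NetworkParams | None = None,
                adapter_offset: float = 20.0,
                adapter_duration: float = 200.0,
                window_ms: float = 500.0,
                variant="none",
                test_orientation: float = 0.0,
                contrast: float = 1.0,
                solver: SolverSettings | None = None) -> TAEPrediction:
    """Predicted TAE time course for a ±``adapter_offset`` adapter pair.

    Runs the network through (test + Δ adapter, then test) and
    (test − Δ adapter, then test), applies the chosen suppression variant
    (preset name, (beta, rho) pair, or SuppressionParams) with onset at test
    onset and gain from the adapter-epoch mean rates, decodes both with the
    labeled-line readout, and returns their difference on the post-onset
    grid.  Positive TAE = attractive.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    params = params or NetworkParams()
    solver = solver or SolverSettings()

    decodes = []
    for sign in (+1.0, -1.0):
        _, trace = _decode_condition(test_orientation + sign * adapter_offset,
                                     test_orientation, adapter_duration,
                                     window_ms, contrast, variant, params, solver)
        post = trace.times >= adapter_duration - 1e-9
        rel = orientation_difference(trace.orientation[post], test_orientation)
        decodes.append((trace.times[post] - adapter_duration, rel))

    t_plus, d_plus = decodes[0]
    _, d_minus = decodes[1]
    variant_name = variant if isinstance(variant, str) else "custom"
    sp = _suppression_params(variant, adapter_duration)
    return TAEPrediction(
        time_since_test_onset=t_plus,
        tae=d_plus - d_minus,
        variant=variant_name,
        adapter_offset=adapter_offset,
        adapter_duration=adapter_duration,
        metadata={"beta": sp.beta, "rho": sp.rho, "contrast": contrast,
                  "test_orientation": test_orientation,
                  "n_units": params.n_units, "window_ms": window_ms},
    )


def predict_tae_variants(variants=("none", "weak", "strong"),
                         params: NetworkParams | None = None,
                         adapter_offset: float = 20.0,
                         adapter_duration: float = 200.0,
                         window_ms: float = 500.0,
                         test_orientation: float = 0.0,
                         contrast: float = 1.0,
                         solver: SolverSettings | None = None) -> dict[str, TAEPrediction]:
    """TAE time courses for several suppression variants sharing one pair of
    underlying simulations (suppression is a post-hoc rate correction, so
    the expensive network integration is reused across variants)."""
    params = params or NetworkParams()
    solver = solver or SolverSettings()

    trajs = {}
    for sign in (+1.0, -1.0):
        protocol = StimulusProtocol.adapt_test(
            test_orientation + sign * adapter_offset,
            adapter_ms=adapter_duration, test_deg=test_orientation,
            test_ms=window_ms, contrast=contrast)
        trajs[sign] = simulate(protocol, params, solver)

    out = {}
    for variant in variants:
        sp = _suppression_params(variant, adapter_duration)
        rel = {}
        for sign, traj in trajs.items():
            if sp.beta > 0:
                mean_rates = supp.mean_adapter_rate(traj, sp.adaptation_window)
                traj_v = supp.apply_suppression(traj, mean_rates, sp)
            else:
                traj_v = traj
            trace = decode_timecourse(traj_v)
            post = trace.times >= adapter_duration - 1e-9
            rel[sign] = (trace.times[post] - adapter_duration,
                         orientation_difference(trace.orientation[post],
                                                test_orientation))
        t_post = rel[+1.0][0]
        name = variant if isinstance(variant, str) else "custom"
        out[name] = TAEPrediction(
            time_since_test_onset=t_post,
            tae=rel[+1.0][1] - rel[-1.0][1],
            variant=name, adapter_offset=adapter_offset,
            adapter_duration=adapter_duration,
            metadata={"beta": sp.beta, "rho": sp.rho, "contrast": contrast,
                      "test_orientation": test_orientation,
                      "n_units": params.n_units, "window_ms": window_ms},
        )
    return out


def tae_decay_time(pred: TAEPrediction, threshold: float = 1.0) -> float:
    """First time after test onset at which |TAE| drops below ``threshold``
    degrees and stays below for the rest of the simulated window.

    Returns 0.0 if the TAE never reaches the threshold, and the sentinel
    ``NOT_REACHED`` (inf) if it is still above threshold at the end.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = np.abs(pred.tae) >= threshold
    if not above.any():
        return 0.0
    last = int(np.nonzero(above)[0][-1])
    if last == len(pred.tae) - 1:
        return NOT_REACHED
    return float(pred.time_since_test_onset[last + 1])
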