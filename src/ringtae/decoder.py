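"""Labeled-line readout of the population orientation.

Each unit's firing is evidence for its fixed preferred orientation; the
percept is the rate-weighted center of population activity.  Because
orientation is circular with period 180°, the weighted center is computed
as a circular mean on doubled angles (the population vector): each unit
contributes a phasor r_i * exp(i * 2 * theta_i); the decoded orientation is
half the argument of the summed phasor.  For activity concentrated well
away from the wrap point this coincides with the arithmetic rate-weighted
mean of the preferred orientations, which is available as an alternative
mode for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import RateTrajectory

#: Resultant lengths below this are treated as a degenerate (uninformative)
#: population state.
MIN_RESULTANT = 1e-6


class DecodeError(ValueError):
    pass


class UndefinedDecodeError(DecodeError):
    """Total population rate is zero: no labeled lines are active."""


class DegenerateDecodeError(DecodeError):
    """Activity is (near-)uniform: the population vector has no direction."""


@dataclass(frozen=True)
class DecodedTrace:
    """Decoded orientation over time.

    ``orientation`` is in degrees [0, 180), NaN where the decode is
    undefined or degenerate; ``resultant`` in [0, 1] measures how
    concentrated the activity is; ``valid`` marks usable samples.
    """

    times: np.ndarray
    orientation: np.ndarray
    resultant: np.ndarray
    valid: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times,
                             "decoded_deg": self.orientation,
                             "resultant": self.resultant})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def wrap_orientation(deg):
    """Reduce an orientation to [0, 180)."""
    return np.asarray(deg, dtype=float) % 180.0


def orientation_difference(a_deg, b_deg):
    """Signed circular difference a - b in degrees, wrapped to (-90, 90]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)


def _population_vector(rates: np.ndarray, preferred: np.ndarray):
    total = rates.sum(axis=-1)
    ang = np.radians(2.0 * preferred)
    c = rates @ np.cos(ang)
    s = rates @ np.sin(ang)
    with np.errstate(invalid="ignore", divide="ignore"):
        resultant = np.hypot(c, s) / total
    orientation = wrap_orientation(np.degrees(np.arctan2(s, c)) / 2.0)
    return total, resultant, orientation


def decode_orientation(rates, preferred, mode: str = "circular",
                       min_resultant: float = MIN_RESULTANT) -> float:
    """Decode one rate vector into an orientation in degrees [0, 180).

    Parameters
    ----------
    rates, preferred : array_like
        Per-unit firing rates (Hz, nonnegative) and preferred orientations
        (degrees).
    mode : {"circular", "arithmetic"}
        "circular" (default) is the population vector on doubled angles;
        "arithmetic" is the plain rate-weighted mean of the preferred
        orientations (frame-dependent; for sensitivity checks only).

    Raises
    ------
    UndefinedDecodeError
        If all rates are zero.
    DegenerateDecodeError
        If the resultant length falls below ``min_resultant`` (circular
        mode), e.g. two equal bumps 90° apart.
    """
    rates = np.asarray(rates, dtype=float)
    preferred = np.asarray(preferred, dtype=float)
    if rates.shape != preferred.shape or rates.ndim != 1:
        raise ValueError("rates and preferred must be matching 1-D arrays")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    total = rates.sum()
    if total <= 0:
        raise UndefinedDecodeError("all rates are zero")
    if mode == "arithmetic":
        return float(rates @ preferred / total)
    if mode != "circular":
        raise ValueError("mode must be 'circular' or 'arithmetic'")
    _, resultant, orientation = _population_vector(rates, preferred)
    if resultant < min_resultant:
        raise DegenerateDecodeError(
            f"resultant length {resultant:.2e} below {min_resultant:g}")
    return float(orientation)


def decode_timecourse(traj: RateTrajectory,
                      min_resultant: float = MIN_RESULTANT) -> DecodedTrace:
    """Decode every sample of a trajectory; degenerate samples are flagged
    (NaN orientation, valid=False), never interpolated."""
    total, resultant, orientation = _population_vector(traj.rates, traj.preferred)
    valid = (total > 0) & (resultant >= min_resultant)
    orientation = np.where(valid, orientation, np.nan)
    resultant = np.where(total > 0, resultant, 0.0)
    return DecodedTrace(times=traj.times, orientation=orientation,
                        resultant=resultant, valid=valid)
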