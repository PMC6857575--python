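"""Generative observer and session design for end-to-end testing.

Emulates the short-term adaptation trial design — a fresh random adapter
orientation every trial, a reference offset of ±20° with uniform jitter,
brief tests of several durations, interleaved catch trials — together with
a stochastic observer whose point of subjective equality is displaced
toward the adapter by a duration-dependent amount.  Sessions are fully
reproducible from their seed and are consumed directly by the
:mod:`ringtae.psychophysics` analysis chain, which should recover a TAE of
twice the per-condition shift.

The observer answers the signed test-minus-reference offset through the
same lapse-corrected logistic the analysis fits.  An attractive shift of
``s`` degrees at some duration displaces the PSE to ``+s`` in the plus
condition (reference offset > 0) and ``-s`` in the minus condition, so the
fitted PSE difference is ``2 s`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .psychophysics import TRIAL_COLUMNS
from .tae import TAEPrediction

#: Constant-stimuli grid of test-minus-reference offsets, degrees.
DEFAULT_TEST_OFFSETS = (-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0)


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer.

    pse_shift_by_duration maps test duration (ms) to the per-condition
    attractive PSE shift (degrees, positive = toward the adapter); slope
    (per degree) and lapse define the response logistic; catch_visibility
    in [0, 0.5] raises the probability of an adapter-consistent response on
    catch trials above chance (0 = the adapter is perfectly invisible).
    """

    pse_shift_by_duration: dict[float, float]
    slope: float = 0.5
    lapse: float = 0.02
    catch_visibility: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0.0 <= self.lapse <= 0.2:
            raise ValueError("lapse must be in [0, 0.2]")
        if not 0.0 <= self.catch_visibility <= 0.5:
            raise ValueError("catch_visibility must be in [0, 0.5]")
        object.__setattr__(self, "pse_shift_by_duration",
                           {float(k): float(v)
                            for k, v in self.pse_shift_by_duration.items()})

    def shift(self, duration_ms: float) -> float:
        try:
            return self.pse_shift_by_duration[float(duration_ms)]
        except KeyError:
            raise ValueError(
                f"observer has no PSE shift for duration {duration_ms} ms; "
                f"known durations: {sorted(self.pse_shift_by_duration)}"
            ) from None


@dataclass(frozen=True)
class SessionDesign:
    """Trial-structure parameters of one session.

    Per trial: adapter orientation uniform on [0°, 180°); reference offset
    sign ±1 equiprobable with magnitude uniform in ``ref_offset_range``;
    test durations cycled in balanced proportion then shuffled; 10% of
    trials are catch trials (no test stimulus, test offset NaN); non-catch
    test offsets drawn uniformly from the constant-stimuli grid.
    """

    n_trials: int = 4000
    durations: tuple[float, ...] = (50.0, 100.0, 200.0)
    ref_offset_range: tuple[float, float] = (17.0, 23.0)
    catch_fraction: float = 0.10
    test_offsets: tuple[float, ...] = DEFAULT_TEST_OFFSETS
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.catch_fraction < 1.0:
            raise ValueError("catch_fraction must be in [0, 1)")
        if len(self.durations) == 0 or len(self.test_offsets) == 0:
            raise ValueError("durations and test_offsets must be nonempty")


def generate_session(design: SessionDesign, observer: ObserverParams,
                     subject: str = "synth") -> pd.DataFrame:
    """Simulate one session; returns a TRIAL_COLUMNS DataFrame.

    A single pseudo-random stream keyed by ``design.seed`` (and
    ``observer.seed`` when set) drives the whole session; draws happen in a
    fixed order (durations shuffle, then per-trial adapter, offset sign,
    offset magnitude, catch flag, test offset, response), so identical
    seeds reproduce identical tables.
    """
    for d in design.durations:
        observer.shift(d)  # fail fast on a missing duration key
    entropy = (design.seed,) if observer.seed is None \
        else (design.seed, observer.seed)
    rng = np.random.default_rng(entropy)
    n = design.n_trials

    durations = np.resize(np.asarray(design.durations, dtype=float), n)
    rng.shuffle(durations)
    adapter = rng.uniform(0.0, 180.0, size=n)
    sign = rng.choice((-1.0, 1.0), size=n)
    magnitude = rng.uniform(*design.ref_offset_range, size=n)
    ref_offset = sign * magnitude
    is_catch = rng.random(size=n) < design.catch_fraction
    test_offset = rng.choice(np.asarray(design.test_offsets, dtype=float), size=n)
    test_offset[is_catch] = np.nan

    shifts = np.array([observer.shift(d) for d in durations])
    pse = sign * shifts
    p_cw = observer.lapse + (1.0 - 2.0 * observer.lapse) * expit(
        observer.slope * (test_offset - pse))
    # catch trials: adapter-consistent response (report CW iff the adapter is
    # clockwise of the reference, i.e. ref_offset < 0) with probability
    # 0.5 + catch_visibility
    p_consistent = 0.5 + observer.catch_visibility
    p_cw = np.where(is_catch,
                    np.where(ref_offset < 0, p_consistent, 1.0 - p_consistent),
                    p_cw)
    response = rng.random(size=n) < p_cw

    return pd.DataFrame({
        "subject": subject,
        "adapter_deg": adapter,
        "ref_offset_deg": ref_offset,
        "test_offset_deg": test_offset,
        "duration_ms": durations,
        "is_catch": is_catch,
        "response_cw": response,
    })[TRIAL_COLUMNS]


def model_linked_observer(pred, durations=(50.0, 100.0, 200.0),
                          slope: float = 0.5, lapse: float = 0.02,
                          seed: int | None = None,
                          readout_mode: str = "instantaneous") -> ObserverParams:
    """Observer whose expected fitted TAE-vs-duration curve equals a model
    prediction: the per-condition shift at each test duration is half the
    predicted TAE evaluated at that time after test onset.

    ``pred`` is either a single :class:`TAEPrediction` (evaluated at each
    duration) or a mapping from duration to prediction/TAE value.
    """
    shifts = {}
    for d in durations:
        if isinstance(pred, TAEPrediction):
            tae = pred.tae_at(d, mode=readout_mode)
        else:
            v = pred[d]
            tae = v.tae_at(d, mode=readout_mode) if isinstance(v, TAEPrediction) \
                else float(v)
        shifts[float(d)] = tae / 2.0
    return ObserverParams(pse_shift_by_duration=shifts, slope=slope,
                          lapse=lapse, seed=seed)
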