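"""Behavioral analysis: psychometric fits, PSE-difference TAE, Monte Carlo
PSE comparison, and catch-trial visibility.

Trial tables are pandas DataFrames with the columns in ``TRIAL_COLUMNS``.
Angles follow a fixed screen convention in which positive offsets are
clockwise rotations; ``ref_offset_deg`` is the reference orientation minus
the adapter orientation, so trials split into a "plus" condition
(ref_offset > 0; the adapter is counterclockwise of the reference) and a
"minus" condition (ref_offset < 0).  ``response_cw`` records whether the
subject reported the test (adapted-side) stimulus as more clockwise than
the reference.

The psychometric model is a logistic with a single symmetric lapse rate:

    P(CW | x) = lambda + (1 - 2 lambda) / (1 + exp(-s (x - pse))),

with x the test-minus-reference offset in degrees.  Analysis follows a
two-stage scheme: the lapse rate is first estimated from the two adapter
conditions pooled, then each condition is refit with the lapse fixed.  The
TAE is the difference of the two PSEs, oriented so that positive values
mean the perceived test was attracted toward the adapter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import binomtest, norm

TRIAL_COLUMNS = ["subject", "adapter_deg", "ref_offset_deg",
                 "test_offset_deg", "duration_ms", "is_catch", "response_cw"]

#: Fitted slopes outside this range (per degree) indicate a degenerate fit:
#: below, the curve is flat and the PSE unidentifiable; above, the data are
#: (near-)perfectly separated and the MLE slope is unbounded.
SLOPE_FLOOR = 0.02
SLOPE_CEILING = 25.0

_SLOPE_BOUNDS = (1e-4, 100.0)


class FitDegenerateError(RuntimeError):
    """Raised when the psychometric MLE is unidentifiable (flat curve) or
    unbounded (perfect separation); carries fit diagnostics."""

    def __init__(self, message: str, pse=None, slope=None):
        super().__init__(message)
        self.pse = pse
        self.slope = slope


@dataclass
class PsychometricFit:
    """Logistic psychometric fit for one condition.

    pse : degrees, 50% point of the lapse-corrected curve.
    slope : per degree.
    lapse : symmetric lapse/guess rate in [0, 0.2].
    lapse_fixed : whether the lapse was held fixed during the fit.
    pse_samples : optional parametric-bootstrap PSE draws for CIs.
    """

    pse: float
    slope: float
    lapse: float
    n_trials: int
    condition: str = ""
    lapse_fixed: bool = False
    nll: float = np.nan
    pse_samples: np.ndarray | None = field(default=None, repr=False)

    def predict(self, x):
        """P(CW) at offset x; lies in [lapse, 1 - lapse]."""
        return self.lapse + (1.0 - 2.0 * self.lapse) * expit(
            self.slope * (np.asarray(x, dtype=float) - self.pse))

    def pse_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Bootstrap percentile CI for the PSE (requires pse_samples)."""
        if self.pse_samples is None or len(self.pse_samples) == 0:
            raise ValueError("fit carries no bootstrap samples")
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(self.pse_samples, [lo, 1.0 - lo]))


# ---------------------------------------------------------------------------
# Trial-table plumbing
# ---------------------------------------------------------------------------

def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["is_catch"] = df["is_catch"].astype(bool)
    df["response_cw"] = df["response_cw"].astype(bool)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def split_by_offset_sign(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group non-catch trials by the SIGN of the reference offset only
    (the jitter around the ±20° mean is ignored, as in the main analysis).
    Returns {"plus": ..., "minus": ...}."""
    t = trials[~trials["is_catch"]]
    return {"plus": t[t["ref_offset_deg"] > 0],
            "minus": t[t["ref_offset_deg"] < 0]}


def _offsets_responses(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        t = trials[~trials["is_catch"]] if "is_catch" in trials else trials
        x = t["test_offset_deg"].to_numpy(dtype=float)
        y = t["response_cw"].to_numpy(dtype=bool)
    else:
        x, y = trials
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=bool)
    if len(x) != len(y):
        raise ValueError("offsets and responses must have equal length")
    return x, y


def _aggregate(x: np.ndarray, y: np.ndarray):
    """Collapse trials to (unique offsets, n trials, n CW responses)."""
    xs, inv = np.unique(x, return_inverse=True)
    n = np.bincount(inv, minlength=len(xs)).astype(float)
    k = np.bincount(inv, weights=y.astype(float), minlength=len(xs))
    return xs, n, k


# ---------------------------------------------------------------------------
# Maximum-likelihood logistic fit
# ---------------------------------------------------------------------------

def _nll(xs, n, k, pse, slope, lapse):
    p = lapse + (1.0 - 2.0 * lapse) * expit(slope * (xs - pse))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(k @ np.log(p) + (n - k) @ np.log1p(-p))


def _initial_guess(xs, n, k):
    """Rough start: PSE from the 50% crossing of linearly interpolated
    proportions, slope from a probit regression on the proportions."""
    p = (k + 0.5) / (n + 1.0)
    if np.any(p > 0.5) and np.any(p < 0.5):
        pse0 = float(np.interp(0.0, p - 0.5, xs))
    else:
        pse0 = float(np.average(xs, weights=n))
    z = norm.ppf(np.clip(p, 0.05, 0.95))
    xbar = np.average(xs, weights=n)
    var_x = np.average((xs - xbar) ** 2, weights=n)
    if var_x > 0:
        cov = np.average((xs - xbar) * (z - np.average(z, weights=n)), weights=n)
        slope0 = 1.7 * cov / var_x  # probit-to-logit scale factor
    else:
        slope0 = 0.5
    slope0 = float(np.clip(slope0, 0.05, 5.0))
    return pse0, slope0


def _nll_grad(xs, n, k, pse, slope, lapse, free_lapse):
    """Bernoulli NLL and its analytic gradient in (pse, slope[, lapse])."""
    sig = expit(slope * (xs - pse))
    p = lapse + (1.0 - 2.0 * lapse) * sig
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -float(k @ np.log(p) + (n - k) @ np.log1p(-p))
    dl_dp = -(k / p - (n - k) / (1.0 - p))
    dsig = (1.0 - 2.0 * lapse) * sig * (1.0 - sig)
    g_pse = float(dl_dp @ (dsig * (-slope)))
    g_slope = float(dl_dp @ (dsig * (xs - pse)))
    if free_lapse:
        g_lapse = float(dl_dp @ (1.0 - 2.0 * sig))
        return nll, np.array([g_pse, g_slope, g_lapse])
    return nll, np.array([g_pse, g_slope])


def _fit_ml(xs, n, k, fixed_lapse, lapse_bound, starts):
    x_span = max(xs.max() - xs.min(), 1.0)
    pse_bounds = (xs.min() - 2.0 * x_span, xs.max() + 2.0 * x_span)
    best = None
    for pse0, slope0, lapse0 in starts:
        pse0 = float(np.clip(pse0, *pse_bounds))
        if fixed_lapse is None:
            def fun(q):
                return _nll_grad(xs, n, k, q[0], q[1], q[2], True)
            res = minimize(fun, [pse0, slope0, lapse0], method="L-BFGS-B",
                           jac=True,
                           bounds=[pse_bounds, _SLOPE_BOUNDS, (0.0, lapse_bound)])
        else:
            def fun(q):
                return _nll_grad(xs, n, k, q[0], q[1], fixed_lapse, False)
            res = minimize(fun, [pse0, slope0], method="L-BFGS-B", jac=True,
                           bounds=[pse_bounds, _SLOPE_BOUNDS])
        if best is None or res.fun < best.fun:
            best = res
    pse, slope = float(best.x[0]), float(best.x[1])
    lapse = fixed_lapse if fixed_lapse is not None else float(best.x[2])
    return pse, slope, lapse, float(best.fun)


def fit_logistic(trials, fixed_lapse: float | None = None, *,
                 condition: str = "", lapse_bound: float = 0.2,
                 n_bootstrap: int = 0, seed=None,
                 check_degenerate: bool = True) -> PsychometricFit:
    """Maximum-likelihood logistic psychometric fit for one condition.

    Parameters
    ----------
    trials : DataFrame (TRIAL_COLUMNS) or (offsets, responses) pair
        Binary CW/CCW responses at signed test offsets; catch trials are
        dropped automatically from DataFrames.
    fixed_lapse : float, optional
        Hold the lapse rate fixed at this value (second analysis stage);
        otherwise the lapse is free in [0, lapse_bound].
    n_bootstrap : int
        If > 0, attach that many parametric-bootstrap PSE draws
        (responses resimulated from the fitted curve at the observed
        placements, then refit) for confidence intervals.

    The optimizer runs from three perturbed starts (PSE from the 50%
    crossing of interpolated proportions, slope from a probit rough fit)
    and keeps the best likelihood, making the fit deterministic for fixed
    input.

    Raises
    ------
    FitDegenerateError
        If the fitted slope hits the flat floor (PSE unidentifiable, e.g.
        50/50 responses everywhere) or the separation ceiling.
    ValueError
        Fewer than two distinct offsets, or invalid fixed_lapse.
    """
    x, y = _offsets_responses(trials)
    xs, n, k = _aggregate(x, y)
    if len(xs) < 2:
        raise ValueError("need responses at >= 2 distinct test offsets")
    if fixed_lapse is not None and not 0.0 <= fixed_lapse <= 0.2:
        raise ValueError("fixed_lapse must be in [0, 0.2]")

    pse0, slope0 = _initial_guess(xs, n, k)
    starts = [(pse0, slope0, 0.02),
              (pse0 + 2.0, 2.0 * slope0, 0.05),
              (pse0 - 2.0, 0.5 * slope0, 0.0)]
    pse, slope, lapse, nll = _fit_ml(xs, n, k, fixed_lapse, lapse_bound, starts)

    if check_degenerate:
        if slope <= SLOPE_FLOOR:
            raise FitDegenerateError(
                f"flat psychometric curve (slope {slope:.4g}/deg); PSE "
                "unidentifiable", pse=pse, slope=slope)
        if slope >= SLOPE_CEILING:
            raise FitDegenerateError(
                f"(near-)perfect separation (slope {slope:.4g}/deg)",
                pse=pse, slope=slope)

    fit = PsychometricFit(pse=pse, slope=slope, lapse=lapse,
                          n_trials=int(n.sum()), condition=condition,
                          lapse_fixed=fixed_lapse is not None, nll=nll)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fit.pse_samples = _bootstrap_pses(fit, xs, n, n_bootstrap, rng)
    return fit


def _refit_from(fit: PsychometricFit, xs, n, k):
    """Single-start refit (fixed lapse) from a known fit; None on failure."""
    try:
        pse, slope, _, _ = _fit_ml(xs, n, k, fit.lapse, 0.2,
                                   [(fit.pse, fit.slope, fit.lapse)])
    except Exception:
        return None
    if not SLOPE_FLOOR < slope < SLOPE_CEILING:
        return None
    return pse, slope


def _simulate_counts(fit: PsychometricFit, xs, n, rng) -> np.ndarray:
    return rng.binomial(n.astype(int), np.clip(fit.predict(xs), 0.0, 1.0))


def _bootstrap_pses(fit, xs, n, n_resamples, rng) -> np.ndarray:
    out = []
    for _ in range(n_resamples):
        res = _refit_from(fit, xs, n, _simulate_counts(fit, xs, n, rng))
        if res is not None:
            out.append(res[0])
    return np.asarray(out)


def estimate_lapse_pooled(trials_a, trials_b, lapse_bound: float = 0.1) -> float:
    """Stage-one lapse estimate: one free-lapse logistic fit over the two
    adapter conditions pooled.  The lapse is bounded at 0.1 to prevent the
    slope-lapse trade-off; a PSE shift between the pooled conditions
    broadens the joint curve but leaves the asymptotes, and hence the
    lapse, identifiable."""
    xa, ya = _offsets_responses(trials_a)
    xb, yb = _offsets_responses(trials_b)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both trial sets must be nonempty")
    fit = fit_logistic((np.concatenate([xa, xb]), np.concatenate([ya, yb])),
                       lapse_bound=lapse_bound, condition="pooled")
    return fit.lapse


def pse_difference(fit_plus: PsychometricFit, fit_minus: PsychometricFit) -> float:
    """TAE as the PSE difference between the two adapter conditions,
    PSE(plus) − PSE(minus), in degrees.

    ``fit_plus`` must be the positive-reference-offset condition and
    ``fit_minus`` the negative one; the result is then positive when the
    perceived test was attracted toward the adapter (a per-condition
    attractive shift of s degrees appears as a difference of 2 s)."""
    return float(fit_plus.pse - fit_minus.pse)


# ---------------------------------------------------------------------------
# Monte Carlo PSE comparison
# ---------------------------------------------------------------------------

def monte_carlo_pse_test(trials_plus, trials_minus, n_resamples: int = 2000,
                         seed=None, fixed_lapse: float | None = None) -> float:
    """Two-sided Monte Carlo p-value for the PSE difference between the two
    adapter conditions.

    A parametric bootstrap: both conditions are fit (lapse fixed to the
    pooled estimate unless given), response sets are resimulated from each
    fitted curve at the observed stimulus placements and refit, and the
    resampled PSE differences re-centered at zero form the null
    distribution; the returned p-value is the (add-one corrected) two-sided
    tail probability of the observed difference.  Deterministic given seed.

    Raises RuntimeError if more than 5% of resample refits fail.
    """
    if n_resamples < 500:
        raise ValueError("n_resamples must be >= 500")
    if fixed_lapse is None:
        fixed_lapse = estimate_lapse_pooled(trials_plus, trials_minus)

    fits, placements = [], []
    for trials, name in ((trials_plus, "plus"), (trials_minus, "minus")):
        x, y = _offsets_responses(trials)
        fits.append(fit_logistic((x, y), fixed_lapse=fixed_lapse, condition=name))
        placements.append(_aggregate(x, y))
    d_obs = pse_difference(fits[0], fits[1])

    rng = np.random.default_rng(seed)
    diffs, failures = [], 0
    for _ in range(n_resamples):
        pses = []
        for fit, (xs, n, _) in zip(fits, placements):
            res = _refit_from(fit, xs, n, _simulate_counts(fit, xs, n, rng))
            if res is None:
                break
            pses.append(res[0])
        if len(pses) == 2:
            diffs.append(pses[0] - pses[1])
        else:
            failures += 1
    if failures > 0.05 * n_resamples:
        raise RuntimeError(
            f"{failures}/{n_resamples} bootstrap refits failed; data too "
            "sparse or degenerate for the Monte Carlo comparison")
    if failures:
        warnings.warn(f"{failures} bootstrap refits failed and were dropped",
                      RuntimeWarning, stacklevel=2)

    null = np.asarray(diffs) - d_obs  # re-centered at zero
    return float((1 + np.sum(np.abs(null) >= abs(d_obs))) / (len(null) + 1))


# ---------------------------------------------------------------------------
# Catch-trial visibility
# ---------------------------------------------------------------------------

def catch_visibility(catch_trials) -> tuple[float, float]:
    """Adapter visibility from catch trials (no test on the adapted side).

    A response is "consistent" when the subject reported the adapted side
    as more clockwise exactly when the adapter was clockwise of the
    reference (ref_offset < 0).  Returns (proportion consistent − 0.5,
    exact two-sided binomial p-value against chance); 0 means the adapter's
    orientation was invisible.
    """
    if isinstance(catch_trials, pd.DataFrame):
        t = catch_trials[catch_trials["is_catch"]] if "is_catch" in catch_trials \
            else catch_trials
        if len(t) == 0:
            raise ValueError("need at least one catch trial")
        consistent = (t["response_cw"].to_numpy(dtype=bool)
                      == (t["ref_offset_deg"].to_numpy(dtype=float) < 0))
    else:
        consistent = np.asarray(catch_trials, dtype=bool)
        if len(consistent) == 0:
            raise ValueError("need at least one catch trial")
    n = len(consistent)
    k = int(consistent.sum())
    return k / n - 0.5, float(binomtest(k, n, 0.5).pvalue)


# ---------------------------------------------------------------------------
# Session-level report
# ---------------------------------------------------------------------------

def analyze_session(trials: pd.DataFrame, n_resamples: int = 2000,
                    seed=None, n_bootstrap: int = 500) -> dict:
    """Full analysis of one session table, by test duration.

    Stage one estimates a single lapse rate from all non-catch trials
    pooled across adapter conditions; stage two refits each
    (duration x condition) cell with the lapse fixed and reports the TAE
    (PSE difference, positive = attractive) with bootstrap CI, the Monte
    Carlo p-value, and the catch-trial visibility.
    """
    non_catch = trials[~trials["is_catch"]]
    groups = split_by_offset_sign(trials)
    lapse = estimate_lapse_pooled(groups["plus"], groups["minus"]) \
        if len(non_catch) else 0.0

    rng = np.random.default_rng(seed)
    report = {"lapse": lapse, "n_trials": int(len(trials)), "by_duration": {}}
    for dur in sorted(non_catch["duration_ms"].unique()):
        cell, fits = {}, {}
        for name, g in groups.items():
            sub = g[g["duration_ms"] == dur]
            fits[name] = fit_logistic(
                sub, fixed_lapse=lapse, condition=f"{name}@{dur:g}ms",
                n_bootstrap=n_bootstrap, seed=int(rng.integers(2**31)))
            cell[name] = {"pse": fits[name].pse, "slope": fits[name].slope,
                          "n_trials": fits[name].n_trials}
        cell["tae_deg"] = pse_difference(fits["plus"], fits["minus"])
        if all(f.pse_samples is not None and len(f.pse_samples)
               for f in fits.values()):
            m = min(len(fits["plus"].pse_samples), len(fits["minus"].pse_samples))
            d = fits["plus"].pse_samples[:m] - fits["minus"].pse_samples[:m]
            cell["tae_ci95"] = [float(q) for q in np.quantile(d, [0.025, 0.975])]
        cell["p_monte_carlo"] = monte_carlo_pse_test(
            groups["plus"][groups["plus"]["duration_ms"] == dur],
            groups["minus"][groups["minus"]["duration_ms"] == dur],
            n_resamples=n_resamples, seed=int(rng.integers(2**31)),
            fixed_lapse=lapse)
        report["by_duration"][float(dur)] = cell

    catch = trials[trials["is_catch"]]
    if len(catch):
        vis, p = catch_visibility(catch)
        report["catch"] = {"visibility": vis, "p_binomial": p,
                           "n_trials": int(len(catch))}
    return report
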