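# Methods

This note documents the model, the analysis chain, the synthetic-data
generator, and the numerical and design choices behind them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Ring network

### Dynamics

Each of `n_units` rate units represents a V1 orientation column with
preferred orientation θ_i = i · 180°/n, i = 0 … n−1 (even tiling, no
duplicated endpoint). The membrane potential obeys

    τ dV^θ/dt + V^θ = V_lgn^θ + V_cortex^θ,
    R^θ = α max(V^θ, 0),

with the feedforward drive V_lgn^θ(ω, c) = c · J_lgn · f(ω | θ, κ_lgn) and
the recurrent input the discretized convolution of the Mexican-hat profile
F with the population rate,

    V_cortex^θ = Σ_φ F_θ(φ) R^φ Δφ,   Δφ = π / n_units.

All von Mises functions f(x | μ, κ) = exp(κ cos 2(x−μ)) / (2π I₀(κ)) have
period 180° (doubled angles), reflecting the circularity of orientation.
Interfaces use degrees; radians are used internally.

### Why the recurrent sum carries the Δφ weight

F is a difference of angular *densities* (units of 1/rad on the doubled
circle), so the natural contraction against the population rate is an
integral over orientation; the sum over units is its Riemann approximation
with weight Δφ = π/n. This choice is load-bearing. In Fourier modes (on
the doubled circle) the loop gain of mode k is

    g_k = α J_cortex · ½ (I_k(κ_E)/I₀(κ_E) − r_IE · I_k(κ_I)/I₀(κ_I)),

which with the default constants gives g₀ ≈ −1.3 (strongly stabilized mean
activity) and g₁ ≈ +0.85: the orientation-selective mode is marginally
stable, and that near-critical slowing is precisely what lets the hill of
activity linger near a previous stimulus for hundreds of milliseconds
despite τ = 8 ms. An unnormalized sum multiplies every g_k by n/π (≈ 81 at
n = 256), and the network diverges within milliseconds. With the Δφ weight
the dynamics converge as n grows, so smaller unit counts (32–64) are valid
cheap approximations in tests.

### Parameters

| name      | meaning                                   | default | units  |
|-----------|-------------------------------------------|---------|--------|
| τ         | membrane time constant                    | 8       | ms     |
| α         | suprathreshold rate gain                  | 3.88    | Hz/mV  |
| J_lgn     | feedforward drive strength                | 11.04   | mV-scaled |
| κ_lgn     | feedforward tuning concentration          | 0.47    | —      |
| J_cortex  | recurrent strength                        | 2.84    | mV/Hz  |
| r_IE      | inhibition/excitation ratio               | 1.24    | —      |
| κ_E       | excitatory profile concentration          | 1.12    | —      |
| κ_I       | inhibitory profile concentration          | 0.56    | —      |
| n_units   | number of units                           | 256     | —      |

The eight constants are the set fitted to tuning-curve shifts measured in
anesthetized macaque V1; the package treats them as given. All must be
strictly positive and n_units ≥ 8 (below that, the profile sampling and
the decoder are meaningless). Note the hat's minimum is interior: with
these κ's the profile crosses zero near ±20° and is most negative near
±59°, rising slightly toward ±90°.

Stimulus contrast for simulations defaults to c = 1.0. The contrast used
for the original simulations is not pinned by the source material; c is a
configurable field and results scale smoothly with it.

### Integration

Protocols are ordered epochs of constant (orientation, contrast, duration);
the drive switches instantaneously at epoch boundaries. Each epoch is
integrated separately with `scipy.integrate.solve_ivp` (RK45,
Dormand–Prince; rtol 1e-6, atol 1e-9), seeding each epoch with the previous
final state so the adaptive solver never steps across a discontinuity.
Output is sampled on a regular 1 ms grid (configurable). The initial
condition is rest (V = 0) at protocol start; there is no inter-trial
carryover, matching a trial design whose adapter orientation is re-randomized
every trial. Solver failure raises an error carrying the failing time;
non-finite states raise a numeric error.

The integrator is validated three ways: against the closed-form first-order
low-pass when recurrence is removed; against an independently written
fixed-step forward-Euler integration (the Euler error halves when its step
halves, converging to the adaptive trajectory at first order, with
agreement below 1e-3 Hz per unit at dt = 0.005 ms); and through exact
symmetry properties (rotational equivariance on the unit grid, reflection,
zero input ⇒ zero output).

## Rate suppression

Suppression is an output-rate correction, not a change to the recurrent
loop:

    R_adapt^θ(t) = max(0, R^θ(t) − β ⟨R^θ⟩ e^{−(t−t₀)/ρ}),  t ≥ t₀,

where ⟨R^θ⟩ is the unit's trapezoidal time-average over the adaptation
window (which must end at t₀, the adapter offset = test onset in the
back-to-back protocol). Applying it post-hoc rather than feeding it back
into the recurrence is a deliberate reading of the defining equation,
which is written as a correction of the readout rates; no feedback
coupling is specified anywhere. Negative corrected rates are clipped at
zero since rates cannot be negative. Because the suppression is *tuned*
(proportional to each unit's own adapter response), it subtracts an
adapter-centered bump from the population and pushes the decode away from
the adapter; an *untuned* (unit-uniform) suppression provably leaves the
decode unchanged when nothing clips, and the tests assert exactly that.

Presets: `none` (β = 0), `weak` (β = 0.20, ρ = 100 ms; brief adapters),
`strong` (β = 0.50, ρ = 500 ms; prolonged adaptation). The recovery
constant for the strong regime is read as ρ = 500 ms (the source states it
once with an inconsistent symbol). Arbitrary (β, ρ) pairs are accepted
everywhere presets are.

## Labeled-line decoder

The percept is the rate-weighted center of population activity. "Weighted
sum of preferred orientations" is implemented as the circular mean on
doubled angles (population vector): z = Σ_i R_i e^{i·2θ_i}, decode =
½ arg z. An arithmetic weighted mean of angle values is frame-dependent
(its value changes under a global rotation of all orientations) and breaks
equivariance at the 0°/180° wrap, so the circular form is the default; the
arithmetic variant is retained as a sensitivity-check mode, and the two
agree closely for activity concentrated away from the wrap. Normalization
is implicit in the circular mean, making the decode invariant to uniform
rate scaling. A total rate of zero is an undefined decode; a resultant
length below 1e-6 (configurable) — e.g. two equal bumps 90° apart — is a
degenerate decode. Time-course decoding flags such samples rather than
interpolating them.

## TAE prediction

Two protocols are simulated that differ only in the adapter: test+Δ and
test−Δ (default Δ = 20°, 200 ms adapter, 0° test, 500 ms post-onset
window — long enough to measure decay past 300 ms). The chosen
suppression variant is applied with t₀ = test onset and the adaptation
window equal to the adapter epoch; both trajectories are decoded and

    TAE(t) = decode_{+Δ}(t) − decode_{−Δ}(t)

on the post-onset grid. This full difference (not halved) mirrors the
behavioral definition of the TAE as a PSE difference between the two
adapter conditions; it is antisymmetric under Δ → −Δ by construction and
invariant to a global rotation of both conditions. The per-duration
operating point is the *instantaneous* decode at t = test duration (the
shortest behavioral test being 50 ms); a time-averaged mode (mean TAE over
[0, t]) is provided since an observer plausibly integrates over the whole
test. The decay time is the first post-onset time at which |TAE| falls
below threshold and stays below for the remainder of the window (0 if it
never exceeds threshold, ∞ if it never settles).

`predict_tae_variants` computes several suppression variants from one pair
of network simulations, since suppression is a cheap post-hoc transform.

## Psychophysics

Geometry and sign conventions: positive angles are clockwise;
`ref_offset_deg` = reference − adapter, so the adapter is clockwise of the
reference exactly when ref_offset < 0. Trials are grouped by the *sign* of
the reference offset only ("plus"/"minus" conditions), ignoring the ±3°
jitter around the ±20° mean. `response_cw` = the test (adapted side) was
reported more clockwise than the reference, modeled as

    P(CW | x) = λ + (1 − 2λ) / (1 + e^{−s(x − PSE)}),

with x the test-minus-reference offset. A single symmetric λ is used
because one lapse rate per subject implies symmetric asymptotes.

Two-stage fitting: (1) λ is estimated by a free-lapse fit over the two
conditions pooled, with λ bounded at 0.1 to prevent the slope–lapse
trade-off; (2) each condition is refit with λ fixed. Fits are maximum
likelihood on binomially aggregated counts (L-BFGS-B with analytic
gradients), started from a 50%-crossing/probit rough fit plus two
perturbed starts with best-likelihood selection — deterministic for fixed
input. Slopes at or below 0.02/deg (flat curve, PSE unidentifiable, e.g.
50/50 responses everywhere) or at or above 25/deg (perfect separation)
raise a degenerate-fit error with diagnostics.

The TAE is PSE(plus) − PSE(minus), positive = attractive; a per-condition
attractive shift of s appears as a difference of 2s.

**Monte Carlo PSE comparison** is a parametric bootstrap (2000 resamples
by default, minimum 500): responses are resimulated from each fitted
curve at the observed stimulus placements and refit (single start at the
generating parameters — standard for parametric bootstrap refits and an
order of magnitude cheaper than multi-start); the resampled PSE
differences re-centered at the observed difference form the null, and the
two-sided add-one-corrected tail probability is returned. The published
analysis this emulates used a toolbox whose exact settings (core shape,
priors, bootstrap variant) are not public, so this implementation is a
documented stand-in validated by calibration: over 200 null replications
the rejection rate at α = 0.05 lies in [0.03, 0.07] (asserted in the
acceptance suite). Failed refits are dropped with a warning; more than 5%
failures abort with an error.

**Catch trials** (test replaced by a non-oriented pattern) measure
inadvertent adapter visibility: a response is consistent when the adapted
side was reported more clockwise exactly when the adapter was clockwise of
the reference. Visibility = proportion consistent − ½, tested with an
exact two-sided binomial test against chance.

Group-level parametric tests (t-tests, repeated-measures ANOVA) are left
to standard statistics packages and are not part of this library.

## Synthetic observer

The generator reproduces the experiment's trial structure: adapter
orientation uniform on [0°, 180°) each trial; reference offset sign ±1
equiprobable with magnitude uniform on [17°, 23°]; test durations
{50, 100, 200} ms cycled in balanced proportion then shuffled; 10% catch
trials; non-catch test offsets uniform over the constant-stimuli grid
{−12, …, +12 in steps of 4}°. Constant stimuli are used rather than the
adaptive placement procedure of the original sessions — the analysis
chain is agnostic to placement, and constant stimuli make the trial
tables reproducible and the fits well-conditioned.

The observer answers through the same lapse-corrected logistic the
analysis fits, with the PSE displaced by +sign(ref_offset) · shift(duration)
— the attractive displacement under the package's sign convention — so the
fitted PSE difference is 2·shift in expectation. Catch-trial responses are
chance by default, with a visibility knob (P(consistent) = ½ + v) to probe
the power of the visibility statistic. One pseudo-random stream keyed by
the design seed (optionally combined with an observer seed) drives the
session, with a fixed draw order, so tables are byte-stable across runs.

`model_linked_observer` closes the model→behavior loop: the per-condition
shift at each duration is half the model-predicted TAE evaluated at that
time after test onset. What passing end-to-end tests show is that the
*analysis* is unbiased and calibrated for an observer that exactly follows
the assumed logistic process; real observers add non-stationarity,
serial dependence, asymmetric lapses, and duration-dependent slopes, none
of which the generator emulates, so recovery here does not certify
robustness to those.

## Problem sizes and runtime choices

A 256-unit, 700 ms paired simulation takes well under a second, so the
model-side checks run at full size. Statistical checks use sizes chosen to
keep the whole suite comfortable on one CPU: Monte Carlo calibration uses
200 replications × 500 resamples at 600 trials/condition; end-to-end
recovery uses 4000-trial sessions; the replicate-coverage suite uses 50
seeded sessions with 200-draw bootstrap CIs. Oracle comparisons use 32
units and 50 ms protocols.

## Known limitations

- Suppression does not feed back into the recurrence; if the brain's rate
  suppression alters the recurrent drive, the strong-suppression TAE curve
  would differ quantitatively.
- Rate units, no spiking, no noise in the network; the decoder is
  deterministic, so all behavioral variability comes from the observer's
  response stochasticity.
- The Monte Carlo comparison is a calibrated stand-in for the original
  toolbox implementation, not a bit-exact replica.
- The marginal stability of the orientation mode means predictions near
  the end of long windows are sensitive to the printed parameters'
  precision; small parameter changes move the TAE decay time noticeably.
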