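# Methods

This note documents the models, estimators and numerical choices behind
`ampar-kinetics`, and what the synthetic-data tests do and do not establish.

## Units and conventions

Time in ms, current in pA, voltage in mV, conductance in pS, concentration
in mM. Inward current is negative (holding at −70 mV gives negative
transients); analysis operates on magnitudes after baseline subtraction and
restores sign only in reports. Stimulus onset is explicit trace metadata,
never inferred from the samples.

## Gating model and presets

The generative model is the minimal 4-state chain

    R ⇌ B ⇌ O ⇌ D        (resting, bound, open, desensitized)

with rate constants k_on (mM⁻¹ms⁻¹, the only ligand-dependent step), k_off,
k_op, k_cl, k_des, k_res. This is the smallest topology that expresses
distinct deactivation (unbinding after a 1 ms pulse), desensitization
(O→D during sustained agonist) and a tunable non-zero steady-state open
fraction; it is a phenomenological stand-in, not a mechanistic AMPA-receptor
model (real receptors have ≥4 binding steps and multiple conductance
levels).

Preset rates were calibrated (`scripts/calibrate_presets.py`) by fitting the
deterministic 500 ms and 1 ms responses to phenotypic targets: weighted
τ_des 4.7 vs 12.9 ms, steady state 0.7 vs 28.1% of peak, τ_deact 0.7 vs
1.8 ms, and peak open probability 0.50 vs 0.56 for the wild-type-like (`wt`)
and gain-of-function (`gof`) presets respectively. The `gof` preset meets
all four targets; for `wt` the integrator's stability ceiling (below) caps
the closing/unbinding rates, and the calibration settles at τ_deact
≈ 0.92 ms with peak P_open ≈ 0.39 while holding the τ_des and steady-state
targets. All wt/gof orderings are preserved. Rates are frozen as named
constants (`WT_RATES`, `GOF_RATES`).

## Integration and stochastic simulation

Both engines hold the agonist concentration piecewise-constant over each
sample interval. The deterministic oracle propagates p ← p·expm(Q·dt) with
propagators cached per unique concentration and long constant-concentration
stretches advanced by one eigendecomposition step; for constant
concentration this is exact to machine precision (verified against the
two-state closed form). The stochastic engine draws per-channel state paths
from the *same* one-step transition matrices, so its ensemble mean equals
the oracle exactly in expectation and the observed discrepancy is pure
Monte-Carlo error (≈ √(p(1−p)/(N·n_sweeps))).

A stiffness guard requires (max total exit rate)·dt < 0.1; at the patch
grid of dt = 0.01 ms (100 kHz) this means rates below 10 ms⁻¹, which is the
constraint that limits the `wt` deactivation speed above. Solution exchange
is modelled as a first-order filter on the concentration square pulse with
τ = 0.1 ms by default (10–90% exchange ≈ 0.22 ms, typical of piezo-driven
theta-glass application); the value is a package choice, configurable per
stimulus.

## Decay fitting

Multi-exponential fits use separable (variable-projection) least squares:
scipy's trust-region optimiser works on log τ only, with amplitudes and
offset solved linearly at each iterate; τ is bounded to [10⁻³, 10⁴] ms and
initialised from 5 log-spaced anchors in [0.2, 100] ms. The component count
k grows from 1 to at most 3 and k+1 is accepted only if it lowers the
residual sum of squares by >5% — a pragmatic rule, not a formal model
selection; the reported weighted τ is insensitive to overfitting because an
extra component that splits an existing one leaves Σaᵢτᵢ/Σaᵢ nearly
unchanged. On noiseless sums of up to three exponentials with τ ratios ≥ 3
the fit recovers parameters to <0.1%.

## NSFA estimator

The variance-mean curve is built over the decay phase (peak → 5% of peak)
of the mean response, the conventional choice that avoids the under-sampled
rise; the background σ₀² comes from the pre-stimulus baseline. Ten
equal-count bins by mean-current magnitude stabilise the fit. Two variance
estimators: plain across-sweep variance, and the successive-difference
(Heinemann–Conti) form Σ(x_{k+1}−x_k)²/(2(M−1)) that cancels slow
multiplicative amplitude drift. The successive-difference curve matches a
drift-free curve only when the drift has mean ≈ 1: a monotone run-down to
scale s rescales the effective single-channel current by ≈ s̄ in *any*
variance estimator, which no differencing can undo.

The parabola σ² = i·Ī − Ī²/N (+ σ₀²) is linear in its parameters and fit by
weighted linear least squares. Default weights are model-based IRLS:
w ∝ bin_count/(fitted total variance)², the GLS weighting implied by
Var(s²) ≈ 2σ⁴/(M−1). The empirical alternative (inverse within-bin
variance-of-variance) is offered but markedly less efficient — the
variance-of-variance estimate is itself so noisy that it systematically
over-weights downward-fluctuating bins. σ₀² can be fixed to the baseline
estimate or fit as a free intercept; both modes are exact on noiseless
parabola points.

**Precision limits.** N is identified by the curvature of the parabola near
its sampled top, i.e. by how far peak open probability rises above ~0.4,
and variance estimates at neighbouring time points are correlated over the
channel dwell time, so a single patch contributes only a handful of
independent high-P_open observations. Consequently, per-patch recovery at
200 sweeps and N = 64 is tight for the `gof` preset (peak P_open ≈ 0.56:
i and γ within ±10%, N within ±15% in ≥9/10 seeds) but intrinsically looser
for `wt` (peak P_open ≈ 0.39: N scatter ~30%). This mirrors the well-known
behaviour of NSFA at low open probability and is a property of the method,
not of the implementation; the parameter-recovery acceptance test therefore
runs on the high-P_open preset.

## Event detection

Detection runs on a 1 kHz low-pass (2nd-order Butterworth, zero-phase)
copy. An event requires the filtered trace to stay beyond
threshold_sd·SD_noise for at least 0.5 ms, where SD_noise is the robust
(MAD-based) SD of the filtered copy. The width criterion is what makes a
4-SD threshold workable: band-limited Gaussian noise crosses 4 SD at a
~0.2 Hz rate, but those excursions last ≲0.2 ms, while synaptic events
persist for milliseconds — amplitude + duration gating yields ≈0 false
positives per minute with recall limited only by genuinely overlapping or
sub-threshold events. Onsets are refined by walking back from each peak to
the preceding local maximum (which also separates events riding on another
event's decay); a minimum inter-event interval (default 5 ms) keeps the
larger of colliding detections. Supplying a template switches the detection
statistic to a normalised matched-filter correlation with identical
threshold logic.

Averaging excludes any event whose analysis window is reached by a
neighbour's window (previous events bleed in for the post-window length);
excluded counts are reported, and no deconvolution is attempted.

## Synthetic synaptic data

mEPSC recordings are homogeneous-Poisson event trains (default 1 Hz;
hypertonic-sucrose facilitation is represented only as a higher rate) on
Gaussian baseline noise (default 4 pA at 10 kHz), each event a unit-peak
difference-of-exponentials kernel (rise 0.3 ms, decay 1.9 ms by default)
scaled by a zero-truncated Gaussian amplitude (20 ± 6 pA, ~30% CV —
realistic for miniature events). The evoked-pair generator uses an
instantaneous-rise exponential kernel by default so that the superposition
of the second response on the first's decay has the closed form
amp₁·(PPR + e^(−interval/τ)), making the decay-subtraction correction
exactly checkable; the default inter-pulse interval is 50 ms.

What the generators do *not* emulate: amplitude/kinetics correlations,
dendritic filtering and rise-time variability, non-stationary event rates,
series-resistance and space-clamp artefacts, seal instability, line noise.
A green detection or recovery test therefore establishes correctness of the
estimators under the stated statistical model, not performance on arbitrary
real recordings; absolute frequencies and amplitudes are comparable only
within this artifact.

## Pipeline

`RunConfig` (YAML) drives per-preset kinetics, NSFA, I-V (−100…+100 mV in
20 mV steps, skipping 0 mV where driving force vanishes), mEPSC and
evoked-pair stages; per-preset synaptic kernel decays (mini 1.2 vs 2.8 ms,
evoked 6.7 vs 16.9 ms) emulate the transfected-neuron contrast. Every
stochastic stage derives its seed from SHA-256 of (config seed, stage
tags), so runs are deterministic and sub-seeds are independent of stage
order. Group comparisons between the first two presets use the classical
unpaired t test; no multiple-testing correction is applied anywhere
(matching the reporting conventions emulated), and Welch's correction is
available but off by default. The rectification index convention is
RI = |I(+60)|/|I(−60)| with linear interpolation when those voltages are
unsampled; values are internal conventions, not comparable to externally
reported rectification indices defined otherwise.

## Known limitations

- The 4-state scheme has a single conductance level and one binding step;
  auxiliary-subunit (TARP/CNIH) biology is representable only as alternative
  rate presets, which are not shipped.
- No exact Gillespie engine: state changes are resolved on the sample grid
  (exact in distribution at sample times, but sub-sample open durations are
  not represented).
- NSFA channel counts at low open probability carry large per-patch
  uncertainty (see above).
- The text/JSON trace dialect is the only I/O format; vendor formats (ABF,
  NWB) are out of scope.
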