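# Methods

## Stimuli

Each stimulus is 1 s of zero-mean unit-variance Gaussian white noise at
44 kHz. Repeated kinds (RN, RefRN) concatenate one 22,000-sample token
twice, so the two raw halves are bit-identical. All waveforms pass through
the standard IEC 61672 A-weighting curve (four zeros at DC, real poles at
20.6 / 107.7 / 737.9 / 12194 Hz, 0 dB at 1 kHz), discretized by bilinear
transform at 44 kHz, then are decimated to 2 kHz by a polyphase FIR
(Kaiser design, passband flat to 0.95 of the 1 kHz Nyquist, ≥ 60 dB
stopband). The processed stimulus keeps its natural pipeline scale
(RMS ≈ 0.14 for unit-variance raw noise). This matters: normalizing the
2 kHz waveform to unit RMS drives the reservoir so strongly that the
order–chaos transition moves to ρ ≈ 1.7–1.9 and the near-critical regime
of interest disappears; at pipeline scale the transition sits just above
ρ = 1, as it should. Unit-RMS normalization and a global input gain remain
available (`normalize`, `input_gain`) for sensitivity analyses.

A training session holds 20 stimuli, five per kind, in a seeded random
order constrained so the final trial is an N. All RefRN (and RefN) trials
reuse one frozen realization. Test material draws fresh realizations for
N/RN (disjoint seeds from training) and reuses the frozen series for
RefN/RefRN. Everything is a pure function of integer seeds; re-running
with the same seeds reproduces every sample bit for bit.

## Reservoir

N = 500 tanh units; Bernoulli(0.1) sparsity mask; nonzero recurrent and
input weights U[−1, 1]; W rescaled exactly to the desired spectral radius
(largest |eigenvalue|, dense eigendecomposition — exact at this size).
State update:

    x(k+1) = tanh(W x(k) + W_in u(k+1)) + ε,  ε ~ N(0, σ²I),  σ = 10⁻³

An alternative `integrator` rule that adds the increment onto the previous
state is implemented for comparison but is dynamically degenerate: its
linearization I + diag(tanh′)·W is unstable whenever an eigenvalue of W
has positive real part, so the network has no echo state property at any
radius, every trajectory drifts, and (with plasticity) the weights are
driven to a saturated, input-slaved regime with inter-segment r ≈ 1
everywhere. All experiments use the standard update.

σ defaults to 10⁻³ (the internal-noise variance is a free parameter of the
model); the qualitative behavior was checked at σ ∈ {0, 10⁻³, 10⁻²}.
Per-trial initial states are x(0) ~ U(−1, 1)^N, the same convention as the
weights.

## Plasticity

Oja's rule ΔW_ij = α x_i (x_j − x_i W_ij), α = 10⁻⁷, applied after every
state update using the just-computed activations, restricted to the
structural nonzeros (the sparse graph is anatomy, not a value). Dense
(unmasked) updates were evaluated and rejected: they let the accumulated
outer products *increase* the spectral radius (e.g. 1.4 → 1.45 over one
session) and destabilize the network non-selectively. With masked updates
the Hebbian arm's spectral radius contracts slightly (≈ −0.3% per
session, e.g. 1.4 → 1.3962) while the non-Hebbian arm is exactly
unchanged — a small, below-significance drift.

Hebbian and non-Hebbian arms are trained as a matched pair: identical
initial weights, identical session, identical per-trial initial states and
noise realizations; only the plasticity flag differs. One sparse random
draw is shared across the radius grid (each radius is a rescaling), so a
whole sweep trains in a single compiled pass.

## Readout

y(k) = W_out x(k), one-step-ahead target d(k) = u(k+1) (the last state of
a trial has no target and is dropped). W_out is initialized U[−1, 1] —
shared between the arms of a pair — and updated by one gradient step per
trial minibatch at η = 0.01 (steps per minibatch configurable). Random
initialization is a substantive choice: a zero-initialized readout trained
this way converges onto the stimulus-locked subspace of the reservoir, so
its output is highly reproducible even in the chaotic regime
(inter-segment r ≈ 0.7 at ρ = 1.9), which both contradicts the phenomenon
under study (output consistency should collapse in chaos) and would make a
no-optimization variant output identically zero. A random projection
lightly adjusted by the optimizer keeps output-level consistency tracking
reservoir-level consistency at every radius.

## Metrics and statistics

Inter-segment consistency: Pearson r between response points [0, 200) and
[1000, 1200) — the first 100 ms of each 500 ms segment, transients
included (a `window_offset` option exists for sensitivity checks).
Inter-trial consistency: mean pairwise r across runs on the [0, 200)
window. Zero-variance windows yield undefined correlations; they are
excluded from aggregates and counted, never imputed.

RMSE(k) is taken across test runs per time point; NRMSE divides each
condition's series by the grand-mean RMSE over time and the 2×2 conditions
{Hebbian, non-Hebbian} × {RN, RefRN}, so the grand mean of NRMSE is
exactly 1.

The paired surrogate test flips the sign of each pair's difference with
probability ½ (5000 surrogates), uses the mean difference as statistic,
and reports the two-sided rank p with the +1 correction (floor 1/5001)
plus the signed percentile rank. Bonferroni correction multiplies by the
number of radius levels × tested stimulus contrasts. Test runs are drawn
independently for the two arms (pairing is by run index): sharing initial
states or noise across arms makes low-radius responses nearly
deterministic, so 10⁻⁴-sized systematic differences test significant —
a miscalibrated null. Both sharing modes remain available
(`eval_pairing`).

Prediction-error statistics are computed for two contrasts: RefRN vs RN
within each arm (the frozen RefRN realization carries a genuine
stimulus-difficulty offset, identical in both arms), and Hebbian vs
non-Hebbian within each stimulus kind, which isolates the
plasticity-dependent component.

## Problem sizes

The replication tests and the acceptance script run the study at reduced
scale, chosen as the smallest sizes at which the evaluated distributions
are stable: the radius sweep (0.1–2.0, step 0.1) uses 50 frozen test runs
per stimulus kind and five master seeds; the three probe radii (0.9, 1.4,
1.9) use 200 runs; surrogate tests always use 5000 surrogates. The
ensemble API (`run_ensemble`) repeats training over independently drawn
paired reservoirs (shared sparsity pattern, fresh weight values) and tests
the contrast across instances.

## What the synthetic stimuli do and do not capture

The corpus reproduces the statistical structure of the frozen-noise
design: exact within-stimulus repetition, exact across-trial freezing of
referenced realizations, fresh realizations elsewhere, A-weighted spectra.
It does not model cochlear filterbanks, level roving, or any perceptual
decision stage, so passing tests speak to network dynamics, not to
behavioral repetition detection.

## What this implementation reproduces, and what it does not

Reproduced robustly: the echo state property at small radii (inter-trial
r > 0.99 after the transient) and its loss in chaos; the consistency
collapse just above ρ = 1; near-zero inter-segment correlations for N and
RefN; a small, non-significant plasticity-induced spectral-radius drift;
prediction error rising monotonically with radius with no selective
RefRN/RN difference in its plasticity dependence at most radii; and a
positive Hebbian-minus-non-Hebbian RefRN consistency difference whose
argmax over the radius grid falls at the order–chaos knee.

Not reproduced at the stated parameters: a *strong, radius-specific*
selective-consistency effect. In this implementation the plasticity-induced
consistency gain is weak (single-pair differences of order 0.01–0.15 at
the knee), its location tracks each network's own transition point
(≈ 1.2–1.6 depending on the draw), and across independently drawn network
pairs its mean (+0.013 ± 0.054 at ρ = 1.4, output level, 40 instances) is
of the same size for RN as for RefRN — a generic stabilization consistent
with the spectral-radius contraction, not a stimulus-specific memory.
Consequently the fixed-radius significance pattern (p < 0.001 at ρ = 1.4
with 200 runs, null elsewhere) is not reliably attained, and the
corresponding replication tests report that honestly. Probed and excluded
as explanations: stimulus normalization and input gain (0.14–1.0 RMS),
noise level (0–10⁻²), learning rate (10⁻⁷–10⁻⁶), dense vs masked
plasticity, readout initialization, training-trial initial conditions
(random / zero / continuous), and update-rule form.

## Known limitations

Evaluation uses float32 matrix products for speed (float64 available via
`eval_dtype`); trajectories in the chaotic regime are individually
dtype-sensitive but all distributional statistics are unaffected. The
ensemble trainer shares one sparsity pattern across instances within a
call. The CLI's `report` plots require matplotlib (optional extra).
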