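# selcon — selective consistency in plastic echo-state networks

`selcon` simulates and analyzes how weak Hebbian plasticity lets a random
recurrent network develop *selective consistency*: reproducible responses
to a particular white-noise stimulus that re-occurs across trials, without
any supervised learning signal. The setting mimics the auditory
noise repetition-detection (NRD) task, in which listeners rapidly learn to
detect the repetition inside one frozen noise token (RefRN) after a handful
of exposures, while performance for fresh repeated noise (RN) stays at
chance. The package is aimed at computational-neuroscience researchers
studying reservoir dynamics, criticality, and unsupervised perceptual
learning.

## Model

The reservoir is an echo-state network of N = 500 tanh units on a sparse
random graph (density d = 0.1), driven by a 1 s noise waveform (44 kHz
Gaussian white noise, A-weighted, resampled to 2 kHz):

    x(k+1) = tanh(W x(k) + W_in u(k+1)) + ε,   ε ~ N(0, σ²I)

The recurrent weights are rescaled so that the spectral radius ρ(W) — the
control parameter for the order/chaos transition — takes a prescribed
value, and evolve under Oja's rule at every time step:

    ΔW_ij = α x_i (x_j − x_i W_ij),   α = 10⁻⁷

restricted to the structural nonzeros. A linear readout y(k) = W_out x(k)
performs one-step-ahead prediction, trained by one minibatch gradient step
per trial (η = 0.01). Training presents a 20-trial session (5 stimuli per
kind N / RN / RefN / RefRN; the referenced kinds reuse one frozen
realization). Evaluation freezes plasticity and the optimizer and measures:

- **inter-segment consistency** — Pearson r between the first 200 points of
  the two 500 ms response halves (nonzero only if the network responds
  reproducibly to the repeated token);
- **inter-trial consistency** — mean pairwise r across test runs;
- **RMSE / NRMSE** of the one-step-ahead prediction;
- a **sign-flip surrogate test** (5000 surrogates, Bonferroni-corrected)
  for the Hebbian-vs-non-Hebbian paired contrast.

## Worked example

Train matched Hebbian/non-Hebbian pairs at three radii and evaluate 50
frozen test runs per stimulus kind:

```bash
selcon sweep --radii 0.9,1.3,1.9 --n-test-runs 50 --master-seed 1 \
       --out results/demo
```

prints

```
RefRN selectivity (hebb - nonhebb) by radius:
  rho=0.90  diff=+0.0254
  rho=1.30  diff=+0.0318
  rho=1.90  diff=-0.0361
```

i.e. the plasticity-induced gain in RefRN inter-segment consistency is
positive in the ordered and near-critical regimes and vanishes (here:
reverses, within noise) in chaos. The written tables include the surrogate
tests — at these settings none of the contrasts survives Bonferroni
correction (e.g. ρ=1.3 RefRN: observed diff +0.032, p_raw = 0.066,
p_adjusted = 0.40) — and the spectral-radius drift induced by training,
e.g. 1.3 → 1.2965 for the Hebbian arm while the non-Hebbian arm stays at
1.3000: plasticity contracts the spectral radius by ~0.3%, a weak generic
stabilization. `selcon report` renders summary plots, `selcon stats`
prints the test table of a saved sweep, and `selcon make-stimuli` /
`selcon train` expose the stimulus generator and single-pair training.

Python API: `selcon.SweepConfig`, `selcon.run_sweep`,
`selcon.selectivity_curve` mirror the CLI; `selcon.run_ensemble` repeats
the whole pipeline over many independently drawn paired reservoirs and
tests the contrast across instances.

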