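# Methods

## Scope and design

`audenc` implements four nested encoding architectures for auditory
cortical neurons (LN, STP, GC, GC+STP), a staged estimation procedure, and
the comparison framework — significance testing, equivalence analysis with
noise ceilings, and response reliability — exercised end to end on
synthetic model neurons. Everything runs from integer seeds through
counter-based (Philox) random streams; identical arguments always produce
identical outputs.

## Front end

Waveforms are converted to 18-channel spectrograms by a bank of
second-order gammatone filters with log-spaced centers (200 Hz – 20 kHz)
and ERB-scaled bandwidths (b = 1.019·ERB(f_c)), normalized to unit gain at
each center. "Second-order" is read literally as impulse-response order
n = 2; whether the source architecture meant filter order or cascade count
is ambiguous, and this choice is a package decision. Envelopes are
extracted by half-wave rectification and a 4th-order Butterworth low-pass
at 30 Hz, averaged into 10-ms bins, and log-compressed as
level = log10(x/x0 + 1) with x0 fixed at 10⁻³ of the full-scale RMS, so
digital silence maps exactly to 0 and amplitude scaling becomes an
additive shift well above the floor.

## Forward models

* **STRF**: rank-3 factorization (18×3 spectral weights, 3×15 temporal
  filters of 10 ms); the effective filter is their product and the
  convolution is causal.
* **Output nonlinearity**: y = b + a·exp(−exp(−k·(x − s))), increasing for
  k > 0 and bounded in [b, b + a]; a ≥ 0 by construction. The inner
  exponent is clipped at ±500 to keep float64 finite; the clip is inactive
  for all realistic parameters.
* **STP**: one virtual synapse per STRF rank. Availability d starts at 1
  and evolves per 10-ms bin as d ← d − u·ŝ·d + (1 − d)·Δt/τ (depression,
  u > 0) or d ← d − u·ŝ·(2 − d) + (1 − d)·Δt/τ (facilitation, u < 0), with
  d clamped to [0, 2] and the release drive ŝ = max(s, 0). The output is
  d(t)·s(t) applied to the *unclamped* signal, which makes u = 0 an exact
  identity — the nesting relations below are bit-exact, not approximate.
  τ is in seconds; the recovery term uses Δt = one bin, so fits bound
  τ ≥ 10 ms (the forward-Euler update is unstable below the bin size) and
  τ ≤ 1 s.
* **Contrast**: C_f(t) = σ_f/μ_f of the log levels over a 7-bin (70-ms)
  window whose most recent bin lags 20 ms behind t; bins whose window has
  fewer than two samples, or mean below 10⁻⁹, score 0. K(t) = Σ_f C_f(t),
  divided by a stored normalizer. Fitted models normalize K to the
  estimation-range maximum: the parameter map θ_i(t) = θ_i0 +
  (θ_i1 − θ_i0)·K(t) is linear in K, so the normalization convention is
  absorbed exactly by the fitted endpoints while keeping extrapolation on
  held-out stimuli small. An optional clip of K at a calibrated maximum is
  available on `GcParams` but off by default.
* Final rates are rectified at zero.

## Estimation

Parameters minimize the MSE against the repetition-averaged response via
L-BFGS-B with exact reverse-mode gradients (including backpropagation
through the synaptic recursion and the contrast-modulated nonlinearity;
verified against central differences to ~1e-7 relative error). The staged
schedule is: (1) linear STRF alone, coarse stopping; (2) output
nonlinearity (+ STP) with the STRF fixed; (3) all LN (+ STP) parameters
jointly, fine stopping; (4) GC (+ STP) with the LN portion fixed; (5) all
parameters jointly. Stages not applicable to an architecture are skipped,
and no stage may end with a higher loss than it started.

Numerical choices that matter:

* **Initialization.** The STRF starts from a ridge-regression estimate of
  the full 18×15 filter truncated to rank 3 by SVD; nonlinearity
  parameters from response percentiles (b = 10th, a = 90th − 10th,
  s = median drive, k = 1/SD(drive)); STP at u = 0.05, τ = 0.1 s; GC
  endpoints at their base values.
* **Gauge canonicalization.** The factored STRF and the nonlinearity leave
  two exact degeneracies (scale/sign split between W and H; overall filter
  scale against s and k). Joint stages run in rounds of ≤250 iterations
  with a prediction-invariant re-canonicalization between rounds
  (unit-norm, sign-fixed spectral columns; unit-SD drive). Without this the
  optimizer crawls along flat valleys.
* **Robustness.** Stage 2 of STP architectures runs from two starts
  (plasticity engaged and effectively disabled) and both branches are
  carried through the joint stage; a stage that ends with a flat
  (dead-saturated) prediction restarts its nonlinearity from percentiles;
  augmented architectures can be warm-started from a fitted LN model
  (`fit_model(..., init_from=ln)`), which the pipeline uses throughout —
  warm nested starts keep the nested solution reachable and measurably
  reduce local minima.
* **Stopping.** Coarse = relative loss change < 1e-4, fine < 1e-7
  (defaults), ≤1000 iterations per stage. Deep-convergence settings
  (~8000 iterations, 1e-10) are used where near-exact recovery of a
  noise-free in-family simulation is the question; at the default
  tolerances the staged fit is accurate to R ≈ 0.99 rather than 0.9995.
* Bounds: |u| ≤ 1, τ ∈ [0.01, 1] s, a ≥ 0 (and a₁ ≥ 0).

## Scoring and evaluation

* **Noise-adjusted correlation**: raw Pearson r between prediction and
  repetition mean, divided by a ceiling estimated by split-half
  correlation (average over 10 seeded random half-partitions of the
  repetitions) mapped through Spearman–Brown to the reliability of the
  full-repetition mean; the ceiling is its square root and the result is
  clipped to [−1, 1]. The exact finite-sampling correction used by the
  source analysis is not public; this split-half contract is a documented
  substitute. Single repetitions and non-positive split-half estimates
  fall back to the raw correlation with a warning.
* **Permutation test**: the null shifts the prediction circularly by ≥500
  ms (preserving autocorrelation); p = (1 + #{null ≥ observed})/(n + 1).
* **Jackknife t test**: 20 contiguous validation blocks, delete-one
  pseudo-values of the correlation difference, two-sided p with 19 df.
* **Equivalence**: first-order partial correlation between two models'
  validation predictions controlling for the LN prediction. The
  within-model ceiling W_half refits one architecture on two stimulus-
  stratified halves of the estimation set (alternating assignment after a
  seeded shuffle); the correction W⁺ = (B_full/B_half)·W_half uses the
  between-model equivalence on the full set and on opposite halves
  (mean of both pairings). The pipeline applies the correction at the
  population level — medians of the three terms — because per-neuron
  ratios blow up when B_half ≈ 0 at small scale.
* **Reliability**: per repetition j, total power ⟨y_j, y_j⟩ and signal
  power mean_{k≠j} ⟨y_j, y_k⟩; per-stimulus reliability is the mean over
  repetitions of signal/total (zero-power repetitions skipped), and the
  overall value the mean over stimuli. This unbiased form reproduces the
  interpretation "0.5 = half signal, half noise" exactly in expectation.

## Synthetic data

The generator emulates the study conditions, not any particular recording:

* **Stimuli** are built directly in log-spectrogram space: sparse
  spectro-temporal ridges carrying fast (tens of ms) amplitude modulation,
  a steady diffuse texture, a slow multiplicative envelope with occasional
  quiet gaps (smoothed at the cochlear envelope scale), and a slowly
  varying sparse/diffuse mixture. The design goals are that short-window
  contrast fluctuates continuously and varies partly independently of
  overall level — both properties of natural sounds, and both necessary
  for gain control and synaptic adaptation to be distinguishable at all.
  The *smooth* regime draws per-stimulus depth and a mild broadband-floor
  mixing (α ~ U(0, 0.3)) from continuous ranges; the *bimodal* regime
  alternates clean stimuli with variants mixed toward a flat floor of
  equal mean power (a 0 dB SNR equivalent in spectrogram space — the
  original noisy stimuli were defined on waveforms, so this is a stand-in,
  not a claim about them), which produces the labeled low-contrast
  cluster.
* **Neurons**: spectral weights are Gaussian bumps, temporal filters
  gamma-shaped (some biphasic), and the nonlinearity is calibrated on the
  bank's drive distribution (s = median, k ~ U(1, 2)/SD). STP ground
  truths sample τ ~ U(0.1, 0.3) s and calibrate u so the per-bin depletion
  rate u·s̄ ~ U(0.08, 0.3) — a slow-adaptation regime; much faster
  depression equilibrates within a bin and degenerates into a static
  compressive nonlinearity that an LN model absorbs. GC ground truths
  lower gain by 70–98 % and amplitude by 60–95 % of the bank's
  contrast-tail margin (so the interpolated parameters never invert sign
  at the bank's maximum contrast) and raise baseline by 0.5–2 spikes/s,
  with the input offset unchanged. Trial noise is Gaussian (SD expressed
  as a fraction of each neuron's signal RMS) or Poisson; Gaussian noise is
  left unclipped so each repetition's expectation equals the prediction
  exactly.
* **Split**: 90 % of stimuli at 3 estimation repetitions, 10 % at 24
  validation repetitions, mirroring the low-repetition/high-repetition
  design.

What passing tests on this generator do **not** show: real neurons are
non-Gaussian, nonstationary, and not drawn from the model family; real
natural sounds have harmonic and phase structure this generator lacks; and
absolute parameter values (u, τ, gain slopes) are calibrated to the
synthetic drive scale, not to physiology.

## Control experiments and desk-scale sizes

* `model_recovery_experiment` simulates noise-free neurons from known LN /
  STP / GC ground truths and refits all three architectures. Simulation
  sources are selected with quick fits, mirroring the original control's
  use of example cells chosen by their model fits: the LN source is the
  candidate the LN model reproduces best; the STP/GC sources are the
  candidates whose own architecture most exceeds both alternatives. The
  expected pattern is a diagonal-dominant table in which the mismatched
  nonlinear architecture does no better than LN.
* The population experiment defaults to 60 neurons (20 LN/20 STP/20 GC,
  two Gaussian noise levels, 30 stimuli of 3 s); the test suite runs
  9-neuron populations on 10 stimuli of 2 s with noise at 0.4 RMS and
  capped iteration counts — the smallest sizes at which the median
  orderings and ceiling comparisons are stable. Parameter-recovery checks
  compare the mean release fraction in the canonical gauge (u scaled by
  its spectral column norm), because (c·W, u/c, H/c) is an exact symmetry
  of the synaptic model; τ is gauge-free.

## Known limitations

* The double-exponential's printed form in the source literature is
  ambiguous; the increasing convention used here is a documented choice.
* The contrast window (70 ms, 20-ms offset) is fixed, not per-neuron.
* Staged fitting is a local method; despite the warm starts, multi-start
  canonicalized rounds and branch carrying, occasional fits still land in
  local minima — population analyses handle this with the
  auditory-responsive filter (all four models must beat the permutation
  null), exactly as the original analysis did.
* The equivalence ceiling correction assumes the half/full ratio transfers
  across architectures; at very small estimation sets B_half is noisy and
  the correction is only applied to medians.
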