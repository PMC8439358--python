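# Methods

## Problem setting

K visual stimuli flicker at distinct frequencies (default: 12 stimuli,
9.25–14.75 Hz in 0.5 Hz steps). Eight occipital/parietal channels
(O1, O2, Oz, PO7, PO3, POz, PO4, PO8) are sampled at 256 Hz; each trial
is 4 s of flicker preceded by a 1 s gaze shift to the cued target. A
detector receives a `[channels × samples]` window and must output the
attended stimulus index. Decisions are always deterministic: the smallest
index attaining the maximal score wins ties.

## Synthetic recordings

The generator (`ssvepkit.synth`) emulates the statistical structure the
detectors assume, not a biophysical forward model:

* **Steady-state response.** A source waveform
  s(t) = Σ_h a_h sin(2π h f_k t + hφ), with relative harmonic amplitudes
  `harmonic_amplitudes` (default (1, 0.5, 0.25) — a conventional decay,
  not an empirical claim). The per-trial phase offset φ acts on harmonic
  h as hφ, i.e. it is a pure latency shift, so the waveform shape is
  phase-invariant. `phase_mode="random"` (the default) draws φ uniformly
  per trial; `"fixed"` sets φ = 0.
* **Transient stage.** Before the response settles, visual cortex
  produces the N75/P100/N135 complex. It is modeled as three
  raised-cosine lobes (full width 50 ms) centered at 75/100/135 ms with
  signed amplitudes (−0.5, +1, −0.5) relative to the unit fundamental,
  added identically to all channels and zeroed after `duration`
  (default 200 ms). This reproduces the operational fact that matters —
  the first ~200 ms are not steady state — without claiming
  physiological fidelity.
* **Channel mixing.** Every channel sees the source with gain near one
  plus ~10 % random cross-talk; the mixing matrix is drawn once per
  configuration (redrawn until its condition number is below 10) so
  multichannel methods face a non-trivial but well-posed problem.
* **Noise.** Gaussian noise with power spectral density ∝ 1/f^α
  (default α = 1), band-limited to 1–100 Hz, independent across
  channels, scaled so steady-state power / noise power matches `snr_db`.
  `snr_db=None` disables noise. The default 0 dB is a deliberately
  benign regime; the worked example uses −15 dB to separate the
  detectors.

What the generator does **not** emulate: eye-blink/EMG artifacts,
non-stationary drift, inter-subject variability, volume-conduction
geometry, or amplitude differences across stimulus frequencies. Passing
tests on this generator therefore demonstrate correctness of the
algorithms under their own assumptions, not performance on real EEG.

## Preprocessing

Zero-phase band-pass: 4th-order Butterworth (6–80 Hz default) run
forward and backward (`sosfiltfilt`, reflect padding), so passband
components suffer no group delay — essential because window position
encodes stimulus phase. Harmonic references use N_h = 3 harmonics by
default, sampled at t = 1/S … T/S. The sliding-window step of one sample
(3.9 ms at 256 Hz) and the transient trim of 50 samples (195.3 ms) are
the package constants for the phase-effect experiment; on 4 s trials a
1 s window yields 769 positions untrimmed and 719 after trimming.

## Linear detectors

**CCA** is solved by whitening: with row-centered views,
ρ = singular values of C_xx^{-1/2} C_xy C_yy^{-1/2}. A ridge of
1e-9 · trace/dim is added to each covariance; rank-deficient windows
(e.g. noise-free synthetic data, where all channels are scalar multiples
of one source) trigger a warning and a regularized solve rather than a
failure. Zero-variance windows return a degenerate flagged decision
(lowest index) so batch evaluation never aborts.

**LASSO** minimizes ‖y − Xβ‖² + λ‖β‖₁ by cyclic coordinate descent with
exact soft-threshold updates (tolerance 1e-7 on the largest coefficient
change, 10 000 sweeps max, per-sweep objective recorded; the objective is
provably non-increasing). The design stacks, for every stimulus and
harmonic, a unit-normalized sin and cos column; both are needed because
a window's phase is unknown. Two scoring conventions exist for the
per-frequency contribution Σ_h β_{f,h}:

* `lasso_classify` sums signed coefficients (the literal contribution
  rule), with `absolute=True` optional;
* `LassoDetector` — the evaluation-facing wrapper — defaults to
  magnitudes, because for windows that do not start at stimulus onset
  the harmonic energy splits between sin and cos with arbitrary signs
  and a signed sum can cancel on the true frequency (measured: 20/60
  correct signed vs 60/60 absolute on phase-shifted high-SNR windows).

The penalty is a config scalar. When unset, it defaults to 5 % of the
largest per-channel deactivation bound 2‖Xᵀy‖∞ of the window;
`calibrate_lambda` performs the accuracy-maximizing grid search on a
calibration set for an offline, subject-independent choice.

## Robust nonlinear CCA

Each barrel is a single-hidden-layer tanh network with a linear output
node (default 4 hidden nodes — small enough to resist overfitting on
256-sample windows). The forward cost is

    C1 = −bicor(u, v) + ⟨u⟩² + ⟨v⟩² + (⟨u²⟩^½ − 1)² + (⟨v²⟩^½ − 1)²
         + P1 (ΣW(x)² + ΣW(y)²)

with P1 on the hidden-layer weights only (default 0.1; larger P1 drives
the maps linear). Inverse networks reconstruct each standardized view
from its variate under C2/C3 = mean absolute error + P2/P3 (defaults
0.01) on their input weights; the error is the mean over all matrix
entries, so a unit shift costs exactly 1 regardless of dimensionality.

**Biweight midcorrelation.** Deviations from the median are scaled by
9·MAD (MAD without the 1.4826 consistency factor), weighted by
(1 − u²)² for |u| < 1 and zero outside, normalized to unit sum of
squares, and correlated by inner product. The weight indicator uses
|u| < 1, the standard biweight; `strict_paper_indicator=True` reproduces
the one-sided u < 1 variant for comparison. The analytic gradient treats
the median and MAD as locally constant and differentiates the weighted,
normalized deviations exactly:

    ∂δ/∂x_i = (ỹ_i − δ x̃_i)(w_i − 4u_i²(1 − u_i²) I_i) / ‖a‖

which matches central finite differences of the frozen-scale bicor to
below 1e-5 (test-verified).

**Optimization.** L-BFGS-B on analytic gradients (backpropagation
through both barrels), 500 iterations max, tolerance 1e-6, 5 restarts
with 0.1-scale random initializations, best final C1 wins; inverse maps
are fitted afterwards the same way. Because the frozen-scale bicor
gradient is inconsistent with the exact cost wherever the median/MAD
move, line searches can stall from a random start on skewed variates;
each restart therefore first minimizes the Pearson variant of C1 (a
smooth surrogate of the same architecture) and then polishes with the
bicor objective from that warm start. Diagnostics record the bicor C1 at
the random initialization and after polishing; descent holds per restart.
Degenerate variates (zero MAD) contribute zero correlation and zero
gradient during training rather than raising, so transient flat regions
cannot kill a restart.

**Templates and inference.** Per stimulus k, the x-view pools the
window samples of that stimulus's training trials (one observation per
time point, one variable per channel — standardized) and the y-view is
the harmonic reference of f_k repeated per trial. The stored template
v_k is the y-barrel's variate of one reference block. Inference pushes
a window through the x-barrel only and scores δ_k = bicor(û, v_k); the
inverse maps serve reconstruction diagnostics, not decisions. A best
score below 0.3 (configurable) flags the decision low-confidence.

Template matching presumes the response is phase-locked to stimulus
onset — which real SSVEP is, and which the generator provides with
`phase_mode="fixed"`. With per-trial uniform random phase a fixed
template is uninformative by construction, so end-to-end NLCCA
evaluations use phase-locked trials; the random default remains for
studying phase effects via window offset.

## Metrics and statistics

Accuracy is percent correct (the binary confusion form reduces to it
with per-trial bookkeeping). Wolpaw bits are continuous at P = 1 and
zero at chance; below chance the formula is misleading, so evaluation
clips bits to zero there (a warning is issued otherwise). ITR uses
decisions per minute 60/(window + gaze) with a 1 s gaze default — the
convention that reproduces every recorded operating point exactly.
CV = 100·std/mean with the sample (n−1) standard deviation. The one-way
ANOVA reports the Treatments/Error/Total decomposition with additive
sums of squares; Tukey's critical difference is q·√(MSE/n) with q from
the studentized-range distribution at 5 % by default.

## Problem sizes in tests

The test suite exercises the full pipeline at reduced scale chosen as
adequate for each property: 7 synthetic blocks (24 training / 60
held-out trials) for end-to-end detection, 10 seeds of 3-block sessions
for the low-SNR comparison, 2 000 samples for the nonlinear benchmark,
and 2 restarts / 200 iterations for fixture training (enough for C1
below −0.95 on these data). The acceptance script's targets are
closed-form arithmetic and run in well under a second.

## Known limitations

* NLCCA maps each time sample independently; it exploits waveform shape,
  not temporal context beyond the window.
* The signed-sum LASSO rule is phase-fragile (see above); the magnitude
  variant is the practical default.
* The Tukey helper requires balanced groups, which sliding-window tables
  always are.
* `load_external_mat` supports one container dialect
  (`[target, channel, sample, repetition]` plus an optional frequency
  vector) and is intentionally best-effort.
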