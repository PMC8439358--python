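# ssvepkit

Frequency recognition for SSVEP brain–computer interfaces, with three
detectors and the evaluation machinery to compare them.

A steady-state visual evoked potential (SSVEP) is the periodic brain
response elicited when a user fixates a stimulus flickering above ~6 Hz:
occipital/parietal EEG then carries power at the stimulus frequency and
its harmonics. A BCI exploits this by presenting K stimuli at distinct
frequencies and deciding, from a short multichannel EEG window, which one
the user is attending. This package implements and compares three
decision rules:

* **CCA** — per candidate frequency f_k, build the harmonic reference
  Y_k = [sin 2πf_k t; cos 2πf_k t; …; sin 2πN_h f_k t; cos 2πN_h f_k t]
  and score the window X by the leading canonical correlation ρ_k between
  linear combinations of X's channels and of Y_k's rows; decide
  k̂ = argmax_k ρ_k.
* **LASSO** — regress each channel y onto the union of all stimuli's
  harmonic regressors, β̂ = argmin ‖y − Xβ‖² + λ‖β‖₁, and decide by the
  frequency whose coefficients (summed over harmonics, averaged over
  channels) contribute most.
* **Robust nonlinear CCA (NLCCA)** — replace CCA's linear projections
  with single-hidden-layer tanh networks (a "double-barreled" pair
  u = f(x), v = g(y) plus inverse-mapping networks), trained by
  minimizing C1 = −bicor(u, v) + moment constraints + L2 penalty, where
  bicor is the outlier-resistant biweight midcorrelation; reconstruction
  costs C2/C3 use the mean absolute error. Each stimulus stores the
  canonical variate of its reference as a template v_k; a new window is
  scored by δ_k = bicor(û_k, v_k) and decided by argmax.

Throughput is measured by the Wolpaw information transfer rate: with N
targets and accuracy P,

    B = log₂N + P log₂P + (1 − P) log₂[(1 − P)/(N − 1)]   bits/decision,
    ITR = B · 60/(window + gaze)                          bits/min,

where `gaze` is the fixed per-decision second the user spends
reorienting to the cued target. The evaluation layer adds sliding-window
phase-effect analysis (accuracy/ITR at every one-sample window offset,
with and without trimming the ~200 ms transient visual response),
coefficient-of-variation summaries, one-way ANOVA and Tukey HSD
comparisons between detectors.

Everything runs on a synthetic generator that emulates the assumed
signal structure — harmonic steady-state responses, the N75/P100/N135
transient complex, per-trial phase offsets, cross-channel mixing and
1/f background noise — so the full pipeline is testable without any
external recordings. A best-effort loader for a MAT container of real
epochs is included (`load_external_mat`) but nothing depends on it.

## Worked example

Train on three blocks of a noisy synthetic session, hold out one block,
and classify one-second steady-state windows:

```python
import ssvepkit as sk

cfg = sk.GeneratorConfig(snr_db=-15.0, phase_mode="fixed", n_blocks=4, seed=11)
epochs = sk.bandpass_zero_phase(sk.generate_dataset(cfg))      # 6-80 Hz, zero phase
epochs = epochs.with_data(epochs.data[:, :, 50:], onset_offset=50)  # skip transient
train, test = epochs.split_blocks([3])

models = sk.train_stimulus_models(
    train, 256, hyper=sk.NLCCAHyper(restarts=2, max_iter=200, seed=0)
)
detectors = [
    sk.CCADetector(epochs.grid, epochs.sample_rate),
    sk.LassoDetector(epochs.grid, epochs.sample_rate),
    sk.NLCCADetector(models),
]
for det in detectors:
    correct = sum(det.classify(test.data[i][:, :256]).decided == test.labels[i]
                  for i in range(test.n_trials))
    p = correct / test.n_trials
    rate = sk.itr(sk.ITRParams(12, p, 1.0, gaze_seconds=1.0))
    print(f"{det.name:6s} accuracy {100*p:5.1f}%  ITR {rate:6.2f} bits/min")
```

Output:

```
CCA    accuracy  91.7%  ITR  86.49 bits/min
LASSO  accuracy  58.3%  ITR  34.91 bits/min
NLCCA  accuracy 100.0%  ITR 107.55 bits/min
```

At −15 dB the template-based nonlinear detector still identifies all 12
held-out trials (log₂12 ≈ 3.585 bits per decision, 30 decisions/min with
the 1 s window + 1 s gaze shift → 107.55 bits/min); CCA misses one trial
and LASSO, the weakest of the three here, five.

A command-line interface wraps the same pipeline:

```sh
ssvepkit generate --config config.json epochs/
ssvepkit detect   --config config.json --out decisions.csv epochs/
ssvepkit evaluate --config config.json epochs/ report/
```

`evaluate` writes the window-length sweep, the sliding-window table, and
per-response summary/ANOVA/Tukey CSVs plus a `summary.json`.

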