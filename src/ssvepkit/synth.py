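"""Synthetic SSVEP recordings with the structure the detectors assume.

Each trial is built from four ingredients:

* a steady-state response: a sum of harmonics of the stimulus frequency
  with decaying relative amplitudes and a per-trial phase offset
  (implemented as a latency shift, so harmonic ``h`` carries phase
  ``h * phi``);
* a transient visual evoked complex during the first ~200 ms: three
  raised-cosine lobes centred at 75, 100 and 135 ms with signed
  amplitudes (negative, positive, negative) emulating the N75/P100/N135
  waves;
* cross-channel mixing: every channel sees the source with a gain near
  one plus small random cross-talk from the other channels;
* background noise: spectrally shaped Gaussian noise with power density
  proportional to ``1/f**noise_exponent``, band-limited to 1-100 Hz and
  scaled so the steady-state-to-noise power ratio matches ``snr_db``.

All randomness flows from ``GeneratorConfig.seed``; identical configs
produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import DEFAULT_CHANNEL_NAMES, EpochArray, StimulusGrid, ValidationError

__all__ = ["TransientSpec", "GeneratorConfig", "generate_trial", "generate_dataset",
           "mixing_matrix", "steady_state_source"]

#: Latencies (seconds) of the three transient lobes.
_TRANSIENT_CENTERS = (0.075, 0.100, 0.135)
#: Full width (seconds) of each raised-cosine lobe; support ends by 160 ms.
_TRANSIENT_WIDTH = 0.050


@dataclass(frozen=True)
class TransientSpec:
    """Transient VEP stage: N75/P100/N135 raised-cosine lobes."""

    enabled: bool = True
    duration: float = 0.2
    amplitudes: tuple[float, float, float] = (-0.5, 1.0, -0.5)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic recording session.

    Defaults mirror the recording protocol the detectors target: 12
    stimuli (9.25-14.75 Hz), 15 blocks of one trial per stimulus, 4 s
    flicker at 256 Hz over 8 occipital/parietal channels.
    """

    grid: StimulusGrid = field(default_factory=StimulusGrid.default)
    sample_rate: float = 256.0
    trial_duration: float = 4.0
    n_blocks: int = 15
    n_channels: int = 8
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.5, 0.25)
    snr_db: float | None = 0.0
    phase_mode: str = "random"  # "fixed" or "random"
    transient: TransientSpec = field(default_factory=TransientSpec)
    mixing: str = "crosstalk"  # "identity", "crosstalk", or via mixing_matrix()
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = self.trial_duration * self.sample_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValidationError("trial_duration * sample_rate must be integral")
        if not self.harmonic_amplitudes or any(a < 0 for a in self.harmonic_amplitudes):
            raise ValidationError("harmonic_amplitudes must be non-empty, non-negative")
        if self.transient.enabled and self.transient.duration >= self.trial_duration:
            raise ValidationError("transient duration must be shorter than the trial")
        if self.phase_mode not in ("fixed", "random"):
            raise ValidationError(f"unknown phase_mode {self.phase_mode!r}")
        if self.mixing not in ("identity", "crosstalk"):
            raise ValidationError(f"unknown mixing {self.mixing!r}")

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.sample_rate)


def mixing_matrix(cfg: GeneratorConfig) -> np.ndarray:
    """Channel mixing matrix for this configuration (deterministic).

    ``identity`` returns the identity; ``crosstalk`` returns identity plus
    small random off-diagonal leakage, redrawn until the condition number
    is below 10 (virtually always the first draw).
    """
    n = cfg.n_channels
    if cfg.mixing == "identity":
        return np.eye(n)
    rng = np.random.default_rng([cfg.seed, 0x4D49])
    while True:
        m = np.eye(n) + 0.1 * rng.standard_normal((n, n))
        if np.linalg.cond(m) < 10:
            return m


def steady_state_source(cfg: GeneratorConfig, frequency: float, phase: float) -> np.ndarray:
    """Noise-free single-channel steady-state waveform (length n_samples).

    ``phase`` is the fundamental's phase offset; harmonic ``h`` carries
    ``h * phase`` so the offset acts as a pure latency shift.
    """
    t = np.arange(1, cfg.n_samples + 1) / cfg.sample_rate
    s = np.zeros(cfg.n_samples)
    for h, amp in enumerate(cfg.harmonic_amplitudes, start=1):
        s += amp * np.sin(2 * np.pi * h * frequency * t + h * phase)
    return s


def _transient_waveform(cfg: GeneratorConfig) -> np.ndarray:
    """Raised-cosine N75/P100/N135 complex, zero outside its lobes."""
    t = np.arange(1, cfg.n_samples + 1) / cfg.sample_rate
    w = np.zeros(cfg.n_samples)
    half = _TRANSIENT_WIDTH / 2
    for center, amp in zip(_TRANSIENT_CENTERS, cfg.transient.amplitudes):
        inside = np.abs(t - center) < half
        w[inside] += amp * 0.5 * (1 + np.cos(np.pi * (t[inside] - center) / half))
    w[t > cfg.transient.duration] = 0.0
    return w


def _colored_noise(cfg: GeneratorConfig, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-power Gaussian noise with 1/f**exponent spectrum, 1-100 Hz."""
    n = cfg.n_samples
    freqs = np.fft.rfftfreq(n, d=1 / cfg.sample_rate)
    shape = np.zeros_like(freqs)
    band = (freqs >= 1.0) & (freqs <= min(100.0, cfg.sample_rate / 2))
    shape[band] = freqs[band] ** (-cfg.noise_exponent / 2)
    spectrum = shape * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    noise = np.fft.irfft(spectrum, n=n, axis=1)
    power = np.mean(noise**2)
    return noise / np.sqrt(power) if power > 0 else noise


def generate_trial(
    cfg: GeneratorConfig,
    stimulus_index: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One trial ``[channel, sample]`` for a 1-based stimulus index.

    Deterministic given ``rng`` state (or ``cfg.seed`` when ``rng`` is
    omitted).  The steady-state-to-noise power ratio over the whole trial
    matches ``cfg.snr_db``; ``snr_db=None`` disables noise entirely.
    """
    if not 1 <= stimulus_index <= cfg.grid.k:
        raise ValidationError(
            f"stimulus_index {stimulus_index} outside [1, {cfg.grid.k}]"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frequency = cfg.grid.frequency_of(stimulus_index)
    phase = rng.uniform(0, 2 * np.pi) if cfg.phase_mode == "random" else 0.0
    source = steady_state_source(cfg, frequency, phase)
    mix = mixing_matrix(cfg)
    trial = mix @ np.tile(source, (cfg.n_channels, 1))
    signal_power = np.mean(trial**2)
    if cfg.transient.enabled:
        trial = trial + _transient_waveform(cfg)[None, :]
    if cfg.snr_db is not None:
        noise = _colored_noise(cfg, cfg.n_channels, rng)
        noise_power = signal_power / 10 ** (cfg.snr_db / 10)
        trial = trial + np.sqrt(noise_power) * noise
    return trial


def generate_dataset(cfg: GeneratorConfig) -> EpochArray:
    """Full synthetic session: ``n_blocks`` x K trials, shuffled per block.

    Trial order within each block is a seeded permutation of the K
    stimuli, mirroring randomized cue order; ``block_ids`` record the
    block each trial came from.
    """
    rng = np.random.default_rng(cfg.seed)
    trials, labels, blocks = [], [], []
    for block in range(cfg.n_blocks):
        order = rng.permutation(cfg.grid.k) + 1
        for label in order:
            trials.append(generate_trial(cfg, int(label), rng))
            labels.append(int(label))
            blocks.append(block)
    names = (
        DEFAULT_CHANNEL_NAMES
        if cfg.n_channels == len(DEFAULT_CHANNEL_NAMES)
        else tuple(f"ch{i + 1}" for i in range(cfg.n_channels))
    )
    return EpochArray(
        data=np.stack(trials),
        sample_rate=cfg.sample_rate,
        channel_names=names,
        labels=np.asarray(labels),
        grid=cfg.grid,
        block_ids=np.asarray(blocks),
    )
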