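"""Band-pass filtering, window extraction and sinusoidal references.

The preprocessing chain is deliberately light — SSVEP trials are short
enough that artifact-removal pipelines add little — and consists of a
zero-phase IIR band-pass (6-80 Hz by default) plus windowing.  Reference
construction builds, per stimulus frequency f_k, the matrix

    Y_k = [sin(2*pi*f_k*t); cos(2*pi*f_k*t); ...;
           sin(2*pi*Nh*f_k*t); cos(2*pi*Nh*f_k*t)],   t = 1/S ... T/S

used both by CCA (as the second canonical view) and by the LASSO design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import signal

from .epochs import EpochArray, StimulusGrid, ValidationError

__all__ = [
    "ReferenceSet",
    "WindowSpec",
    "bandpass_zero_phase",
    "build_references",
    "extract_windows",
    "window_starts",
]

#: Default number of harmonics in the reference matrices (fundamental + 2).
DEFAULT_N_HARMONICS = 3


@dataclass(frozen=True)
class ReferenceSet:
    """Per-stimulus sinusoidal harmonic reference matrices.

    ``matrices[k]`` has shape ``[2*Nh, T]`` with rows ordered
    sin(h=1), cos(h=1), sin(h=2), ... for stimulus ``grid[k]``.
    """

    grid: StimulusGrid
    n_harmonics: int
    sample_rate: float
    length: int
    matrices: tuple[np.ndarray, ...]

    def __getitem__(self, k: int) -> np.ndarray:
        """Reference matrix for 0-based grid position ``k``."""
        return self.matrices[k]


@dataclass(frozen=True)
class WindowSpec:
    """Window placement inside a trial (all quantities in samples)."""

    length_samples: int
    start_sample: int = 0
    step_samples: int = 1
    trim_samples: int = 0

    def __post_init__(self) -> None:
        if self.length_samples <= 0:
            raise ValidationError("window length must be positive")
        if min(self.start_sample, self.step_samples, self.trim_samples) < 0:
            raise ValidationError("window offsets must be non-negative")
        if self.step_samples == 0:
            raise ValidationError("step_samples must be positive")


def bandpass_zero_phase(
    epochs: EpochArray, low: float = 6.0, high: float = 80.0, order: int = 4
) -> EpochArray:
    """Zero-phase band-pass filter applied per channel.

    A Butterworth band-pass of the given order is run forward and
    backward (``sosfiltfilt``), so the passband suffers no phase
    distortion — essential when window position encodes stimulus phase.
    """
    nyquist = epochs.sample_rate / 2
    if not 0 < low < high < nyquist:
        raise ValidationError(
            f"band edges ({low}, {high}) must satisfy 0 < low < high < {nyquist}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=epochs.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(filtered)


def build_references(
    grid: StimulusGrid,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    length: int = 256,
    sample_rate: float = 256.0,
) -> ReferenceSet:
    """Sin/cos harmonic reference matrices for every stimulus."""
    if n_harmonics < 1:
        raise ValidationError("n_harmonics must be >= 1")
    if length < 1:
        raise ValidationError("length must be >= 1")
    t = np.arange(1, length + 1) / sample_rate
    matrices = []
    for f in grid.frequencies:
        rows = []
        for h in range(1, n_harmonics + 1):
            rows.append(np.sin(2 * np.pi * h * f * t))
            rows.append(np.cos(2 * np.pi * h * f * t))
        matrices.append(np.asarray(rows))
    return ReferenceSet(
        grid=grid,
        n_harmonics=n_harmonics,
        sample_rate=sample_rate,
        length=length,
        matrices=tuple(matrices),
    )


def window_starts(trial_length: int, spec: WindowSpec, mode: str = "sliding") -> np.ndarray:
    """Start positions produced by :func:`extract_windows`.

    ``fixed`` yields the single start ``trim + start_sample``; ``sliding``
    yields every position from ``trim`` to ``trial_length - length``
    inclusive, stepping by ``step_samples``.
    """
    if mode == "fixed":
        start = spec.trim_samples + spec.start_sample
        if start + spec.length_samples > trial_length:
            raise ValidationError(
                f"window [{start}, {start + spec.length_samples}) exceeds "
                f"trial length {trial_length}"
            )
        return np.asarray([start])
    if mode == "sliding":
        last = trial_length - spec.length_samples
        if spec.trim_samples > last:
            raise ValidationError(
                f"no sliding window of {spec.length_samples} samples fits after "
                f"trimming {spec.trim_samples} of {trial_length}"
            )
        return np.arange(spec.trim_samples, last + 1, spec.step_samples)
    raise ValueError(f"unknown mode {mode!r}")


def extract_windows(
    epochs: EpochArray, spec: WindowSpec, mode: str = "fixed"
) -> Iterator[tuple[int, EpochArray]]:
    """Yield ``(start_sample, windowed EpochArray)`` pairs.

    Windows are views into the original data (nothing is copied), so
    sliding extraction over long trials streams cheaply to detectors.
    """
    for start in window_starts(epochs.n_samples, spec, mode):
        window = epochs.data[:, :, start : start + spec.length_samples]
        yield int(start), epochs.with_data(
            window, onset_offset=epochs.onset_offset + int(start)
        )
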