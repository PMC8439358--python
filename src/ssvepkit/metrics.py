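"""Accuracy, bits per trial, information transfer rate, and variability.

The throughput metric for a K-target brain-computer interface is the
Wolpaw information transfer rate: with ``N`` targets and accuracy ``P``
the bits carried per decision are

    B = log2 N + P log2 P + (1 - P) log2[(1 - P) / (N - 1)]

and ITR = B * T bits/min, where T is the number of decisions per minute.
A decision occupies the analysis window plus a fixed gaze-shift overhead
(the second the user spends reorienting to the cued target), so
``T = 60 / (window_seconds + gaze_seconds)`` with a 1 s default overhead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import ValidationError

__all__ = [
    "ConfusionCounts",
    "ITRParams",
    "accuracy",
    "bits_per_trial",
    "itr",
    "coefficient_of_variation",
    "DEFAULT_GAZE_SECONDS",
]

#: Per-decision gaze-shift overhead in seconds.
DEFAULT_GAZE_SECONDS = 1.0


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; multi-class percent-correct uses TP only."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(counts: ConfusionCounts) -> float:
    """Percent of correctly classified events, ``(TP+TN)/total * 100``."""
    if counts.total == 0:
        raise ValidationError("accuracy undefined for zero total count")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def bits_per_trial(n_targets: int, p: float, *, clip_below_chance: bool = False) -> float:
    """Wolpaw bits per decision for ``n_targets`` at accuracy ``p``.

    Continuous at ``p = 1`` (both entropy terms vanish) and zero at
    chance ``p = 1/N``.  Below chance the formula turns back up and
    overstates throughput; a warning is issued unless
    ``clip_below_chance`` floors the result at 0.
    """
    if n_targets < 2:
        raise ValidationError("need at least 2 targets")
    if not 0 < p <= 1:
        raise ValidationError(f"accuracy proportion {p} outside (0, 1]")
    bits = float(np.log2(n_targets))
    if p < 1.0:
        bits += p * np.log2(p) + (1 - p) * np.log2((1 - p) / (n_targets - 1))
    if p < 1.0 / n_targets:
        if clip_below_chance:
            return 0.0
        warnings.warn(
            f"accuracy {p:.3f} below chance 1/{n_targets}; the Wolpaw "
            "formula overstates throughput here",
            RuntimeWarning, stacklevel=2,
        )
    return float(bits)


@dataclass(frozen=True)
class ITRParams:
    """Inputs of one ITR evaluation."""

    n_targets: int
    p: float
    window_seconds: float
    gaze_seconds: float = DEFAULT_GAZE_SECONDS

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValidationError("need at least 2 targets")
        if not 0 < self.p <= 1:
            raise ValidationError(f"accuracy proportion {self.p} outside (0, 1]")
        if self.window_seconds <= 0:
            raise ValidationError("window_seconds must be positive")
        if self.gaze_seconds < 0:
            raise ValidationError("gaze_seconds must be >= 0")


def itr(params: ITRParams, *, clip_below_chance: bool = False) -> float:
    """Information transfer rate in bits per minute.

    ``B * 60 / (window_seconds + gaze_seconds)``.
    """
    bits = bits_per_trial(
        params.n_targets, params.p, clip_below_chance=clip_below_chance
    )
    return bits * 60.0 / (params.window_seconds + params.gaze_seconds)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Relative dispersion ``100 * sample std / mean`` in percent.

    Accepts either a series of observations or a precomputed
    (mean, std) pair via :func:`cv_from_summary`.
    """
    values = np.asarray(values, dtype=float).ravel()
    mean = values.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def cv_from_summary(mean: float, std: float) -> float:
    """Coefficient of variation from an already-computed mean and std."""
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return 100.0 * std / mean
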