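"""Core containers for labeled multichannel SSVEP epochs.

An :class:`EpochArray` holds a stack of equally shaped EEG trials
(``[trial, channel, sample]``, microvolts) together with the sampling
rate, channel names, the stimulus grid, per-trial stimulus labels and
block identifiers.  Stimulus labels are 1-based indices into the
:class:`StimulusGrid`, mirroring the convention of per-stimulus template
banks where template *k* answers for grid frequency *k*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNEL_NAMES",
    "StimulusGrid",
    "EpochArray",
    "ValidationError",
]

#: Occipital/parietal montage conventionally used for SSVEP recordings.
DEFAULT_CHANNEL_NAMES = ("O1", "O2", "Oz", "PO7", "PO3", "POz", "PO4", "PO8")


class ValidationError(ValueError):
    """An epoch container or configuration violates its invariants."""


@dataclass(frozen=True)
class StimulusGrid:
    """Ordered set of flicker frequencies, one per selectable target.

    Frequencies must be strictly increasing and above 6 Hz, the regime in
    which the visual response is steady-state rather than transient.
    """

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) == 0:
            raise ValidationError("stimulus grid must contain at least one frequency")
        if any(f <= 6.0 for f in freqs):
            raise ValidationError("stimulus frequencies must exceed 6 Hz")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValidationError("stimulus frequencies must be strictly increasing")

    @property
    def k(self) -> int:
        """Number of stimuli (K)."""
        return len(self.frequencies)

    def __len__(self) -> int:
        return len(self.frequencies)

    def __getitem__(self, index: int) -> float:
        return self.frequencies[index]

    def frequency_of(self, label: int) -> float:
        """Frequency for a 1-based stimulus label."""
        if not 1 <= label <= self.k:
            raise ValidationError(f"label {label} outside [1, {self.k}]")
        return self.frequencies[label - 1]

    @classmethod
    def default(cls) -> "StimulusGrid":
        """The 12-target grid: 9.25 to 14.75 Hz in 0.5 Hz steps."""
        return cls(tuple(9.25 + 0.5 * i for i in range(12)))


@dataclass(frozen=True)
class EpochArray:
    """Stack of labeled EEG trials with sampling metadata.

    Parameters
    ----------
    data
        Array ``[n_trials, n_channels, n_samples]`` in microvolts.
    sample_rate
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, one per data row.
    labels
        1-based stimulus index per trial (into ``grid``).
    grid
        The stimulus grid the labels refer to.
    block_ids
        Integer block (repetition) identifier per trial.
    onset_offset
        Number of samples already trimmed from stimulus onset; sample 0 of
        each stored trial is ``onset_offset`` samples after flicker onset.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: tuple[str, ...]
    labels: np.ndarray
    grid: StimulusGrid
    block_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    onset_offset: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValidationError(
                f"data must be [trial, channel, sample]; got ndim={data.ndim}"
            )
        object.__setattr__(self, "data", data)
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        names = tuple(str(n) for n in self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(names) != data.shape[1]:
            raise ValidationError(
                f"{len(names)} channel names for {data.shape[1]} channels"
            )
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (data.shape[0],):
            raise ValidationError(
                f"labels shape {labels.shape} does not match {data.shape[0]} trials"
            )
        if labels.size and (labels.min() < 1 or labels.max() > self.grid.k):
            raise ValidationError(f"labels must lie in [1, {self.grid.k}]")
        blocks = self.block_ids
        if blocks is None:
            blocks = np.zeros(data.shape[0], dtype=np.int64)
        blocks = np.asarray(blocks, dtype=np.int64)
        object.__setattr__(self, "block_ids", blocks)
        if blocks.shape != (data.shape[0],):
            raise ValidationError(
                f"block_ids shape {blocks.shape} does not match {data.shape[0]} trials"
            )
        if self.onset_offset < 0:
            raise ValidationError("onset_offset must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sample_rate

    def with_data(self, data: np.ndarray, *, onset_offset: int | None = None) -> "EpochArray":
        """Copy of this container with new trial data (same metadata)."""
        kwargs = {"data": data}
        if onset_offset is not None:
            kwargs["onset_offset"] = onset_offset
        return replace(self, **kwargs)

    def select(self, indices: Sequence[int] | np.ndarray) -> "EpochArray":
        """Subset of trials by position."""
        idx = np.asarray(indices)
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            block_ids=self.block_ids[idx],
        )

    def split_blocks(self, test_blocks: Sequence[int]) -> tuple["EpochArray", "EpochArray"]:
        """Split into (train, test) by block identifier."""
        test = np.isin(self.block_ids, np.asarray(list(test_blocks)))
        return self.select(np.flatnonzero(~test)), self.select(np.flatnonzero(test))

    def equals(self, other: "EpochArray") -> bool:
        """Exact equality of data and metadata (bit-identical samples)."""
        return (
            np.array_equal(self.data, other.data)
            and self.sample_rate == other.sample_rate
            and self.channel_names == other.channel_names
            and np.array_equal(self.labels, other.labels)
            and self.grid.frequencies == other.grid.frequencies
            and np.array_equal(self.block_ids, other.block_ids)
            and self.onset_offset == other.onset_offset
        )
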