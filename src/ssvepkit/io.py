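"""Reading and writing epoch directories, plus best-effort MAT ingestion.

On-disk layout of an epoch directory::

    metadata.json          sample rate, channels, grid, labels, blocks, offset
    trial_0000.tsv ...     one channels-x-samples matrix per trial   (text)
    epochs.h5              all trial matrices as HDF5 datasets       (hdf5)

Text matrices are written at full float64 precision so a write/read
round-trip is bit-identical; HDF5 is lossless by construction.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .epochs import DEFAULT_CHANNEL_NAMES, EpochArray, StimulusGrid, ValidationError

__all__ = ["write_epochs", "read_epochs", "load_external_mat", "EpochIOError"]

_METADATA_NAME = "metadata.json"
_H5_NAME = "epochs.h5"


class EpochIOError(IOError):
    """An epoch directory is missing files or internally inconsistent."""


def _trial_name(i: int) -> str:
    return f"trial_{i:04d}"


def write_epochs(epochs: EpochArray, path: str | Path, *, fmt: str = "text") -> Path:
    """Write an :class:`EpochArray` to a directory.

    Parameters
    ----------
    epochs
        Validated epoch container.
    path
        Target directory (created if absent).
    fmt
        ``"text"`` for per-trial tab-delimited matrices (diff-able),
        ``"hdf5"`` for a single HDF5 container.
    """
    if fmt not in ("text", "hdf5"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": fmt,
        "sample_rate": epochs.sample_rate,
        "channel_names": list(epochs.channel_names),
        "grid_frequencies": list(epochs.grid.frequencies),
        "labels": epochs.labels.tolist(),
        "block_ids": epochs.block_ids.tolist(),
        "onset_offset": int(epochs.onset_offset),
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
    }
    (path / _METADATA_NAME).write_text(json.dumps(meta, indent=1))
    if fmt == "text":
        for i in range(epochs.n_trials):
            np.savetxt(path / f"{_trial_name(i)}.tsv", epochs.data[i],
                       fmt="%.17e", delimiter="\t")
    else:
        import h5py

        with h5py.File(path / _H5_NAME, "w") as h5:
            for i in range(epochs.n_trials):
                h5.create_dataset(_trial_name(i), data=epochs.data[i])
    return path


def read_epochs(path: str | Path) -> EpochArray:
    """Read an epoch directory written by :func:`write_epochs`."""
    path = Path(path)
    meta_path = path / _METADATA_NAME
    if not meta_path.is_file():
        raise EpochIOError(f"missing {_METADATA_NAME} in {path}")
    meta = json.loads(meta_path.read_text())
    n_trials = int(meta["n_trials"])
    shape = (int(meta["n_channels"]), int(meta["n_samples"]))
    fmt = meta.get("format", "text")
    trials = []
    if fmt == "hdf5":
        import h5py

        h5_path = path / _H5_NAME
        if not h5_path.is_file():
            raise EpochIOError(f"missing {_H5_NAME} in {path}")
        with h5py.File(h5_path, "r") as h5:
            for i in range(n_trials):
                name = _trial_name(i)
                if name not in h5:
                    raise EpochIOError(f"missing trial dataset {name!r}")
                trials.append(np.asarray(h5[name]))
    else:
        for i in range(n_trials):
            tsv = path / f"{_trial_name(i)}.tsv"
            if not tsv.is_file():
                raise EpochIOError(f"missing trial matrix {tsv.name}")
            trials.append(np.loadtxt(tsv, delimiter="\t", ndmin=2))
    for i, t in enumerate(trials):
        if t.shape != shape:
            raise EpochIOError(
                f"trial {i} has shape {t.shape}, metadata declares {shape}"
            )
    data = np.stack(trials) if trials else np.empty((0,) + shape)
    try:
        return EpochArray(
            data=data,
            sample_rate=float(meta["sample_rate"]),
            channel_names=tuple(meta["channel_names"]),
            labels=np.asarray(meta["labels"], dtype=np.int64),
            grid=StimulusGrid(tuple(meta["grid_frequencies"])),
            block_ids=np.asarray(meta["block_ids"], dtype=np.int64),
            onset_offset=int(meta["onset_offset"]),
        )
    except ValidationError as exc:
        raise EpochIOError(f"inconsistent metadata in {path}: {exc}") from exc


def load_external_mat(path: str | Path, *, sample_rate: float = 256.0) -> EpochArray:
    """Best-effort ingestion of a MAT container of SSVEP epochs.

    Expected dialect: a 4-D numeric array (any variable name, first one
    found wins) laid out ``[target, channel, sample, trial-repetition]``,
    the convention of the public San Diego SSVEP recordings.  An optional
    1-D variable named ``freqs`` (or ``frequencies``) gives the stimulus
    frequencies; when absent and the target axis has length 12, the
    default 9.25-14.75 Hz grid is assumed.

    This loader is a convenience only; nothing in the package requires it.
    """
    from scipy.io import loadmat

    try:
        contents = loadmat(str(path))
    except Exception as exc:  # unreadable / not a MAT file
        raise EpochIOError(f"cannot read MAT file {path}: {exc}") from exc
    arr = None
    for key, value in contents.items():
        if key.startswith("__"):
            continue
        value = np.asarray(value)
        if value.ndim == 4 and np.issubdtype(value.dtype, np.number):
            arr = value
            break
    if arr is None:
        raise EpochIOError(
            f"unsupported MAT dialect in {path}: no 4-D numeric array found"
        )
    freqs = None
    for key in ("freqs", "frequencies"):
        if key in contents:
            freqs = np.asarray(contents[key], dtype=float).ravel()
            break
    n_targets = arr.shape[0]
    if freqs is not None:
        if freqs.size != n_targets:
            raise EpochIOError(
                f"frequency list length {freqs.size} does not match "
                f"target axis length {n_targets}"
            )
        grid = StimulusGrid(tuple(np.sort(freqs)))
        order = np.argsort(freqs)
    elif n_targets == 12:
        grid = StimulusGrid.default()
        order = np.arange(12)
    else:
        raise EpochIOError(
            f"unsupported MAT dialect: {n_targets} targets and no frequency list"
        )
    n_channels = arr.shape[1]
    names = (
        DEFAULT_CHANNEL_NAMES
        if n_channels == len(DEFAULT_CHANNEL_NAMES)
        else tuple(f"ch{i + 1}" for i in range(n_channels))
    )
    trials, labels, blocks = [], [], []
    for block in range(arr.shape[3]):
        for label, target in enumerate(order, start=1):
            trials.append(arr[target, :, :, block])
            labels.append(label)
            blocks.append(block)
    return EpochArray(
        data=np.stack(trials).astype(np.float64),
        sample_rate=sample_rate,
        channel_names=names,
        labels=np.asarray(labels),
        grid=grid,
        block_ids=np.asarray(blocks),
    )
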