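"""On-disk dataset container and EDF import.

The container is a directory holding one ``subject_NN.npy`` array per
subject (trials x channels x samples) and a ``dataset.json`` sidecar
with the sampling rate, channel names, segment durations and the
rating table.  EDF files can additionally be imported (one file per
subject/trial) through MNE when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import DIMENSIONS, RatingTable, RawRecording

__all__ = ["save_dataset", "load_dataset", "load_edf"]

_SIDECAR = "dataset.json"


def save_dataset(path, recording: RawRecording, ratings: RatingTable) -> None:
    """Write a recording + ratings to a container directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for s in range(recording.n_subjects):
        np.save(path / f"subject_{s:02d}.npy", recording.data[s])
    meta = {
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        "baseline_seconds": recording.baseline_seconds,
        "trial_seconds": recording.trial_seconds,
        "n_subjects": recording.n_subjects,
        "dimensions": list(ratings.dimensions),
        "ratings": ratings.ratings.tolist(),
    }
    with open(path / _SIDECAR, "w") as fh:
        json.dump(meta, fh)


def load_dataset(path) -> tuple[RawRecording, RatingTable]:
    """Read a container directory written by :func:`save_dataset`."""
    path = Path(path)
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise FileNotFoundError(f"no {_SIDECAR} in {path}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = np.stack(
        [
            np.load(path / f"subject_{s:02d}.npy")
            for s in range(meta["n_subjects"])
        ]
    )
    rec = RawRecording(
        data=data,
        fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        baseline_seconds=meta["baseline_seconds"],
        trial_seconds=meta["trial_seconds"],
    )
    ratings = RatingTable(
        ratings=np.asarray(meta["ratings"], dtype=float),
        dimensions=tuple(meta.get("dimensions", DIMENSIONS)),
    )
    return rec, ratings


def load_edf(path, channels=None) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read one EDF file into (channels x samples, fs, channel names).

    Requires MNE (``pip install eegmse[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF files requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    return raw.get_data(), float(raw.info["sfreq"]), tuple(raw.ch_names)
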