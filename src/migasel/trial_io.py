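"""Reading and writing labeled EEG trial archives.

A trial archive is a directory holding one ``manifest.json`` plus one CSV
matrix per trial.  The manifest records the sampling rate, the ordered
channel names and the ordered per-trial class labels; each trial file has a
header row of channel names and one row per sample, values in scientific
notation with 9+ significant digits so a write/read round trip preserves
the signal.  Labels are exactly the strings ``"left"`` and ``"right"``.

An optional read-only adapter accepts a MATLAB container (the form in
which cued motor-imagery competition recordings are typically
distributed): a 3-D trials array plus a label vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = ("C3", "Cz", "C4")
VALID_LABELS = ("left", "right")

_MANIFEST_NAME = "manifest.json"


class ArchiveFormatError(ValueError):
    """The on-disk archive is structurally malformed (e.g. missing manifest)."""


class ArchiveConsistencyError(ValueError):
    """Manifest and trial data disagree (counts, lengths, channels)."""


@dataclass
class Trial:
    """One fixed-length multichannel EEG recording, in microvolts.

    ``samples`` has shape (n_samples, n_channels); column order follows
    ``channel_names``.
    """

    samples: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ValueError("trial samples must be a 2-D (samples x channels) array")
        if self.samples.shape[0] < 1:
            raise ValueError("trial must contain at least one sample")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[1]} data columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.samples[:, idx]


@dataclass
class TrialSet:
    """An ordered collection of same-shape trials with one label each."""

    trials: list[Trial]
    labels: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.trials = list(self.trials)
        self.labels = [str(lbl) for lbl in self.labels]
        if len(self.trials) != len(self.labels):
            raise ValueError(
                f"{len(self.trials)} trials but {len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        for lbl in self.labels:
            if lbl not in VALID_LABELS:
                raise ValueError(f"label must be one of {VALID_LABELS}, got {lbl!r}")
        if self.trials:
            ref = self.trials[0]
            for tr in self.trials[1:]:
                if tr.n_samples != ref.n_samples:
                    raise ValueError("all trials must share the same length")
                if tr.channel_names != ref.channel_names:
                    raise ValueError("all trials must share the same channel set")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_samples(self) -> int:
        if not self.trials:
            raise ValueError("empty trial set has no sample count")
        return self.trials[0].n_samples

    @property
    def channel_names(self) -> tuple[str, ...]:
        if not self.trials:
            return DEFAULT_CHANNELS
        return self.trials[0].channel_names

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


def write_trial_archive(ts: TrialSet, path: str | Path) -> None:
    """Write ``ts`` as a directory archive readable by :func:`read_trial_archive`.

    Values are serialized with ``%.9e`` so numeric content round-trips to
    at least 9 significant digits.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fs": ts.fs,
        "channel_names": list(ts.channel_names),
        "labels": list(ts.labels),
        "trial_files": [f"trial_{i:04d}.csv" for i in range(len(ts))],
    }
    (root / _MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    header = ",".join(ts.channel_names)
    for fname, trial in zip(manifest["trial_files"], ts.trials):
        np.savetxt(
            root / fname, trial.samples, fmt="%.9e", delimiter=",",
            header=header, comments="",
        )


def read_trial_archive(path: str | Path) -> TrialSet:
    """Read a directory archive written by :func:`write_trial_archive`.

    Raises
    ------
    ArchiveFormatError
        If the manifest is missing or unparseable.
    ArchiveConsistencyError
        If trial files are missing, label and trial counts disagree, or
        trial shapes are ragged.
    """
    root = Path(path)
    mpath = root / _MANIFEST_NAME
    if not mpath.is_file():
        raise ArchiveFormatError(f"no {_MANIFEST_NAME} in {root}")
    try:
        manifest = json.loads(mpath.read_text())
        fs = float(manifest["fs"])
        channels = tuple(str(c) for c in manifest["channel_names"])
        labels = [str(x) for x in manifest["labels"]]
        trial_files = list(manifest["trial_files"])
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ArchiveFormatError(f"malformed manifest in {root}: {exc}") from exc
    if len(labels) != len(trial_files):
        raise ArchiveConsistencyError(
            f"manifest lists {len(labels)} labels but {len(trial_files)} trial files"
        )
    trials: list[Trial] = []
    for fname in trial_files:
        fpath = root / fname
        if not fpath.is_file():
            raise ArchiveConsistencyError(f"trial file {fname} listed but absent")
        df = pd.read_csv(fpath)
        if tuple(df.columns) != channels:
            raise ArchiveConsistencyError(
                f"{fname}: header {tuple(df.columns)} != manifest channels {channels}"
            )
        trials.append(Trial(df.to_numpy(dtype=float), channels))
    try:
        return TrialSet(trials, labels, fs)
    except ValueError as exc:
        raise ArchiveConsistencyError(str(exc)) from exc


def read_mat_trialset(
    path: str | Path,
    data_key: str = "x_train",
    label_key: str = "y_train",
    fs: float = 128.0,
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
    left_value: int = 1,
) -> TrialSet:
    """Best-effort adapter for a MATLAB container of cued motor-imagery trials.

    Expects ``data_key`` to hold an array arranged (samples, channels,
    trials) or (trials, samples, channels), and ``label_key`` a numeric
    vector where ``left_value`` marks left-hand trials (all other values
    are read as right).
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    if data_key not in mat or label_key not in mat:
        raise ArchiveFormatError(
            f"expected variables {data_key!r} and {label_key!r} in {path}"
        )
    arr = np.asarray(mat[data_key], dtype=float)
    y = np.asarray(mat[label_key]).ravel()
    if arr.ndim != 3:
        raise ArchiveFormatError("trials array must be 3-D")
    n_ch = len(channel_names)
    if arr.shape[1] == n_ch and arr.shape[2] == len(y):  # (samples, ch, trials)
        arr = np.moveaxis(arr, 2, 0)
    elif arr.shape[0] == len(y) and arr.shape[2] == n_ch:  # (trials, samples, ch)
        pass
    else:
        raise ArchiveFormatError(
            f"cannot orient trials array of shape {arr.shape} "
            f"for {len(y)} labels and {n_ch} channels"
        )
    labels = ["left" if v == left_value else "right" for v in y]
    trials = [Trial(arr[i], tuple(channel_names)) for i in range(arr.shape[0])]
    return TrialSet(trials, labels, fs)
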