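"""Data containers and I/O for multichannel physiological recordings.

A trial is a :class:`Recording`: a channels-by-samples matrix (EEG in
microvolts, GSR in microsiemens) with a sampling rate and two half-open
sample intervals marking the pre-stimulus baseline and the stimulus
period.  Feature tables and subjective-ratings tables are pandas
DataFrames round-tripped through delimited text.

Supported on-disk layouts:

``generic-array``
    One ``.npz`` file per subject holding ``data`` (trials x channels x
    samples) plus metadata (channel names, sampling rate, spans).
``deap-preprocessed``
    The public pickled per-subject format of the DEAP affective database
    (40 trials x 40 channels x 8064 samples at 128 Hz; 32 EEG channels
    followed by peripheral channels, GSR at index 36).  Read-only.
``edf``
    European Data Format, read-only, one recording per file (delegated
    to :mod:`mne`).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "DEAP_EEG_CHANNELS",
    "load_recording",
    "save_recording",
    "read_feature_table",
    "write_feature_table",
    "read_ratings",
    "write_ratings",
    "validate_ratings",
]

#: The 32 EEG channel labels of the DEAP montage (10-20 system), in the
#: channel order of the publicly distributed preprocessed files.
DEAP_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P8", "P4", "PO4", "O2",
)

_DEAP_PERIPHERAL = ("hEOG", "vEOG", "zEMG", "tEMG", "GSR",
                    "Respiration", "Plethysmograph", "Temperature")

RATING_DIMENSIONS = ("arousal", "valence", "dominance", "liking")


@dataclass
class Recording:
    """One trial of multichannel time series.

    Parameters
    ----------
    channels : list of str
        Unique channel labels.  A channel named ``"GSR"``
        (case-insensitive) is treated as the galvanic-skin-response
        channel; all others are EEG.
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    baseline_span, stimulus_span : (int, int)
        0-based half-open sample intervals; must lie within the data and
        must not overlap.
    subject, trial
        Identifiers carried through feature tables.
    """

    channels: list[str]
    data: np.ndarray
    fs: float
    baseline_span: tuple[int, int]
    stimulus_span: tuple[int, int]
    subject: str = "s01"
    trial: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels, n_samples); got {self.data.shape} "
                f"for {len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        for name, (a, b) in (("baseline_span", self.baseline_span),
                             ("stimulus_span", self.stimulus_span)):
            if not (0 <= a <= b <= n):
                raise ValueError(f"{name} {a, b} outside data of length {n}")
        b0, b1 = self.baseline_span
        s0, s1 = self.stimulus_span
        if max(b0, s0) < min(b1, s1):
            raise ValueError("baseline and stimulus spans overlap")

    # -- channel selection -------------------------------------------------

    @property
    def eeg_channels(self) -> list[str]:
        return [c for c in self.channels if c.lower() != "gsr"]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def eeg(self) -> tuple[list[str], np.ndarray]:
        """EEG channel names and their rows of ``data``."""
        idx = [i for i, c in enumerate(self.channels) if c.lower() != "gsr"]
        return [self.channels[i] for i in idx], self.data[idx]

    def gsr(self) -> np.ndarray | None:
        """The GSR channel, or None if the montage has none."""
        for i, c in enumerate(self.channels):
            if c.lower() == "gsr":
                return self.data[i]
        return None


# ---------------------------------------------------------------------------
# recordings

def save_recording(recordings: list[Recording], path) -> None:
    """Write one subject's trials to a generic ``.npz`` container.

    All trials must share the montage, sampling rate, spans, and subject.
    """
    if not recordings:
        raise ValueError("no recordings to save")
    first = recordings[0]
    for r in recordings[1:]:
        if r.channels != first.channels or r.fs != first.fs:
            raise ValueError("trials in one container must share channels and fs")
        if r.data.shape != first.data.shape:
            raise ValueError("trials in one container must share shape")
    np.savez(
        path,
        data=np.stack([r.data for r in recordings]),
        channels=np.array(first.channels),
        fs=float(first.fs),
        baseline_span=np.array(first.baseline_span),
        stimulus_span=np.array(first.stimulus_span),
        subject=str(first.subject),
        trials=np.array([r.trial for r in recordings]),
    )


def load_recording(path, layout: str = "generic-array") -> list[Recording]:
    """Read a per-subject file into a list of trial Recordings."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "generic-array":
        return _load_generic(path)
    if layout == "deap-preprocessed":
        return _load_deap(path)
    if layout == "edf":
        return _load_edf(path)
    raise ValueError(f"unknown layout {layout!r}")


def _load_generic(path: Path) -> list[Recording]:
    with np.load(path, allow_pickle=False) as z:
        data = z["data"]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected trials x channels x samples")
        channels = [str(c) for c in z["channels"]]
        fs = float(z["fs"])
        bspan = tuple(int(v) for v in z["baseline_span"])
        sspan = tuple(int(v) for v in z["stimulus_span"])
        subject = str(z["subject"])
        trials = [int(t) for t in z["trials"]]
    return [
        Recording(channels, data[t], fs, bspan, sspan,
                  subject=subject, trial=trials[t])
        for t in range(data.shape[0])
    ]


def _load_deap(path: Path) -> list[Recording]:
    """Public DEAP preprocessed pickle: dict with 'data' (40, 40, 8064)."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh, encoding="latin1")
    data = np.asarray(payload["data"], dtype=float)
    if data.ndim != 3 or data.shape[1] < 33:
        raise ValueError(f"{path}: not a DEAP preprocessed file "
                         f"(shape {data.shape})")
    # keep the 32 EEG channels plus GSR; other peripherals are unused
    keep = list(range(32))
    channels = list(DEAP_EEG_CHANNELS)
    gsr_idx = 32 + _DEAP_PERIPHERAL.index("GSR")
    if data.shape[1] > gsr_idx:
        keep.append(gsr_idx)
        channels.append("GSR")
    data = data[:, keep, :]
    fs = 128.0
    # documented trial structure: 3 s pre-trial baseline then 60 s stimulus
    bspan = (0, int(3 * fs))
    sspan = (int(3 * fs), data.shape[2])
    subject = path.stem
    return [
        Recording(channels, data[t], fs, bspan, sspan,
                  subject=subject, trial=t)
        for t in range(data.shape[0])
    ]


def _load_edf(path: Path) -> list[Recording]:
    import mne  # optional; EEG-only EDF support

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    n = data.shape[1]
    return [Recording(list(raw.ch_names), data, fs, (0, 0), (0, n),
                      subject=path.stem, trial=0)]


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a trials-by-features table as CSV.

    The index must be (subject, trial); values survive the round trip to
    at least 12 significant digits.
    """
    _check_feature_table(table)
    table.to_csv(path, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=[0, 1])
    df.index.names = ["subject", "trial"]
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dupes}")
    return df


def _check_feature_table(table: pd.DataFrame) -> None:
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dupes}")
    if table.index.nlevels != 2:
        raise ValueError("feature table index must be (subject, trial)")
    if table.index.duplicated().any():
        raise ValueError("one row per (subject, trial) required")


def feature_table(rows: dict, index: list[tuple[str, int]]) -> pd.DataFrame:
    """Assemble a FeatureTable from {(subject, trial): Series} rows."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject", "trial"])
    df = df.reindex(pd.MultiIndex.from_tuples(index, names=["subject", "trial"]))
    _check_feature_table(df)
    return df


# ---------------------------------------------------------------------------
# ratings

def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "trial", *RATING_DIMENSIONS}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    vals = ratings[list(RATING_DIMENSIONS)].to_numpy(dtype=float)
    if np.any((vals < 1) | (vals > 9)):
        raise ValueError("ratings must lie on the 9-point scale [1, 9]")
    return ratings


def write_ratings(ratings: pd.DataFrame, path) -> None:
    validate_ratings(ratings)
    ratings.to_csv(path, index=False, float_format="%.17g")


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for dim in RATING_DIMENSIONS:
        if dim in df.columns:
            df[dim] = df[dim].astype(float)
    return validate_ratings(df)
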