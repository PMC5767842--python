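"""Benchmark spectral feature set (SF): subband powers + asymmetry indices.

The classical EEG feature set against which the amplitude-modulation
families are compared: log subband power per electrode (theta, alpha,
beta, gamma) and inter-hemispheric asymmetry indices (difference of left
and right log powers) for 14 left-right electrode pairs.  With a
32-channel 10-20 montage: 128 power + 56 asymmetry = 184 features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import welch

from .recordings_io import Recording
from .subband_dsp import BandSet, DEFAULT_BANDS

__all__ = [
    "ASYMMETRY_PAIRS",
    "band_powers",
    "spectral_power_features",
    "asymmetry_features",
    "spectral_features",
]

#: The 14 inter-hemispheric (left, right) electrode pairs used for the
#: asymmetry indices.
ASYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"),
    ("FC5", "FC6"), ("FC1", "FC2"), ("T7", "T8"), ("C3", "C4"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("PO3", "PO4"), ("O1", "O2"),
)

_WELCH_SEG_S = 8.0
_WELCH_OVERLAP = 0.5


def band_powers(x, fs: float, bands: BandSet = DEFAULT_BANDS,
                seg_seconds: float = _WELCH_SEG_S,
                overlap: float = _WELCH_OVERLAP) -> np.ndarray:
    """Band power (signal units squared) per band from a Welch PSD."""
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(seg_seconds * fs)), len(x))
    f, psd = welch(x, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=int(round(overlap * nperseg)))
    out = np.empty(len(bands))
    for i, b in enumerate(bands):
        sel = (f >= b.lo) & (f <= b.hi)
        out[i] = np.trapezoid(psd[sel], f[sel])
    return out


def spectral_power_features(recording: Recording,
                            bands: BandSet = DEFAULT_BANDS,
                            span: tuple[int, int] | None = None) -> pd.Series:
    """log10 band power per EEG channel and band over the stimulus span.

    Named ``<band>_<ch>``; 32 channels x 4 bands -> 128 features.
    """
    a, b = span if span is not None else recording.stimulus_span
    names, data = recording.eeg()
    out: dict[str, float] = {}
    for ch, x in zip(names, data):
        p = band_powers(x[a:b], recording.fs, bands)
        for band, v in zip(bands, p):
            out[f"{band.name}_{ch}"] = np.log10(v) if v > 0 else np.nan
    return pd.Series(out, dtype=float)


def asymmetry_features(recording: Recording,
                       bands: BandSet = DEFAULT_BANDS,
                       pairs=ASYMMETRY_PAIRS,
                       span: tuple[int, int] | None = None) -> pd.Series:
    """Inter-hemispheric asymmetry: log10(P_left) - log10(P_right).

    Named ``AI_<band>_<chL>_<chR>``; 14 pairs x 4 bands -> 56 features.
    Scale-free (invariant to common amplitude scaling of both channels)
    and antisymmetric under swapping the pair order.
    """
    a, b = span if span is not None else recording.stimulus_span
    missing = [c for pair in pairs for c in pair if c not in recording.channels]
    if missing:
        raise ValueError(f"montage lacks asymmetry-pair channels: {missing}")
    out: dict[str, float] = {}
    for left, right in pairs:
        pl = band_powers(recording.channel(left)[a:b], recording.fs, bands)
        pr = band_powers(recording.channel(right)[a:b], recording.fs, bands)
        for band, vl, vr in zip(bands, pl, pr):
            out[f"AI_{band.name}_{left}_{right}"] = np.log10(vl) - np.log10(vr)
    return pd.Series(out, dtype=float)


def spectral_features(recording: Recording,
                      bands: BandSet = DEFAULT_BANDS,
                      pairs=ASYMMETRY_PAIRS,
                      span: tuple[int, int] | None = None) -> pd.Series:
    """The full SF benchmark set: powers then asymmetry indices (184 for
    the 32-channel montage)."""
    available = [p for p in pairs
                 if p[0] in recording.channels and p[1] in recording.channels]
    return pd.concat([
        spectral_power_features(recording, bands, span),
        asymmetry_features(recording, bands, tuple(available), span),
    ])
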