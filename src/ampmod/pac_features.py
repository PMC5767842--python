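"""Coupling between peripheral (GSR) and central (EEG) signals.

Three phase/amplitude coupling measures between the galvanic skin
response and the EEG amplitude envelope:

ESC (envelope-to-signal coupling)
    Pearson correlation between the EEG amplitude envelope and the raw
    GSR signal.
CFC (cross-frequency coherence)
    Magnitude-squared coherence between the low-passed (0-1 Hz) GSR and
    the broadband (4-45 Hz) EEG envelope, sampled at 42 integer
    frequencies from 4 to 45 Hz.
ModI (modulation index)
    The phase of the 0.5-1 Hz skin conductance response (SCR) is binned
    into M = 18 equal phase bins; the mean EEG envelope amplitude per
    bin, normalized to a distribution P(m), is compared with the uniform
    distribution via Kullback-Leibler divergence, and ModI =
    D_KL(P, Q) / log(M) in [0, 1].  ModI is 0 exactly when amplitude is
    distributed uniformly over phase (no coupling) and 1 when all
    amplitude mass falls in a single phase bin.

The EEG amplitude envelope here follows the peak-interpolation
convention: a shape-preserving piecewise cubic (PCHIP) through the
local maxima of the rectified signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, coherence, find_peaks, hilbert, sosfiltfilt

from .recordings_io import Recording
from .subband_dsp import hilbert_envelope

__all__ = [
    "ScrSignal",
    "scr_phase",
    "eeg_interp_envelope",
    "esc",
    "cfc",
    "modi",
    "pac_features",
    "SCR_BAND",
    "DEFAULT_MODI_BINS",
    "DEFAULT_CFC_FREQS",
]

#: Skin conductance response band (Hz): the rapid transient component of GSR.
SCR_BAND = (0.5, 1.0)
DEFAULT_MODI_BINS = 18
#: Integer frequencies (Hz) at which CFC is reported: 4..45.
DEFAULT_CFC_FREQS = tuple(range(4, 46))
#: EEG broadband for the PAC envelope (Hz).
EEG_BROADBAND = (4.0, 45.0)
DEFAULT_WELCH_SEG_S = 8.0
DEFAULT_WELCH_OVERLAP = 0.5
MIN_WELCH_SEGMENTS = 8


@dataclass
class ScrSignal:
    """Narrowband skin conductance response with instantaneous phase."""

    series: np.ndarray
    fs: float
    band: tuple[float, float]
    phase: np.ndarray  # radians in (-pi, pi]


def _bandpass(x, fs, lo, hi, order=4):
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _lowpass(x, fs, hi, order=4):
    sos = butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def scr_phase(gsr, fs: float, band: tuple[float, float] = SCR_BAND) -> ScrSignal:
    """Instantaneous phase of the skin conductance response.

    The GSR is zero-phase bandpassed into the SCR band (0.5-1 Hz by
    default) and the four-quadrant phase of its analytic signal is
    taken.
    """
    if fs < 2.0:
        raise ValueError("sampling rate too low for the SCR band")
    gsr = np.asarray(gsr, dtype=float)
    u = _bandpass(gsr, fs, *band)
    phase = np.angle(hilbert(u))
    return ScrSignal(series=u, fs=fs, band=band, phase=phase)


def eeg_interp_envelope(x, fs: float) -> np.ndarray:
    """Amplitude envelope through the local maxima of ``|x|``.

    Shape-preserving piecewise cubic (PCHIP) interpolation between the
    rectified signal's peaks, evaluated at every sample.  If fewer than
    three peaks exist the Hilbert envelope is returned instead, with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    rect = np.abs(x)
    peaks, _ = find_peaks(rect)
    if len(peaks) < 3:
        warnings.warn("fewer than 3 local maxima; falling back to the "
                      "Hilbert envelope")
        return hilbert_envelope(x)
    env = PchipInterpolator(peaks, rect[peaks], extrapolate=True)(
        np.arange(len(x)))
    return np.clip(env, 0.0, None)


def esc(envelope, gsr_raw) -> float:
    """Envelope-to-signal coupling: Pearson r, or NaN if degenerate."""
    a = np.asarray(envelope, dtype=float)
    b = np.asarray(gsr_raw, dtype=float)
    if a.shape != b.shape:
        raise ValueError("envelope and GSR must have equal length")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant input; ESC undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cfc(envelope, gsr_lowpassed, fs: float,
        freqs=DEFAULT_CFC_FREQS,
        seg_seconds: float = DEFAULT_WELCH_SEG_S,
        overlap: float = DEFAULT_WELCH_OVERLAP) -> np.ndarray:
    """Magnitude-squared coherence at the requested frequencies.

    Welch-averaged cross- and auto-spectra (Hann window, ``seg_seconds``
    segments with fractional ``overlap``); requires at least 8 segments
    so the coherence estimate is meaningfully below 1 for independent
    signals.
    """
    a = np.asarray(envelope, dtype=float)
    u = np.asarray(gsr_lowpassed, dtype=float)
    if a.shape != u.shape:
        raise ValueError("inputs must have equal length")
    nperseg = int(round(seg_seconds * fs))
    step = nperseg - int(round(overlap * nperseg))
    n_seg = 1 + max(0, (len(a) - nperseg)) // step if len(a) >= nperseg else 0
    if n_seg < MIN_WELCH_SEGMENTS:
        raise ValueError(
            f"span supports only {n_seg} Welch segments of {seg_seconds} s "
            f"({overlap:.0%} overlap); at least {MIN_WELCH_SEGMENTS} required"
        )
    f, coh = coherence(a, u, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=int(round(overlap * nperseg)))
    out = np.empty(len(freqs))
    for i, fq in enumerate(freqs):
        out[i] = coh[np.argmin(np.abs(f - fq))]
    return out


def modi(phase, envelope, bins: int = DEFAULT_MODI_BINS,
         eps: float = 1e-12) -> float:
    """Modulation index: KL divergence of the phase-conditioned amplitude
    distribution from uniform, normalized by log(bins).

    Phases are binned into ``bins`` equal bins over (-pi, pi]; the mean
    envelope amplitude per bin is normalized to P(m) and compared with
    the uniform Q(m) = 1/bins via D_KL(P, Q) = sum P log(P/Q) (natural
    logs; the base cancels against log(bins)).  Empty bins receive an
    epsilon mass before renormalization so the divergence stays finite.
    """
    ph = np.asarray(phase, dtype=float)
    a = np.asarray(envelope, dtype=float)
    if ph.shape != a.shape:
        raise ValueError("phase and envelope must have equal length")
    if len(ph) == 0:
        raise ValueError("empty input")
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    # (-pi, pi]: right-closed bins
    idx = np.searchsorted(edges, ph, side="left") - 1
    np.clip(idx, 0, bins - 1, out=idx)
    sums = np.bincount(idx, weights=a, minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    mean_amp = np.full(bins, np.nan)
    nz = counts > 0
    if not nz.any():
        raise ValueError("all phase bins empty")
    mean_amp[nz] = sums[nz] / counts[nz]
    mean_amp[~nz] = 0.0
    total = mean_amp.sum()
    if total <= 0:
        warnings.warn("zero total amplitude; ModI undefined")
        return float("nan")
    p = mean_amp / total
    p = np.where(p <= 0, eps, p)
    p = p / p.sum()
    q = 1.0 / bins
    dkl = float(np.sum(p * np.log(p / q)))
    return dkl / np.log(bins)


# ---------------------------------------------------------------------------
# per-recording feature extraction

def pac_features(recording: Recording,
                 cfc_freqs=DEFAULT_CFC_FREQS,
                 modi_bins: int = DEFAULT_MODI_BINS,
                 seg_seconds: float = DEFAULT_WELCH_SEG_S,
                 overlap: float = DEFAULT_WELCH_OVERLAP) -> pd.Series:
    """ESC, CFC and ModI features for every EEG channel of a trial.

    Computed over the stimulus span.  With 32 EEG channels and the
    default 42 CFC frequencies this yields 32 + 1344 + 32 = 1408
    features, named ``esc_<ch>``, ``cfc_<ch>_<f>Hz`` and ``modi_<ch>``.
    """
    gsr = recording.gsr()
    if gsr is None:
        raise ValueError("recording has no GSR channel")
    a, b = recording.stimulus_span
    fs = recording.fs
    scr = scr_phase(gsr, fs)
    gsr_low = _lowpass(gsr, fs, 1.0)
    names, data = recording.eeg()
    out: dict[str, float] = {}
    envs = {}
    for ch, x in zip(names, data):
        broadband = _bandpass(x, fs, *EEG_BROADBAND)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            envs[ch] = eeg_interp_envelope(broadband, fs)
    for ch in names:
        out[f"esc_{ch}"] = esc(envs[ch][a:b], gsr[a:b])
    for ch in names:
        coh = cfc(envs[ch][a:b], gsr_low[a:b], fs, cfc_freqs,
                  seg_seconds, overlap)
        for fq, v in zip(cfc_freqs, coh):
            out[f"cfc_{ch}_{fq:g}Hz"] = v
    for ch in names:
        out[f"modi_{ch}"] = modi(scr.phase[a:b], envs[ch][a:b], modi_bins)
    return pd.Series(out, dtype=float)
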