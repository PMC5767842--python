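"""Amplitude-modulation feature families: AME, AMI, AMC.

All three families are computed from the cross-frequency patterns
``s_k(i, j)`` produced by :func:`ampmod.subband_dsp.modulation_decompose`:

AME (amplitude modulation energy)
    Per electrode and pattern, the fraction of the electrode's
    modulation energy carried by that pattern, plus the dB ratio of
    stimulus-period to baseline-period modulation energy.
AMI (amplitude modulation interaction)
    Per electrode pair and pattern, the normalized mutual information
    between the two pattern series (histogram estimator, 50 bins) — a
    non-linear synchrony measure — plus its stimulus/baseline log-ratio.
AMC (amplitude modulation coherence)
    Per electrode pair and pattern, the Pearson correlation between the
    two pattern series — the linear counterpart of AMI — plus the
    stimulus/baseline log-ratio of its magnitude.

With 32 electrodes and the default four-band set this yields 640 AME,
9920 AMI and 9920 AMC features (20480 in total).

Feature names mirror the pattern/electrode convention used in the
affective-computing literature, e.g. ``gamma_m-theta_Fz`` (AME),
``ratio_gamma_m-gamma_Fz`` (AME baseline ratio) and
``gamma_m-gamma_FC5_CP2`` (pair features).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .subband_dsp import CrossFrequencyPattern

__all__ = [
    "ame",
    "ami",
    "amc",
    "normalized_mutual_information",
    "DEFAULT_HIST_BINS",
    "DEFAULT_GUARD_S",
    "RATIO_FLOOR",
]

DEFAULT_HIST_BINS = 50
#: Seconds trimmed from each end of every pattern series before feature
#: statistics, suppressing zero-phase filter transients.
DEFAULT_GUARD_S = 1.0
#: Floor applied to coupling values before forming stimulus/baseline
#: log-ratios, keeping the logarithm finite.
RATIO_FLOOR = 1e-6


def _trim(x: np.ndarray, fs: float, guard_s: float) -> np.ndarray:
    g = int(round(guard_s * fs))
    if g > 0 and len(x) > 2 * g:
        return x[g:-g]
    if g > 0:
        warnings.warn("series shorter than twice the guard; guard skipped")
    return x


def _by_channel(patterns: list[CrossFrequencyPattern]):
    """Group a flat pattern list into {channel: [patterns in pair order]}."""
    grouped: dict[str, list[CrossFrequencyPattern]] = {}
    for p in patterns:
        grouped.setdefault(p.electrode, []).append(p)
    n = {len(v) for v in grouped.values()}
    if len(n) != 1:
        raise ValueError("inconsistent pattern count across channels")
    return grouped


def _check_aligned(video: dict, baseline: dict) -> None:
    if list(video) != list(baseline):
        raise ValueError("video and baseline patterns cover different channels")
    for ch in video:
        pv = [(p.band_i, p.band_j) for p in video[ch]]
        pb = [(p.band_i, p.band_j) for p in baseline[ch]]
        if pv != pb:
            raise ValueError(f"pattern mismatch on channel {ch}")


# ---------------------------------------------------------------------------
# AME

def ame(patterns_video: list[CrossFrequencyPattern],
        patterns_baseline: list[CrossFrequencyPattern],
        fs: float,
        guard_s: float = DEFAULT_GUARD_S) -> pd.Series:
    """Amplitude-modulation energy features.

    For each electrode k and admissible pattern (i, j), the modulation
    energy is the mean squared amplitude xi_k(i, j) of the pattern
    series over the guard-trimmed span (a mean rather than a sum, so
    stimulus and baseline spans of unequal length are comparable).  Two
    features are emitted per pattern:

    - ``<pattern>_<ch>``: xi_k(i, j) normalized by the electrode's total
      over the admissible patterns, so each electrode's values lie on
      the probability simplex;
    - ``ratio_<pattern>_<ch>``: 10*log10(xi_video / xi_baseline) in dB.

    A zero baseline energy yields a missing ratio with a warning.
    """
    vid, base = _by_channel(patterns_video), _by_channel(patterns_baseline)
    _check_aligned(vid, base)
    ratios: dict[str, float] = {}
    db: dict[str, float] = {}
    for ch, pats in vid.items():
        ev = np.array([np.mean(_trim(p.series, fs, guard_s) ** 2) for p in pats])
        eb = np.array([np.mean(_trim(p.series, fs, guard_s) ** 2)
                       for p in base[ch]])
        total = ev.sum()
        norm = ev / total if total > 0 else np.full_like(ev, np.nan)
        for p, frac in zip(pats, norm):
            ratios[f"{p.name}_{ch}"] = frac
        for p, xi_v, xi_b in zip(pats, ev, eb):
            key = f"ratio_{p.name}_{ch}"
            if xi_b <= 0:
                warnings.warn(f"zero baseline modulation energy for {key}; "
                              "ratio set to missing")
                db[key] = np.nan
            else:
                db[key] = 10.0 * np.log10(xi_v / xi_b)
    return pd.Series({**ratios, **db}, dtype=float)


# ---------------------------------------------------------------------------
# normalized mutual information

def _digitize(x: np.ndarray, bins: int) -> np.ndarray | None:
    """Equal-width binning over the series' own range; None if constant."""
    lo = x.min()
    hi = x.max()
    if not hi > lo:
        return None
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(np.intp)
    np.clip(idx, 0, bins - 1, out=idx)  # ties at the max -> last bin
    return idx


def _entropy(counts: np.ndarray) -> float:
    """Plug-in entropy in nats from a count vector."""
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(a, b, bins: int = DEFAULT_HIST_BINS) -> float:
    """Histogram-based normalized mutual information in [0, 1].

    ``(H(a) + H(b) - H(a, b)) / sqrt(H(a) * H(b))`` with marginal and
    joint entropies estimated from equal-width histograms (``bins`` per
    variable).  Symmetric; exactly 1 for a series against itself; a
    constant series has zero entropy and returns 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    da, dbv = _digitize(a, bins), _digitize(b, bins)
    if da is None or dbv is None:
        warnings.warn("constant series has zero entropy; NMI defined as 0")
        return 0.0
    return _nmi_from_codes(da, dbv, bins)


def _nmi_from_codes(da: np.ndarray, db: np.ndarray, bins: int) -> float:
    ha = _entropy(np.bincount(da, minlength=bins))
    hb = _entropy(np.bincount(db, minlength=bins))
    hab = _entropy(np.bincount(da * bins + db, minlength=bins * bins))
    if ha <= 0 or hb <= 0:
        warnings.warn("zero marginal entropy; NMI defined as 0")
        return 0.0
    return float((ha + hb - hab) / np.sqrt(ha * hb))


# ---------------------------------------------------------------------------
# AMI / AMC

def _pairs(channels: list[str]) -> list[tuple[str, str]]:
    return [(channels[k], channels[l])
            for k in range(len(channels)) for l in range(k + 1, len(channels))]


def _log_ratio(v: float, b: float) -> float:
    if np.isnan(v) or np.isnan(b):
        return np.nan
    return float(np.log10(max(v, RATIO_FLOOR) / max(b, RATIO_FLOOR)))


def ami(patterns_video: list[CrossFrequencyPattern],
        patterns_baseline: list[CrossFrequencyPattern],
        fs: float,
        bins: int = DEFAULT_HIST_BINS,
        guard_s: float = DEFAULT_GUARD_S) -> pd.Series:
    """Amplitude-modulation interaction: pairwise normalized MI.

    For every unordered electrode pair and admissible pattern, the
    normalized mutual information between the two pattern series during
    the stimulus, plus ``ratio_*`` = log10 of the stimulus value over
    the baseline value (both floored at 1e-6).  Degenerate (constant)
    series yield missing values.
    """
    vid, base = _by_channel(patterns_video), _by_channel(patterns_baseline)
    _check_aligned(vid, base)
    channels = list(vid)
    if len(channels) < 2:
        raise ValueError("AMI needs at least two channels")
    pat_names = [p.name for p in vid[channels[0]]]
    n_pat = len(pat_names)

    def codes(grouped):
        # {channel: [digitized series per pattern]}
        return {ch: [_digitize(_trim(p.series, fs, guard_s), bins)
                     for p in pats]
                for ch, pats in grouped.items()}

    cv, cb = codes(vid), codes(base)
    values: dict[str, float] = {}
    ratio: dict[str, float] = {}
    for k, l in _pairs(channels):
        for m in range(n_pat):
            name = f"{pat_names[m]}_{k}_{l}"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = (np.nan if cv[k][m] is None or cv[l][m] is None
                     else _nmi_from_codes(cv[k][m], cv[l][m], bins))
                b = (np.nan if cb[k][m] is None or cb[l][m] is None
                     else _nmi_from_codes(cb[k][m], cb[l][m], bins))
            values[name] = v
            ratio[f"ratio_{name}"] = _log_ratio(v, b)
    return pd.Series({**values, **ratio}, dtype=float)


def amc(patterns_video: list[CrossFrequencyPattern],
        patterns_baseline: list[CrossFrequencyPattern],
        fs: float,
        guard_s: float = DEFAULT_GUARD_S) -> pd.Series:
    """Amplitude-modulation coherence: pairwise Pearson correlation.

    For every unordered electrode pair and admissible pattern, the
    Pearson correlation r between the two pattern series during the
    stimulus, plus ``ratio_*`` = log10(|r_video| / |r_baseline|) (the
    magnitude is used because r may be non-positive; both floored at
    1e-6).  Constant series yield missing values.
    """
    vid, base = _by_channel(patterns_video), _by_channel(patterns_baseline)
    _check_aligned(vid, base)
    channels = list(vid)
    if len(channels) < 2:
        raise ValueError("AMC needs at least two channels")
    pat_names = [p.name for p in vid[channels[0]]]
    n_pat = len(pat_names)

    def corr_stack(grouped, m):
        mat = np.stack([_trim(grouped[ch][m].series, fs, guard_s)
                        for ch in channels])
        sd = mat.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(mat)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        return r

    values: dict[str, float] = {}
    ratio: dict[str, float] = {}
    r_v = [corr_stack(vid, m) for m in range(n_pat)]
    r_b = [corr_stack(base, m) for m in range(n_pat)]
    for ki, k in enumerate(channels):
        for li in range(ki + 1, len(channels)):
            l = channels[li]
            for m in range(n_pat):
                name = f"{pat_names[m]}_{k}_{l}"
                v = float(r_v[m][ki, li])
                b = float(r_b[m][ki, li])
                values[name] = v
                ratio[f"ratio_{name}"] = _log_ratio(abs(v), abs(b))
    return pd.Series({**values, **ratio}, dtype=float)
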