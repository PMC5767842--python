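"""Synthetic recordings with known coupling structure.

Generators emulating the trial structure of an affective music-clip
experiment — a short pre-stimulus baseline followed by a stimulus
period, multichannel band-limited EEG, one slow GSR channel, and
9-point subjective ratings — with every coupling ingredient under
explicit control:

- band-limited EEG carriers (Gaussian noise filtered into a carrier
  band by default; a sinusoid mode for analytic checks) whose amplitude
  is modulated at a controllable rate and depth during the stimulus;
- inter-channel synchrony of the modulators (shared vs independent
  modulator phase);
- a 0.75 Hz GSR oscillation plus slow drift whose phase modulates the
  amplitude of a coupled EEG channel (phase-amplitude coupling of
  controllable depth);
- additive broadband noise;
- ratings whose high/low class tracks an elevated modulation/coupling
  depth, drawn with subject-specific scale offsets so the
  individualized-threshold binarization is exercised.

All generators are pure functions of a :class:`SynthSpec` (the seed is
mandatory), so identical specs reproduce identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recordings_io import Recording

__all__ = ["SynthSpec", "gen_am_channel", "gen_pac_trial",
           "gen_labeled_dataset"]

PAC_GSR_HZ = 0.75  # within the 0.5-1 Hz skin-conductance-response band


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study.

    Depths are in [0, 1]; ``class_effect`` is added to both the AM and
    PAC depths of high-class trials.  Durations follow the emulated
    protocol: 3 s baseline, 60 s stimulus at 128 Hz.
    """

    seed: int
    n_subjects: int = 4
    n_trials: int = 32
    fs: float = 128.0
    baseline_s: float = 3.0
    stimulus_s: float = 60.0
    channels: tuple[str, ...] = ("F3", "F4", "C3", "C4")
    carrier_band: tuple[float, float] = (30.0, 45.0)
    modulator_hz: float = 6.0
    am_depth: float = 0.2
    pair_synchrony: float = 1.0
    pac_depth: float = 0.2
    noise_sd: float = 0.1
    class_effect: float = 0.6
    carrier_mode: str = "noise"  # "noise" | "sine"

    def __post_init__(self):
        for name in ("am_depth", "pair_synchrony", "pac_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_s <= 0 or self.stimulus_s <= 0:
            raise ValueError("durations must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.modulator_hz > self.carrier_band[0]:
            raise ValueError(
                f"modulator at {self.modulator_hz} Hz exceeds the carrier "
                f"band's lower edge {self.carrier_band[0]} Hz; the envelope "
                "could not carry it"
            )

    @property
    def n_baseline(self) -> int:
        return int(round(self.baseline_s * self.fs))

    @property
    def n_stimulus(self) -> int:
        return int(round(self.stimulus_s * self.fs))

    @property
    def n_total(self) -> int:
        return self.n_baseline + self.n_stimulus

    @property
    def baseline_span(self) -> tuple[int, int]:
        return (0, self.n_baseline)

    @property
    def stimulus_span(self) -> tuple[int, int]:
        return (self.n_baseline, self.n_total)


def _carrier(spec: SynthSpec, rng: np.random.Generator,
             n: int) -> np.ndarray:
    """Unit-RMS carrier confined to the carrier band."""
    if spec.carrier_mode == "sine":
        fc = 0.5 * (spec.carrier_band[0] + spec.carrier_band[1])
        t = np.arange(n) / spec.fs
        return np.sqrt(2.0) * np.sin(2 * np.pi * fc * t
                                     + rng.uniform(0, 2 * np.pi))
    if spec.carrier_mode != "noise":
        raise ValueError(f"unknown carrier_mode {spec.carrier_mode!r}")
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, list(spec.carrier_band), btype="bandpass",
                 fs=spec.fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _am_profile(spec: SynthSpec, depth: float, phase: float,
                stimulus_only: bool) -> np.ndarray:
    """Multiplicative amplitude profile 1 + depth*sin(2*pi*f_m*t)."""
    t = np.arange(spec.n_total) / spec.fs
    mod = np.sin(2 * np.pi * spec.modulator_hz * t + phase)
    if stimulus_only:
        gate = np.zeros(spec.n_total)
        a, b = spec.stimulus_span
        gate[a:b] = 1.0
        mod = mod * gate
    return 1.0 + depth * mod


def gen_am_channel(spec: SynthSpec,
                   rng: np.random.Generator | None = None,
                   depth: float | None = None,
                   modulator_phase: float | None = None,
                   stimulus_only: bool = False) -> np.ndarray:
    """One amplitude-modulated EEG channel over baseline + stimulus.

    ``x(t) = (1 + depth * sin(2*pi*f_m*t + phase)) * carrier(t) +
    noise``, with the carrier confined to ``spec.carrier_band``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if depth is None:
        depth = spec.am_depth
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    if modulator_phase is None:
        modulator_phase = rng.uniform(0, 2 * np.pi)
    n = spec.n_total
    carrier = _carrier(spec, rng, n)
    profile = _am_profile(spec, depth, modulator_phase, stimulus_only)
    return profile * carrier + spec.noise_sd * rng.standard_normal(n)


def _gsr(spec: SynthSpec, rng: np.random.Generator,
         phase: float) -> tuple[np.ndarray, np.ndarray]:
    """Slow GSR trace and the instantaneous angle of its oscillation."""
    t = np.arange(spec.n_total) / spec.fs
    theta = 2 * np.pi * PAC_GSR_HZ * t + phase
    drift = np.cumsum(rng.standard_normal(spec.n_total)) / spec.fs
    u = 2.0 + 0.5 * np.sin(theta) + 0.02 * drift
    return u, theta


def gen_pac_trial(spec: SynthSpec,
                  rng: np.random.Generator | None = None,
                  pac_depth: float | None = None,
                  am_depth: float | None = None,
                  subject: str = "s01", trial: int = 0) -> Recording:
    """One trial with GSR-phase -> EEG-amplitude coupling.

    The GSR channel carries a 0.75 Hz oscillation plus drift.  The
    first EEG channel's band amplitude follows
    ``1 + pac_depth * cos(phase_GSR)``; the remaining channels are
    uncoupled.  All EEG channels additionally carry the spec's
    stimulus-period amplitude modulation at ``modulator_hz``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if pac_depth is None:
        pac_depth = spec.pac_depth
    if am_depth is None:
        am_depth = spec.am_depth
    gsr_phase = rng.uniform(0, 2 * np.pi)
    u, theta = _gsr(spec, rng, gsr_phase)
    shared_mod_phase = rng.uniform(0, 2 * np.pi)
    rows = []
    for k, _ch in enumerate(spec.channels):
        own_phase = (shared_mod_phase
                     + (1.0 - spec.pair_synchrony) * rng.uniform(0, 2 * np.pi))
        x = gen_am_channel(spec, rng, depth=am_depth,
                           modulator_phase=own_phase, stimulus_only=True)
        if k == 0 and pac_depth > 0:
            x = x * (1.0 + pac_depth * np.cos(theta)) / (1.0 + pac_depth)
        rows.append(x)
    rows.append(u)
    data = np.stack(rows)
    return Recording(list(spec.channels) + ["GSR"], data, spec.fs,
                     spec.baseline_span, spec.stimulus_span,
                     subject=subject, trial=trial)


def gen_labeled_dataset(spec: SynthSpec
                        ) -> tuple[list[Recording], pd.DataFrame]:
    """A full multi-subject dataset with class-dependent coupling.

    Each subject contributes ``spec.n_trials`` trials, half of them
    high-class: high trials have their AM and PAC depths raised by
    ``spec.class_effect`` (clipped to 1).  Ratings for every dimension
    are drawn above/below the scale midpoint according to the class,
    shifted by a subject-specific offset so a fixed global cut at 5
    would misclassify some subjects but the individualized threshold
    recovers the intended classes.  Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[Recording] = []
    rating_rows = []
    hi_am = min(1.0, spec.am_depth + spec.class_effect)
    hi_pac = min(1.0, spec.pac_depth + spec.class_effect)
    for s in range(spec.n_subjects):
        subject = f"s{s + 1:02d}"
        offset = int(rng.integers(-1, 2))
        n_high = spec.n_trials // 2
        classes = np.array([1] * n_high + [0] * (spec.n_trials - n_high))
        rng.shuffle(classes)
        for t, cls in enumerate(classes):
            rec = gen_pac_trial(
                spec, rng,
                pac_depth=hi_pac if cls else spec.pac_depth,
                am_depth=hi_am if cls else spec.am_depth,
                subject=subject, trial=t,
            )
            recordings.append(rec)
            row = {"subject": subject, "trial": t}
            for dim in ("arousal", "valence", "dominance", "liking"):
                lo, hi = ((6, 8) if cls else (2, 4))
                row[dim] = int(np.clip(rng.integers(lo, hi + 1) + offset,
                                       1, 9))
            rating_rows.append(row)
    ratings = pd.DataFrame(rating_rows)
    return recordings, ratings
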