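"""GSR-phase / EEG-amplitude coupling measures: ESC, CFC, ModI."""

import numpy as np
import pytest
from scipy import stats

from ampmod.pac_features import (cfc, eeg_interp_envelope, esc, modi,
                                 pac_features, scr_phase, DEFAULT_CFC_FREQS)
from ampmod.synthetic_data import SynthSpec, gen_pac_trial

FS = 128.0


def brute_force_modi(phase, envelope, bins=18):
    """Direct implementation: loop over bins, mean amplitude, KL."""
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    means = []
    for m in range(bins):
        if m == 0:
            mask = (phase >= edges[0]) & (phase <= edges[1])
        else:
            mask = (phase > edges[m]) & (phase <= edges[m + 1])
        means.append(envelope[mask].mean() if mask.any() else 0.0)
    p = np.array(means) / np.sum(means)
    p = np.where(p <= 0, 1e-12, p)
    p = p / p.sum()
    dkl = float(np.sum(p * np.log(p * bins)))
    return dkl / np.log(bins)


class TestScrPhase:
    def test_linear_phase_advance_of_pure_tone(self):
        t = np.arange(int(60 * FS)) / FS
        u = np.sin(2 * np.pi * 0.75 * t)
        scr = scr_phase(u, FS)
        interior = slice(int(5 * FS), -int(5 * FS))
        slope = np.polyfit(t[interior], np.unwrap(scr.phase)[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.75, rel=0.01)

    def test_sign_flip_shifts_phase_by_pi(self):
        t = np.arange(int(60 * FS)) / FS
        u = np.sin(2 * np.pi * 0.75 * t)
        p1 = scr_phase(u, FS).phase
        p2 = scr_phase(-u, FS).phase
        interior = slice(int(5 * FS), -int(5 * FS))
        diff = np.angle(np.exp(1j * (p2 - p1)))[interior]
        np.testing.assert_allclose(np.abs(diff), np.pi, atol=1e-6)

    def test_narrowband_phase_distribution_uniform(self, rng):
        x = rng.standard_normal(int(600 * FS))
        scr = scr_phase(x, FS)
        counts, _ = np.histogram(scr.phase, bins=18, range=(-np.pi, np.pi))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            scr_phase(np.zeros(100), fs=1.0)


class TestInterpEnvelope:
    def test_sinusoid_gives_constant_amplitude(self):
        t = np.arange(int(20 * FS)) / FS
        env = eeg_interp_envelope(3.0 * np.sin(2 * np.pi * 10 * t), FS)
        interior = slice(int(FS), -int(FS))
        np.testing.assert_allclose(env[interior], 3.0, rtol=0.03)

    def test_tracks_am_modulator(self):
        t = np.arange(int(20 * FS)) / FS
        modulator = 1 + 0.7 * np.sin(2 * np.pi * 2.0 * t)
        x = modulator * np.sin(2 * np.pi * 30.0 * t)
        env = eeg_interp_envelope(x, FS)
        interior = slice(int(FS), -int(FS))
        r = np.corrcoef(env[interior], modulator[interior])[0, 1]
        assert r > 0.9

    def test_degenerate_input_falls_back(self):
        with pytest.warns(UserWarning, match="falling back"):
            env = eeg_interp_envelope(np.zeros(256), FS)
        np.testing.assert_array_equal(env, 0.0)


class TestEsc:
    def test_affine_transform_gives_unit_correlation(self, rng):
        g = rng.standard_normal(5000)
        assert esc(3.0 * g + 7.0, g) == pytest.approx(1.0)

    def test_independent_signals_near_zero(self, rng):
        assert abs(esc(rng.standard_normal(100_000),
                       rng.standard_normal(100_000))) <= 0.02

    def test_constant_input_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(esc(np.ones(100), np.arange(100.0)))


class TestCfc:
    def test_identical_signals_coherent_at_powered_frequencies(self, rng):
        x = rng.standard_normal(int(120 * FS))
        coh = cfc(x, x.copy(), FS)
        np.testing.assert_allclose(coh, 1.0, atol=1e-6)

    def test_independent_noise_low_mean_coherence(self, rng):
        # >= 32 Welch segments: bias of magnitude-squared coherence for
        # independent signals is about 1/#segments
        n = int((32 * 4 + 4) * FS)
        a, b = rng.standard_normal((2, n))
        coh = cfc(a, b, FS, seg_seconds=8.0, overlap=0.5)
        assert coh.mean() <= 0.15

    def test_values_in_unit_interval_and_count(self, rng):
        a, b = rng.standard_normal((2, int(60 * FS)))
        coh = cfc(a, b, FS)
        assert len(coh) == len(DEFAULT_CFC_FREQS) == 42
        assert np.all((coh >= 0) & (coh <= 1))

    def test_short_span_rejected(self, rng):
        with pytest.raises(ValueError, match="segments"):
            cfc(np.zeros(int(10 * FS)), np.zeros(int(10 * FS)), FS)


class TestModi:
    def test_uniform_coupling_gives_zero(self):
        phase = np.linspace(-np.pi + 1e-9, np.pi, 18_000)
        env = np.ones_like(phase)
        assert modi(phase, env) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_mass_gives_one(self):
        phase = np.linspace(-np.pi + 1e-9, np.pi, 1800)
        env = np.where((phase > 0) & (phase <= np.pi / 9), 1.0, 0.0)
        assert modi(phase, env) == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_on_cosine_modulator(self):
        phase = np.linspace(-np.pi + 1e-9, np.pi, 100_000)
        env = 1.0 + 0.5 * np.cos(phase)
        assert modi(phase, env) == pytest.approx(
            brute_force_modi(phase, env), abs=1e-6)

    def test_amplitude_scale_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        env = 1.0 + 0.4 * np.cos(phase) + 0.05 * rng.standard_normal(5000)
        env = np.abs(env)
        assert modi(phase, 37.5 * env) == pytest.approx(modi(phase, env),
                                                        abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 2000)
        env = np.abs(rng.standard_normal(2000))
        assert 0.0 <= modi(phase, env) <= 1.0


class TestPacOnSyntheticTrials:
    def test_modi_monotone_in_coupling_depth(self):
        """ModI must increase with planted phase-amplitude coupling depth
        (Spearman rho > 0.9 across depths 0..1, over seeded replicates)."""
        depths = np.linspace(0.0, 1.0, 6)
        rhos = []
        for rep in range(10):
            vals = []
            for d in depths:
                spec = SynthSpec(seed=3000 + rep, channels=("C3",),
                                 pac_depth=d, am_depth=0.0, stimulus_s=30.0)
                rec = gen_pac_trial(spec)
                feats = pac_features(rec, seg_seconds=3.0)
                vals.append(feats["modi_C3"])
            rhos.append(stats.spearmanr(depths, vals).statistic)
        assert np.mean(rhos) > 0.9

    def test_zero_depth_modi_null(self):
        """Without coupling, ModI stays near zero (95th percentile of
        seeded replicates below 0.02)."""
        vals = []
        for rep in range(20):
            spec = SynthSpec(seed=4000 + rep, channels=("C3",),
                             pac_depth=0.0, am_depth=0.0)
            rec = gen_pac_trial(spec)
            a, b = rec.stimulus_span
            scr = scr_phase(rec.gsr(), FS)
            env = eeg_interp_envelope(rec.channel("C3"), FS)
            vals.append(modi(scr.phase[a:b], env[a:b]))
        assert np.quantile(vals, 0.95) <= 0.02

    def test_coupled_channel_cfc_at_gsr_rate_exceeds_uncoupled(self):
        spec = SynthSpec(seed=5, channels=("C3", "C4"), pac_depth=1.0,
                         am_depth=0.0)
        rec = gen_pac_trial(spec)  # C3 coupled, C4 not
        a, b = rec.stimulus_span
        from ampmod.pac_features import _bandpass, _lowpass
        gsr_low = _lowpass(rec.gsr(), FS, 1.0)
        coh = {}
        for ch in ("C3", "C4"):
            env = eeg_interp_envelope(_bandpass(rec.channel(ch), FS, 4, 45),
                                      FS)
            coh[ch] = cfc(env[a:b], gsr_low[a:b], FS, freqs=[0.75])[0]
        assert coh["C3"] > coh["C4"]

    def test_full_feature_vector_count(self):
        spec = SynthSpec(seed=6, channels=("C3", "C4"))
        feats = pac_features(gen_pac_trial(spec))
        assert len(feats) == 2 + 2 * 42 + 2  # esc + cfc + modi
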