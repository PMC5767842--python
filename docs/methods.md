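# Methods

## Signal model and feature families

A trial is a multichannel recording at sampling rate `fs` (128 Hz in
the emulated protocol) with a pre-stimulus baseline span (3 s) and a
stimulus span (60 s), both 0-based half-open sample intervals.  EEG is
assumed already cleaned (artifact removal and re-referencing happen
upstream); GSR is a single channel in the same container.

**Cross-frequency patterns.**  Each EEG channel is bandpassed into
θ (4–8), α (8–12), β (12–30) and γ (30–45 Hz) with zero-phase
Butterworth filters (order 6, applied forward–backward with
`sosfiltfilt`; see *Numerical choices*).  The Hilbert amplitude
envelope of each subband — the magnitude of the analytic signal,
√(x² + H{x}²) — is decomposed a second time into the same four bands
("modulation bands", prefixed `m-`).  An envelope cannot carry
modulation frequencies above its carrier band's upper edge
(Bedrosian's theorem), so only modulation bands at or below the
carrier band are admissible: n(n+1)/2 pairs for n ordered bands, ten
for the default set.  Filtering runs over the full recording and the
pattern series are then restricted to the requested span, so span
edges add no filter transients of their own.

**AME.**  The modulation energy ξ of a pattern is the *mean* squared
amplitude over the guard-trimmed span (a mean, not a sum, so the 3-s
baseline and the 60-s stimulus are directly comparable).  Two features
per electrode and pattern: the energy fraction ξ/Σξ with the sum over
the ten admissible patterns only (the per-electrode fractions form a
probability simplex), and the baseline ratio 10·log₁₀(ξ_video /
ξ_baseline) in dB.  A zero baseline energy produces a missing value
with a warning.

**AMI.**  Normalized mutual information between the pattern series of
an electrode pair, (H(a)+H(b)−H(a,b))/√(H(a)H(b)), with plug-in
entropies from 50 equal-width bins spanning each series' own range
(ties at the maximum fall in the last bin; entropies in nats — the
base cancels).  The denominator makes self-coupling exactly 1 and the
estimate lies in [0, 1] by construction.  A constant series has zero
entropy; its couplings are reported missing (the standalone estimator
returns 0 with a warning).  The second variant is
log₁₀(AMI_video / AMI_baseline) with both values floored at 1e−6 so
the logarithm stays finite.

**AMC.**  Pearson correlation between the same pair of pattern
series, in [−1, 1]; the baseline-ratio variant uses |r| (a correlation
may be non-positive) with the same 1e−6 floor.

**PAC (GSR phase → EEG amplitude).**  The skin conductance response
(SCR) is the 0.5–1 Hz band of the GSR; its instantaneous phase is the
four-quadrant angle of the analytic signal.  The EEG amplitude
envelope here follows the peak-interpolation convention: a
shape-preserving piecewise cubic (PCHIP) through the local maxima of
the rectified 4–45 Hz-bandpassed channel (with fewer than three peaks
the Hilbert envelope is used instead, with a warning).  Three
measures:

- *ESC*: Pearson correlation between that envelope and the raw GSR.
- *CFC*: magnitude-squared coherence |P_Au|²/(P_AA·P_uu) between the
  envelope and the 0–1 Hz low-passed GSR, Welch-averaged (Hann window,
  8-s segments, 50% overlap — 1-Hz-aligned bins at fs = 128) and
  sampled at the 42 integer frequencies 4..45 Hz.  At least 8 segments
  are required; below that the coherence estimate is too close to 1
  even for independent signals (its bias is ≈ 1/#segments).
- *ModI*: phases binned into M = 18 equal bins over (−π, π]; the mean
  envelope amplitude per bin, normalized to a distribution P(m), is
  compared with the uniform Q(m) = 1/M through
  D_KL(P, Q) = Σ P(m)·log(P(m)/Q(m)), and ModI = D_KL/log M ∈ [0, 1].
  Empty bins receive ε = 1e−12 mass before renormalization so the
  divergence stays finite.  Natural logarithms throughout (the base
  cancels in the ratio).  ModI is invariant to amplitude scaling and
  is zero exactly when amplitude is uniform over phase.

The three GSR conditionings differ deliberately: ESC uses the raw
GSR, CFC the 0–1 Hz low-passed GSR, and the ModI phase comes from the
0.5–1 Hz SCR band.

**Benchmark SF.**  log₁₀ band power per channel and band from a Welch
PSD over the stimulus span (same Welch settings as CFC), plus
asymmetry indices log₁₀P_left − log₁₀P_right for 14 left–right
10-20 pairs.  The asymmetry formula is the standard scale-free
difference-of-log-powers convention; band powers are integrated PSD
(trapezoid) over the band.

## Selection and classification

Ratings on the 9-point scale are binarized per subject at the cut
minimizing |#high − #low| (high means rating ≥ cut; ties break toward
the scale midpoint 5).  A per-subject stratified 25% of trials forms
the ranking set; selection never sees the remaining 75%.  On the
ranking set, a two-group one-way ANOVA (computed from sums of squares;
for two groups F = t²) keeps features with p < 0.1, and greedy mRMR
ranks the survivors: step 1 takes the feature with maximal
MI(feature; label), later steps maximize MI(f; label) − mean MI(f, s)
over the already-selected s.  MI uses the same 50-bin equal-width
discretization as AMI; ties break lexicographically on the feature
name, so the ranking is deterministic.  In the fair-comparison mode
every feature class is truncated to the number of SF survivors; the
unconstrained mode keeps each class's own survivors capped at
`max_features` (default 50).

Classification is leave-one-sample-out over the evaluation trials,
pooled across subjects: an RBF-kernel SVM with the fixed defaults
C = 1 and γ = 0.01, each fold z-scored with training-fold statistics
only.  Feature standardization is this package's own addition to the
fixed-parameter procedure: without it the fixed
kernel width is meaningless against raw feature scales that span
orders of magnitude.  Scores are balanced accuracy; significance is a
two-sided one-sample t-test of the observed BACC against the
empirical BACC distribution of a fair-coin voter on the same labels
(1000 simulated voters by default).

Fusion: feature-level fusion concatenates the top selected features
of SF, AMF and PAC (family prefixes keep the shared pair-naming
convention unambiguous); decision-level fusion takes the majority
vote of exactly three classifiers (three voters make ties
impossible).

## Synthetic data

The generator emulates the study conditions: 4 subjects × 32 trials
by default, fs = 128 Hz, 3-s baseline + 60-s stimulus, four EEG
channels (F3/F4/C3/C4) plus GSR.  Carriers are unit-RMS Gaussian
noise filtered into the carrier band (30–45 Hz by default) — more
realistic envelope statistics than sinusoids — with a sinusoid mode
for analytic checks.  During the stimulus the carrier amplitude is
modulated at 6 Hz with depth `am_depth`; `pair_synchrony` interpolates
between a shared and independent modulator phase across channels.
GSR is a 0.75 Hz oscillation (inside the SCR band) plus a slow random
drift; the first EEG channel's amplitude additionally follows
1 + pac_depth·cos(φ_GSR).  Additive white noise has standard
deviation `noise_sd` (0.1 of carrier RMS).  High-class trials raise
both depths by `class_effect` (default 0.6, from a 0.2 base); ratings
are drawn above/below the scale midpoint per class with a
subject-specific offset in {−1, 0, +1}, so the individualized
threshold logic is actually exercised.  All four rating dimensions
track the same planted class — the generator makes no attempt to give
arousal and valence distinct physiology.  Everything is a pure
function of the generator parameters and their mandatory seed.

What the generator does *not* emulate: volume conduction and
reference-induced channel correlations, 1/f background spectra,
ocular/muscle artifacts, non-stationary tonic GSR responses, and any
realistic relationship between the four affective dimensions.
Passing tests therefore demonstrate that the estimators and the
pipeline recover planted coupling structure of realistic magnitude —
not that the features separate real affective states.

## Numerical choices

- **Filter order.**  Zero-phase Butterworth, order 6 per pass
  (`sosfiltfilt`, so the effective magnitude response is order 12).
  Order 4 leaves ~6% residual amplitude for a 10 Hz tone in the
  12–30 Hz band — too leaky for band-attribution of modulation energy
  — while order 6 keeps such leakage under 5% with stable
  second-order sections even for the narrow 0.5–1 Hz SCR band.
- **Guard interval.**  1 s (configurable) is trimmed from each end of
  every pattern series before feature statistics, suppressing the
  filter's edge transients; all envelope/correlation comparisons in
  the tests likewise exclude 1 s per edge.
- **Band clipping.**  At sampling rates where a band edge exceeds
  0.45·fs the band is clipped there with a warning (a band entirely
  above the limit is dropped); an explicitly invalid band (lo ≥ hi or
  above Nyquist at filter design time) is an error.
- **Degenerate inputs.**  Constant series yield missing coupling
  values; all-equal ratings cannot be binarized and raise;
  single-class LOSO training folds are skipped with a warning; a
  degenerate random-voter variance falls back to exact comparison.
- **Histogram conventions.**  50 equal-width bins per variable over
  the observed range for all MI estimates, maxima assigned to the last
  bin; 18 right-closed phase bins over (−π, π] for ModI.

## Known limitations

- **LOSO small-sample bias.**  Leave-one-out removes the held-out
  trial from its own class, so with near-balanced labels the training
  majority systematically opposes the held-out class; a signal-free
  classifier that tracks the majority then scores *below* chance.
  Simulating the evaluator on pure noise gives mean null BACC ≈ 0.43
  at 75 evaluation trials, ≈ 0.48 at 150 and ≈ 0.50 at 300; at the
  full study scale (~960 evaluation trials) the effect is negligible.
  The pessimism is conservative (it cannot create spurious positives),
  but null-calibration checks in this package run at ≥ 150 evaluation
  trials where the evaluator is unbiased.
- The histogram NMI is only invariant under monotone transforms when
  the binning resolves the same partition under both scales; strongly
  curved bijections can lower the estimate of a deterministic
  relation to ~0.8.
- The equal-width MI estimator on a 25% ranking split of a small
  study (tens of trials) is noisy; mRMR rankings are deterministic
  but not stable across different splits; repeated partitioning or
  boosting would be needed for stable rankings.
- CFC is reported at 4–45 Hz where a 0–1 Hz GSR has essentially no
  power; values there sit near the coherence noise floor.  The frequency
  grid is configurable for exploratory use.
- The DEAP reader follows the documented public preprocessed pickle
  layout but has only been exercised against synthetic files written
  in that layout.
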