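# ampmod

EEG amplitude-modulation and EEG–GSR coupling features for
affective-state recognition.

Affective brain–computer interfaces try to recognize a listener's
arousal, valence, dominance and liking from physiological signals
recorded while they watch music video clips.  The classical EEG
features for this task are subband spectral powers and
inter-hemispheric asymmetry indices.  `ampmod` implements a richer
family built on **amplitude modulation analysis**: the EEG is
decomposed into the θ (4–8 Hz), α (8–12 Hz), β (12–30 Hz) and γ
(30–45 Hz) subbands with zero-phase filters, the Hilbert amplitude
envelope of each subband is decomposed a second time into the same
bands, and the resulting cross-frequency patterns *s*<sub>k</sub>(*i, j*)
(channel *k*, frequency band *i*, modulation band *j*; only *j* ≤ *i*
is admissible by Bedrosian's theorem, ten patterns per channel) feed
three feature families:

- **AME** — per-electrode modulation energy: the energy fraction
  ξ<sub>k</sub>(*i, j*)/Σξ per pattern, plus the stimulus/baseline dB
  ratio 10·log₁₀(ξ_video/ξ_baseline);
- **AMI** — non-linear inter-electrode interaction: normalized mutual
  information (H(*s*ₖ)+H(*s*ₗ)−H(*s*ₖ,*s*ₗ))/√(H(*s*ₖ)H(*s*ₗ)) between
  pattern series of every electrode pair (50-bin histogram entropies);
- **AMC** — linear inter-electrode coherence: Pearson correlation
  between the same pattern series.

It also implements three phase–amplitude coupling measures between the
galvanic skin response (peripheral nervous system) and the EEG
envelope (central nervous system): **ESC** (envelope/GSR correlation),
**CFC** (magnitude-squared coherence between the 0–1 Hz GSR and the
4–45 Hz EEG envelope at 42 integer frequencies) and **ModI** (the
Kullback–Leibler modulation index of the 18-bin phase-conditioned
amplitude distribution, normalized by log 18).  With a 32-electrode
montage this yields 184 benchmark SF, 20480 AMF and 1408 PAC features.

Downstream, 9-point subjective ratings are binarized per subject with
an individualized balanced threshold, features are selected on a 25%
per-subject hold-out (ANOVA pre-screen at p < 0.1, then mRMR forward
selection), and an RBF-kernel SVM (C = 1, γ = 0.01) is evaluated
leave-one-sample-out, scored by balanced accuracy
BACC = (SENS + SPEC)/2 with a t-test against a random voter.  Feature-
and decision-level fusion of the SF/AMF/PAC sets is included.

A synthetic-signal generator with controllable modulation depth,
inter-channel synchrony, GSR-phase coupling and class effect makes the
whole pipeline testable without any recorded data; a reader for the
public DEAP preprocessed per-subject format is included for use with
the real dataset.

## Worked example

```sh
ampmod simulate --out demo/data --seed 3 --subjects 2 --trials 16
ampmod evaluate --data demo/data --out demo/results --seed 3
```

which prints (per affective dimension and feature class):

```
arousal    SF               BACC = 1.000
arousal    AMF              BACC = 1.000
arousal    PAC              BACC = 1.000
arousal    feature_fusion   BACC = 1.000
arousal    decision_fusion  BACC = 1.000
...
```

The simulated high-class trials carry deeper amplitude modulation and
GSR–EEG coupling than the low-class trials (a large planted effect, so
a balanced accuracy of 1.000 on every feature class is the expected
outcome here; `--class-effect 0` produces chance-level results
instead).  `demo/results/` holds the five per-set feature tables
(`features_sf.csv`, `features_ame.csv`, ...), `evaluation.json` with
counts, sensitivity, specificity, balanced accuracy and the p-value
against a random voter for every dimension and fusion mode, and a
`run.log` recording every configuration value.

The same steps are available as library calls
(`ampmod.gen_labeled_dataset`, `ampmod.extract_feature_tables`,
`ampmod.run_affective_analysis`), and every estimator is exposed on
its own (`ampmod.normalized_mutual_information`, `ampmod.modi`,
`ampmod.cfc`, `ampmod.mrmr_select`, `ampmod.loso_evaluate`, ...).

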