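# qeeg

Quantitative resting-state EEG analysis for dementia research: spectral
features, alpha-band Phase Lag Index connectivity, minimum-spanning-tree
network topology, and out-of-bag random-forest classification — plus a
synthetic EEG cohort generator with known ground truth so the whole
pipeline is testable without clinical recordings.

## The problem

Dementia with Lewy bodies (DLB) is hard to separate from Alzheimer's
disease (AD) clinically, yet the resting EEG differs characteristically:
DLB shows a slowed dominant rhythm, more delta/theta power, weaker
alpha-band functional connectivity and a less hub-like network backbone.
This package implements the standard quantitative pipeline used to turn a
21-channel 10-20 recording into the 25 features such studies feed to a
classifier:

- **Spectral** — relative power per band (delta 0.5–4, theta 4–8,
  alpha-1 8–10, alpha-2 10–13, beta 13–30, gamma 30–48 Hz) from Welch
  spectra; peak frequency (4–13 Hz argmax); its SD across 16 two-second
  sub-epochs; the slowing index θ/(θ+α₁+α₂).
- **Connectivity** — Phase Lag Index, PLI = |⟨sign sin(φᵢ−φⱼ)⟩|, in the
  8–13 Hz alpha band for all channel pairs; 0 means no consistent phase
  lead/lag, 1 perfect asymmetric locking; zero-lag (volume-conducted)
  coupling contributes nothing.
- **Network** — the spanning tree retaining the strongest PLI links, with
  highest degree, leaf fraction, diameter and tree hierarchy
  L/(2·M·BC_max), all normalized by M = N−1.
- **Classification** — a random forest whose trees grow on size-⌈2n/3⌉
  bootstrap samples drawn with replacement; out-of-bag majority votes
  give accuracy/sensitivity/specificity without a held-out set, and
  permutation VIMP scores rank the features.

Recordings are read from EDF (or generated synthetically and written to
EDF); preprocessing applies Hjorth source-derivation referencing and
zero-phase band-pass filters. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from qeeg.synthetic import archetype_cohort, generate_cohort
from qeeg.pipeline import subject_features

cohort = archetype_cohort("dlb", n_subjects=1, seed=7)
recording, truth = generate_cohort(cohort)[0]

fv, spectral, conn, tree = subject_features(recording, group_label="dlb")
print(f"dominant frequency: {spectral.global_peak_freq:.1f} Hz "
      f"(ground truth {truth.dominant_freq:.1f} Hz)")
print(f"theta/alpha ratio:  {spectral.theta_alpha_ratio:.2f}")
print(f"mean alpha PLI:     {conn.upper_triangle().mean():.3f}")
print(f"tree highest degree: {tree.metrics['degree_max_norm']:.2f}")
```

prints

```
dominant frequency: 6.0 Hz (ground truth 5.9 Hz)
theta/alpha ratio:  0.78
mean alpha PLI:     0.109
tree highest degree: 0.33
```

— a slowed, theta-dominant subject (this one jittered down from the
6.9 Hz group template) with near-null alpha connectivity, as intended for
the DLB-like archetype; the pipeline recovers the generated dominant
frequency to within its 0.5 Hz spectral resolution. The full study-shaped analysis lives under
`analysis/`: `01_simulate_cohorts.py` writes three 20-subject cohorts
(DLB-like, AD-like, mixed-pathology) as EDF under `scratch/`,
`02_extract_features.py` produces the 25-column feature table,
`03_group_statistics.py` runs ANOVA/Kruskal-Wallis with Bonferroni
post-hocs, and `04_classify.py` fits the three pairwise OOB forests. On
the default seeds the two Lewy-body-like groups separate from the
AD-like group at 93% OOB accuracy each, while the two Lewy-body-like
groups are much harder to tell apart (75%) — the clinical pattern.

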