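# Methods

`qeeg` implements a resting-state quantitative-EEG pipeline of the kind
used to separate dementia with Lewy bodies (DLB) from Alzheimer's disease
(AD): per-channel spectral features, alpha-band phase-lag-index (PLI)
connectivity, minimum-spanning-tree (MST) network topology, and an
out-of-bag random-forest classifier over the resulting 25-feature vector.
Because clinical recordings of this kind are not publicly deposited, the
package ships a synthetic cohort generator with known ground truth; every
pipeline stage is validated against that ground truth or against an
independent oracle.

## Recording model and preprocessing

Recordings are 21-channel 10-20 montages (Fp2 … Pz, including the ear
electrodes A1/A2) sampled at 500 Hz, held in µV. The analysis montage
defaults to the 19 scalp channels: ear electrodes sit outside the scalp
neighbour lattice used for Laplacian-style referencing and are excluded
by default (configurable via `Montage`). Consequently the
"lowest/mean/highest across channels" feature reductions run over 19
channels here.

**Source derivation (Hjorth referencing).** Each output channel is the
input channel minus the unweighted mean of its montage neighbours, all
computed from the original signals. The neighbour table is the standard
nearest-neighbour adjacency on the 10-20 grid, shipped as data and
editable as YAML. Unweighted means are the simplest defensible reading of
Hjorth referencing; distance-weighted variants exist but require electrode
coordinates the montage does not carry. The derivation annihilates any
spatially uniform component exactly, which is the property the tests pin.

**Band-pass filtering.** Six bands partition 0.5–48 Hz: delta (0.5–4),
theta (4–8), alpha-1 (8–10), alpha-2 (10–13), beta (13–30), gamma
(30–48 Hz); bands are half-open `[lo, hi)` so every frequency belongs to
exactly one. Filters are zero-phase forward–backward 4th-order
Butterworth in second-order sections. The contract, not the realization,
is normative: unit gain (±5%) at band centre, ≥20 dB one octave outside
either edge, output length preserved. Note that forward–backward
filtering squares the magnitude response, so gain at a band edge is ~0.5.

**Epochs.** Four artifact-free epochs per subject are the unit of
analysis. Clinical practice selects them visually; here explicit sample
offsets replace visual selection (evenly spaced by default). The default
epoch length is 8 s: conventional descriptions say "approximately 10 s",
but dividing four epochs into 2-s pieces is also conventionally described
as yielding 16 sub-epochs per subject, which forces 8 usable seconds per
epoch. We adopt 8 s as the reconciliation and document it here. Splitting
discards any trailing remainder shorter than one piece.

## Spectral features

Welch spectra: 2-s Hamming-tapered segments, 50% overlap, mean over
segments and epochs; 0.5 Hz resolution; total integrated power matches
time-domain variance within 5% (Parseval check). Band power uses a
rectangle rule over half-open bin masks so the six band powers partition
broadband power exactly; relative power divides by the 0.5–48 Hz
broadband power (configurable to 0.5–30 Hz). Gamma is computed and
reported but, following convention for muscle-artifact-prone bands, not
classified on.

The peak (dominant) frequency is the argmax of the density inside a 4–13
Hz search window (full-range argmax would lock onto delta in slowed
records); ties break toward the lower frequency; the global peak uses the
channel-averaged spectrum (taking the peak of the average rather than the
average of peaks is a choice; both are defensible and the former is less
noisy at 0.5 Hz resolution). Peak-frequency variability is the SD of the
global peak across the 16 2-s sub-epochs, population formula (divisor n)
by default, switchable with `ddof=1`. The theta/alpha ratio —
theta / (theta + alpha-1 + alpha-2), an index of EEG slowing — is
computed from channel-mean relative powers.

## Connectivity and network topology

PLI between two channels is |⟨sign(sin(Δφ))⟩| with Δφ the instantaneous
phase difference of the analytic (Hilbert) signal after filtering to the
8–13 Hz alpha band (the union of alpha-1 and alpha-2, filtered as one
band). `sign(0)` contributes 0, which forces the zero-lag → PLI 0
property that makes the measure insensitive to volume conduction. A
0.25-s margin at each epoch end is excluded from the sign average to
suppress filter/Hilbert transients (configurable). PLI is computed per
epoch and the matrices averaged, matching standard epoch-wise practice;
pooling phases across epochs is the plausible alternative and agrees
exactly for identical epochs (tested).

The "minimum spanning tree of the PLI matrix", as the term is used in
this literature, keeps the N−1 *strongest* links: we compute the
maximum-weight spanning tree (equivalently, minimum over 1−PLI) by
Kruskal over edges sorted by descending weight, ties broken by
lexicographic node order for cross-platform determinism. Minimizing raw
PLI would retain the weakest links and invert the meaning of every
hub/leaf metric. With M = N−1 edges, L leaves, diameter d in edges and
BC_max the maximum normalized betweenness centrality:
degree_max/M, L/M, d/M and L/(2·M·BC_max) are the four reported
metrics (all dimensionless; L/M is capped at 1 for the two-node tree).
These normalizations place a star at (1, 1, 0.1, 0.5) and a path at
(0.1, 0.1, 1, ·) for N = 21, the magnitude range reported for clinical
alpha-band trees. Diameter is computed and reported but excluded from the
classifier feature set.

## Classification

The 25-feature vector is fixed and ordered: lowest/mean/highest relative
power for delta, theta, alpha-1, alpha-2, beta; lowest/mean/highest peak
frequency; theta/alpha ratio; lowest/mean/highest alpha-band PLI (matrix
upper triangle); highest degree, leaf number, tree hierarchy.

Each forest tree is a CART tree (Gini, grown to purity, `m_try = 5 =
⌊√25⌋` features per split) fitted on a bootstrap sample drawn **with
replacement of size ⌈2n/3⌉** — deliberately non-standard, following the
explicit "2/3 with replacement" convention of the source analysis
software rather than the classical size-n bootstrap
(`conventional_bootstrap=True` restores the classical behaviour; with the
2/3 bootstrap a subject is out-of-bag per tree with probability
(1−1/n)^⌈2n/3⌉ ≈ 0.51 at n = 40). A subject's OOB prediction is the
majority vote over trees whose bootstrap excluded it; accuracy,
sensitivity and specificity come from OOB predictions, so no held-out set
is needed. VIMP is permutation importance: the mean decrease in per-tree
OOB accuracy when one feature is permuted within the OOB block. Defaults
n_tree = 1000 (500 in the analysis scripts and acceptance runs, where the
OOB estimates are already stable), deterministic given the seed. Note the
OOB vote is pessimistically biased on exchangeable groups at small n;
measured null accuracies sit at or somewhat below 0.5.

Group comparison (`compare_groups`) is a thin stage over scipy: one-way
ANOVA and Kruskal-Wallis with Bonferroni-multiplied pairwise Welch
t-tests, capped at 1.

## Synthetic cohorts

Each channel is built on a variance budget: a dominant rhythm plus
band-limited noise per band (white noise through the package's own band
filters, so generator and analyzer agree exactly on band edges), plus
white observation noise. The rhythm is an oscillator with a Brownian
phase walk giving a Lorentzian line (default FWHM 1 Hz), then confined
with its band's filter because the Lorentzian tails would otherwise leak
across band edges. The phase walk is essential: pure sinusoids at a
shared frequency are phase-locked between *all* channels, so uncoupled
channels would show spuriously perfect PLI.

Coupling phase-shifts a copy of the source channel's oscillatory content
into the target through the analytic signal (exact lag at every
frequency, not a time delay), mixed at weight `strength` against
√(1−strength²) of the target's own content. This makes the PLI oracle
analytic (constant lag → 1, zero lag → 0) and measured PLI monotone in
strength under noise.

Archetype templates emulate group-level clinical structure, not any
dataset: DLB-like (dominant 6.9 Hz, theta-heavy spectrum, weak coupling
0.45), AD-like (8.4 Hz, alpha-heavy, strong coupling 0.9), mixed
(6.9 Hz, intermediate spectrum, coupling 0.4). Band fractions follow
published group-mean relative powers with the remainder assigned to
gamma. Coupling is a posterior hub (Pz → seven posterior/central
channels) with per-target lags spread over 0.4–2.2 rad; equal lags would
leave target–target pairs at zero effective lag, invisible to PLI. The
AD-like coupling weight (0.9) is deliberately high because Hjorth
derivation and the target's independent content dilute pair-level PLI;
the chosen weights place group-mean alpha PLI near 0.13 (DLB-like) vs
0.17 (AD-like), the clinically reported scale. Between-subject jitter
defaults match reported clinical spread (dominant-frequency SD 1 Hz,
band-fraction SD 0.05 renormalized, coupling-strength SD 0.1). Seeds use
NumPy PCG64 throughout; per-subject seeds derive from the cohort seed by
a counter-based `SeedSequence` key, so extending a cohort never perturbs
existing subjects.

What the generator does **not** emulate: eye/muscle artifacts, frontal
rhythmic delta morphology, sleep or drowsiness, volume conduction (no
head model), non-stationarity beyond the phase walk, or 1/f broadband
structure. Passing tests therefore demonstrate correctness of the
estimators and the direction of group contrasts under the stated
generative assumptions — not clinical performance on real EEG.

## Problem sizes and numerical choices

Analysis scripts and acceptance runs use 20 subjects per group, 32-s
recordings (4 × 8-s epochs), chosen so a full three-cohort pipeline run
completes in about a minute while group contrasts remain many standard
errors wide. Degenerate inputs are handled explicitly: constant signals
raise on phase extraction, zero total power raises on relative power, an
all-zero connectivity matrix still yields a (flagged) tree via the
deterministic tie-break. EDF output quantizes to 16 bits over each
channel's observed physical range; round-trips are exact to one
quantization step and are cross-checked against an independent reader.

Known limitations: the finite-sample PLI null for 4 × 8-s alpha-filtered
epochs is ≈0.1 (the sign series decorrelates in roughly 1/bandwidth
= 0.2 s, giving ~40 effective samples per epoch), so small true couplings
are not detectable at this recording length; tree metrics on near-null
matrices are dominated by noise ordering; and the OOB accuracy of the
2/3 bootstrap differs slightly from the classical forest's.
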