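"""Synthetic multichannel EEG cohorts with known ground truth.

Each synthetic channel is the sum of three components on a controlled
variance budget:

* a narrowband rhythm — an oscillator at the subject's dominant frequency
  with a random starting phase and a slow phase-diffusion walk (finite
  coherence time, Lorentzian linewidth ``rhythm_linewidth_hz``), carrying a
  fixed share (``rhythm_fraction``) of its band's variance. The phase walk
  is essential: perfectly sinusoidal rhythms at a shared frequency would be
  phase-locked between *all* channels, coupled or not;
* band-limited noise per frequency band, realized as white noise passed
  through the package's own zero-phase band-pass filters (so generator and
  analyzer agree exactly on band edges), scaled so per-band variance
  fractions match ``band_fractions``;
* white observation noise with standard deviation ``noise_sd``.

Phase-lagged coupling between channel pairs is implemented as a phase
offset, not a whole-signal delay. The coupled channel's oscillatory
content (rhythm plus all band-limited noise, everything except the white
observation noise) is a ``strength``-weighted mix of a phase-shifted copy
of the source channel's oscillatory content and its own independent one;
the shift is applied through the analytic signal, so the lag is exact at
every frequency. The Phase Lag Index of a clean coupled pair is therefore
analytic — a constant non-zero lag gives PLI 1, a zero lag gives PLI 0 —
while uncoupled oscillators decohere to the null because their phase walks
and band noises are independent.

The cohort archetypes emulate the *statistical contrast* between
dementia-with-Lewy-bodies-like and Alzheimer-like resting-state EEG —
a slowed dominant rhythm with a theta-heavy spectrum and weak alpha-band
coupling versus a faster, alpha-heavy spectrum with stronger coupling.
They are an emulation of group-level structure, not a reproduction of any
clinical dataset: no eye/muscle artifacts, no frontal rhythmic delta
morphology, no volume-conduction head model.

Randomness uses NumPy's PCG64 generator throughout; identical specs and
seeds give bit-identical recordings. Per-subject seeds are derived from the
cohort seed with a counter-based ``SeedSequence`` spawn key, so adding a
subject to a cohort never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from qeeg.bands import Band, DEFAULT_BANDS, band_for
from qeeg.montage import CHANNELS_1020
from qeeg.preprocess import bandpass
from qeeg.recording import EEGRecording

#: (channel_i, channel_j, phase lag in radians, coupling strength in [0, 1])
Coupling = tuple[int, int, float, float]


@dataclass
class SubjectSpec:
    """Ground-truth generative parameters for one synthetic subject."""

    dominant_freq: float = 8.4
    band_fractions: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.32, "theta": 0.18, "alpha1": 0.15,
                                 "alpha2": 0.09, "beta": 0.15, "gamma": 0.11})
    coupling: list[Coupling] = field(default_factory=list)
    noise_sd: float = 0.1
    n_channels: int = 21
    fs: float = 500.0
    epoch_length_s: float = 8.0
    n_epochs: int = 4
    seed: int = 0
    rhythm_fraction: float = 0.5     # share of the dominant band's variance in the rhythm
    rhythm_linewidth_hz: float = 1.0  # Lorentzian linewidth of the rhythm (phase diffusion)
    signal_rms: float = 1.0          # RMS of the noise-free signal, µV
    bands: tuple[Band, ...] = DEFAULT_BANDS

    def validate(self) -> None:
        fracs = self.band_fractions
        names = {b.name for b in self.bands}
        unknown = set(fracs) - names
        if unknown:
            raise ValueError(f"band_fractions names unknown bands: {sorted(unknown)}")
        if any(v < 0 for v in fracs.values()):
            raise ValueError("band_fractions values must be >= 0")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band_fractions must sum to 1 +- 1e-9, got {total}")
        band_for(self.dominant_freq, self.bands)  # raises unless in exactly one band
        if not 0.0 <= self.rhythm_fraction <= 1.0:
            raise ValueError("rhythm_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_channels < 1 or self.fs <= 0 or self.epoch_length_s <= 0 or self.n_epochs < 1:
            raise ValueError("n_channels, fs, epoch_length_s and n_epochs must be positive")
        seen = set()
        for (i, j, lag, strength) in self.coupling:
            if i == j:
                raise ValueError(f"coupling channel indices must be distinct, got ({i}, {j})")
            for c in (i, j):
                if not 0 <= c < self.n_channels:
                    raise ValueError(f"coupling channel index {c} out of range [0, {self.n_channels})")
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"coupling strength must be in [0, 1], got {strength}")
            if j in seen:
                raise ValueError(f"channel {j} is the target of more than one coupling")
            seen.add(j)

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.epoch_length_s * self.n_epochs)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CohortSpec:
    """A group of subjects drawn from a template with between-subject jitter.

    ``between_subject_jitter`` maps parameter names to spreads (SDs):
    ``dominant_freq`` (Hz), ``band_fractions`` (additive SD per fraction,
    renormalized), ``coupling_strength`` (clipped to [0, 1]) and
    ``noise_sd`` (clipped to >= 0).
    """

    group_label: str
    n_subjects: int
    subject_template: SubjectSpec
    between_subject_jitter: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(v < 0 for v in self.between_subject_jitter.values()):
            raise ValueError("jitter values must be >= 0")
        known = {"dominant_freq", "band_fractions", "coupling_strength", "noise_sd"}
        unknown = set(self.between_subject_jitter) - known
        if unknown:
            raise ValueError(f"unknown jitter parameters: {sorted(unknown)}")
        self.subject_template.validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        tmpl = data.pop("subject_template")
        coupling = [tuple(c) for c in tmpl.pop("coupling", [])]
        return cls(subject_template=SubjectSpec(coupling=coupling, **tmpl), **data)


def _unit_rhythm(freq: float, phase, n: int, fs: float) -> np.ndarray:
    """Unit-variance oscillation at ``freq``; ``phase`` may be scalar or a walk."""
    t = np.arange(n) / fs
    return np.sqrt(2.0) * np.cos(2.0 * np.pi * freq * t + phase)


def _phase_walk(rng: np.random.Generator, n: int, fs: float, linewidth_hz: float) -> np.ndarray:
    """Brownian phase path giving a Lorentzian line of FWHM ~ ``linewidth_hz``."""
    if linewidth_hz <= 0:
        return np.zeros(n)
    step_sd = np.sqrt(2.0 * np.pi * linewidth_hz / fs)
    return np.cumsum(rng.normal(0.0, step_sd, size=n))


def _unit_band_noise(rng: np.random.Generator, band: Band, n: int, fs: float) -> np.ndarray:
    x = rng.standard_normal(n)
    y = bandpass(x, band, fs=fs)
    sd = y.std()
    return y / sd if sd > 0 else y


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Advance the instantaneous phase of a band-limited signal by ``lag`` rad."""
    from scipy.signal import hilbert

    return np.real(hilbert(x) * np.exp(1j * lag))


def generate_subject(spec: SubjectSpec, subject_id: str = "") -> EEGRecording:
    """Generate one synthetic multichannel recording; deterministic given seed."""
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    n = spec.n_samples
    dom_band = band_for(spec.dominant_freq, spec.bands)

    total_var = spec.signal_rms ** 2
    rhythm_sd = np.sqrt(total_var * spec.band_fractions.get(dom_band.name, 0.0)
                        * spec.rhythm_fraction)

    phases = rng.uniform(-np.pi, np.pi, size=spec.n_channels)
    walks = np.vstack([_phase_walk(rng, n, spec.fs, spec.rhythm_linewidth_hz)
                       for _ in range(spec.n_channels)])
    coupled_target = {j: (i, lag, s) for (i, j, lag, s) in spec.coupling}

    # per-channel oscillatory content, kept separate from the white
    # observation noise so coupling can mix it between channels afterwards
    osc = np.zeros((spec.n_channels, n))
    white = np.zeros((spec.n_channels, n))
    for c in range(spec.n_channels):
        # the Lorentzian line of the diffusing oscillator has heavy tails;
        # confining it with the band's own filter keeps the variance budget
        raw = _unit_rhythm(spec.dominant_freq, phases[c] + walks[c], n, spec.fs)
        if rhythm_sd > 0:
            confined = bandpass(raw, dom_band, fs=spec.fs)
            osc[c] += rhythm_sd * confined / confined.std()
        for band in spec.bands:
            frac = spec.band_fractions.get(band.name, 0.0)
            if frac <= 0:
                continue
            var = total_var * frac
            if band.name == dom_band.name:
                var *= (1.0 - spec.rhythm_fraction)
            if var > 0:
                osc[c] += np.sqrt(var) * _unit_band_noise(rng, band, n, spec.fs)
        if spec.noise_sd > 0:
            white[c] = spec.noise_sd * rng.standard_normal(n)

    out = white
    for c in range(spec.n_channels):
        if c in coupled_target:
            src, lag, strength = coupled_target[c]
            out[c] += (strength * _phase_shift(osc[src], lag)
                       + np.sqrt(max(0.0, 1.0 - strength ** 2)) * osc[c])
        else:
            out[c] += osc[c]

    labels = list(CHANNELS_1020[:spec.n_channels]) if spec.n_channels <= len(CHANNELS_1020) \
        else [f"ch{i}" for i in range(spec.n_channels)]
    return EEGRecording(out, spec.fs, labels, subject_id)


def subject_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed (counter-based, order-independent)."""
    return int(np.random.SeedSequence((cohort_seed, index)).generate_state(1)[0])


def _jitter_spec(template: SubjectSpec, jitter: dict[str, float],
                 rng: np.random.Generator, seed: int) -> SubjectSpec:
    spec = replace(template, seed=seed,
                   band_fractions=dict(template.band_fractions),
                   coupling=list(template.coupling))
    if jitter.get("dominant_freq", 0) > 0:
        f = spec.dominant_freq + rng.normal(0, jitter["dominant_freq"])
        spec.dominant_freq = float(np.clip(f, 1.0, 13.0))
    if jitter.get("band_fractions", 0) > 0:
        sd = jitter["band_fractions"]
        fr = {k: max(1e-6, v + rng.normal(0, sd)) for k, v in spec.band_fractions.items()}
        total = sum(fr.values())
        spec.band_fractions = {k: v / total for k, v in fr.items()}
    if jitter.get("coupling_strength", 0) > 0:
        sd = jitter["coupling_strength"]
        spec.coupling = [(i, j, lag, float(np.clip(s + rng.normal(0, sd), 0.0, 1.0)))
                         for (i, j, lag, s) in spec.coupling]
    if jitter.get("noise_sd", 0) > 0:
        spec.noise_sd = float(max(0.0, spec.noise_sd + rng.normal(0, jitter["noise_sd"])))
    return spec


def generate_cohort(cohort: CohortSpec) -> list[tuple[EEGRecording, SubjectSpec]]:
    """Generate a cohort; returns (recording, ground-truth spec) per subject."""
    cohort.validate()
    out = []
    for i in range(cohort.n_subjects):
        seed_i = subject_seed(cohort.seed, i)
        # jitter drawn from a stream independent of the subject's own noise
        jit_rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence((cohort.seed, i, 1))))
        spec_i = _jitter_spec(cohort.subject_template, cohort.between_subject_jitter,
                              jit_rng, seed_i)
        sid = f"{cohort.group_label}-{i:03d}"
        out.append((generate_subject(spec_i, subject_id=sid), spec_i))
    return out


def coupled_pair(freq: float, lag: float, strength: float, duration_s: float,
                 fs: float = 500.0, noise_sd: float = 0.0, seed: int = 0) -> EEGRecording:
    """Two-channel oracle input for the Phase Lag Index.

    Channel 2 carries a ``strength``-weighted copy of channel 1's sinusoidal
    source phase-shifted by ``lag`` radians; both channels get independent
    white noise of SD ``noise_sd``.
    """
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq must lie in (0, Nyquist={fs / 2}), got {freq}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n = round(duration_s * fs)
    phase0 = rng.uniform(-np.pi, np.pi)
    walk = _phase_walk(rng, n, fs, linewidth_hz=1.0)
    ch1 = _unit_rhythm(freq, phase0 + walk, n, fs)
    ch2 = strength * _unit_rhythm(freq, phase0 + walk + lag, n, fs)
    if noise_sd > 0:
        ch1 = ch1 + noise_sd * rng.standard_normal(n)
        ch2 = ch2 + noise_sd * rng.standard_normal(n)
    return EEGRecording(np.vstack([ch1, ch2]), fs, ["ch1", "ch2"], "coupled-pair")


# --------------------------------------------------------------------------
# Cohort archetypes: group-mean spectral profiles and dominant frequencies
# follow published group-level contrasts between Lewy-body dementia and
# Alzheimer's disease resting-state EEG (slowed, theta-heavy vs alpha-heavy).
# Coupling is a posterior hub (Pz) phase-lagged to seven posterior/central
# channels at the dominant frequency: in the alpha-heavy archetype the
# rhythm falls inside the 8-13 Hz connectivity band so coupling is visible
# to alpha-band PLI; in the slowed archetypes it falls below it.
# --------------------------------------------------------------------------

_PZ = CHANNELS_1020.index("Pz")
_HUB_TARGETS = tuple(CHANNELS_1020.index(c) for c in ("O1", "O2", "P3", "P4", "T5", "T6", "Cz"))
# lags spread over (0, pi) so target-target pairs also carry non-zero
# effective lags (equal lags would leave them at zero lag, invisible to PLI)
_HUB_LAGS = tuple(0.4 + 0.3 * k for k in range(len(_HUB_TARGETS)))


def _hub_coupling(strength: float) -> list[Coupling]:
    return [(_PZ, j, lag, strength) for j, lag in zip(_HUB_TARGETS, _HUB_LAGS)]


def dlb_like_template(**overrides) -> SubjectSpec:
    """Lewy-body-like archetype: slowed dominant rhythm, theta-heavy, weak coupling."""
    spec = SubjectSpec(
        dominant_freq=6.9,
        band_fractions={"delta": 0.41, "theta": 0.34, "alpha1": 0.07,
                        "alpha2": 0.04, "beta": 0.06, "gamma": 0.08},
        coupling=_hub_coupling(0.45),
        noise_sd=1.5, signal_rms=15.0,
    )
    return replace(spec, **overrides)


def ad_like_template(**overrides) -> SubjectSpec:
    """Alzheimer-like archetype: alpha-range dominant rhythm, stronger coupling."""
    spec = SubjectSpec(
        dominant_freq=8.4,
        band_fractions={"delta": 0.32, "theta": 0.18, "alpha1": 0.15,
                        "alpha2": 0.09, "beta": 0.15, "gamma": 0.11},
        coupling=_hub_coupling(0.9),
        noise_sd=1.5, signal_rms=15.0,
    )
    return replace(spec, **overrides)


def mixed_like_template(**overrides) -> SubjectSpec:
    """Mixed-pathology archetype: slowed rhythm with an intermediate spectrum."""
    spec = SubjectSpec(
        dominant_freq=6.9,
        band_fractions={"delta": 0.42, "theta": 0.26, "alpha1": 0.09,
                        "alpha2": 0.04, "beta": 0.08, "gamma": 0.11},
        coupling=_hub_coupling(0.4),
        noise_sd=1.5, signal_rms=15.0,
    )
    return replace(spec, **overrides)


#: Default between-subject jitter for archetype cohorts, matching the
#: between-subject spread reported for clinical dementia groups
#: (peak-frequency SD ~1 Hz, band-power SDs of several percentage points).
DEFAULT_JITTER = {"dominant_freq": 1.0, "band_fractions": 0.05,
                  "coupling_strength": 0.10}


def archetype_cohort(group: str, n_subjects: int = 20, seed: int = 0,
                     jitter: dict[str, float] | None = None) -> CohortSpec:
    """Convenience constructor for the three study-like cohorts.

    ``group`` is one of ``"dlb"`` (Lewy-body-like), ``"ad"``
    (Alzheimer-like) or ``"mixed"`` (Lewy-body with Alzheimer-like
    co-pathology).
    """
    templates = {"dlb": dlb_like_template, "ad": ad_like_template,
                 "mixed": mixed_like_template}
    if group not in templates:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(templates)}")
    return CohortSpec(
        group_label=group,
        n_subjects=n_subjects,
        subject_template=templates[group](),
        between_subject_jitter=dict(DEFAULT_JITTER if jitter is None else jitter),
        seed=seed,
    )
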