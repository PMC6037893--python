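"""Spectral qEEG features: relative band power, peak frequency and its
variability, and the theta/alpha ratio.

Spectra are Welch-averaged periodograms (2-s Hamming-tapered segments, 50%
overlap, mean over epochs and segments), giving 0.5 Hz resolution and
Parseval-consistent power. The theta/alpha ratio — an index of EEG slowing
— is theta / (theta + alpha-1 + alpha-2), computed from channel-mean
relative powers. Peak-frequency variability is the standard deviation of
the global peak frequency across short (conventionally 2-s) sub-epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from qeeg.bands import Band, DEFAULT_BANDS, BROADBAND
from qeeg.recording import EpochSet

#: Default search range for the dominant (peak) frequency, Hz. Reported
#: dominant rhythms in dementia cohorts fall in the theta-alpha range; a
#: full-range argmax would lock onto delta.
PEAK_SEARCH_RANGE: tuple[float, float] = (4.0, 13.0)


@dataclass
class PowerSpectrum:
    """Per-channel Welch power spectral density."""

    freqs: np.ndarray            # Hz grid, strictly increasing
    density: np.ndarray          # (n_channels, n_freqs), power per Hz
    channel_labels: list[str]
    resolution: float            # Hz

    def band_power(self, band: Band) -> np.ndarray:
        """Integrated power in [band.lo, band.hi) per channel.

        Rectangle rule over half-open bin masks, so contiguous bands
        partition the broadband power exactly.
        """
        mask = (self.freqs >= band.lo) & (self.freqs < band.hi)
        return self.density[:, mask].sum(axis=1) * self.resolution


@dataclass
class SpectralSummary:
    """The spectral feature block for one subject."""

    rel_power: dict[str, np.ndarray]     # band name -> per-channel fraction
    peak_freq_per_channel: np.ndarray    # Hz
    global_peak_freq: float              # Hz, peak of the channel-averaged spectrum
    peak_freq_variability: float         # Hz, SD over sub-epochs
    theta_alpha_ratio: float
    channel_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (channel, band, fraction) table."""
        rows = [
            {"channel": ch, "band": band, "fraction": self.rel_power[band][i]}
            for band in self.rel_power
            for i, ch in enumerate(self.channel_labels)
        ]
        return pd.DataFrame(rows)


def power_spectrum(epochs: EpochSet, segment_s: float = 2.0) -> PowerSpectrum:
    """Welch-average periodogram per channel across epochs.

    Raises if epochs are shorter than one segment (the 0.5 Hz resolution
    contract would be unattainable).
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    nperseg = round(segment_s * epochs.fs)
    if epochs.n_times < nperseg:
        raise ValueError(
            f"epoch length {epochs.n_times / epochs.fs:.2f} s is shorter than the "
            f"{segment_s} s analysis segment"
        )
    freqs, psd = sps.welch(
        epochs.epochs, fs=epochs.fs, window="hamming", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant", scaling="density", axis=-1,
    )
    density = psd.mean(axis=0)  # average over epochs
    return PowerSpectrum(freqs=freqs, density=density,
                         channel_labels=list(epochs.channel_labels),
                         resolution=float(freqs[1] - freqs[0]))


def relative_band_power(
    spectrum: PowerSpectrum,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    denominator_range: Band = BROADBAND,
) -> dict[str, np.ndarray]:
    """Per-channel fraction of power in each band relative to the broadband
    denominator (default 0.5-48 Hz, the union of the six bands)."""
    for b in bands:
        if b.lo < denominator_range.lo or b.hi > denominator_range.hi:
            raise ValueError(f"band {b.name!r} exceeds the denominator range")
    denom = spectrum.band_power(denominator_range)
    if np.any(denom <= 0):
        raise ValueError("zero total power in the denominator range")
    return {b.name: spectrum.band_power(b) / denom for b in bands}


def peak_frequency(
    spectrum: PowerSpectrum,
    search_range: tuple[float, float] = PEAK_SEARCH_RANGE,
) -> tuple[np.ndarray, float]:
    """Per-channel and global peak frequency.

    The per-channel peak is the argmax of the density inside the search
    range; the global peak is the argmax of the channel-averaged spectrum.
    Ties break toward the lower frequency.
    """
    lo, hi = search_range
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(f"search range {search_range} contains no spectral bins")
    freqs = spectrum.freqs[mask]
    dens = spectrum.density[:, mask]
    per_channel = freqs[np.argmax(dens, axis=1)]  # argmax returns first (lowest) on ties
    global_peak = float(freqs[np.argmax(dens.mean(axis=0))])
    return per_channel, global_peak


def peak_frequency_variability(
    sub_epochs: EpochSet,
    search_range: tuple[float, float] = PEAK_SEARCH_RANGE,
    segment_s: float = 2.0,
    ddof: int = 0,
) -> float:
    """SD of the global peak frequency across sub-epochs (population SD by
    default; pass ``ddof=1`` for the sample formula)."""
    if sub_epochs.n_epochs < 2:
        raise ValueError("need at least 2 sub-epochs to estimate variability")
    peaks = []
    for e in range(sub_epochs.n_epochs):
        one = EpochSet(sub_epochs.epochs[e:e + 1], sub_epochs.fs,
                       list(sub_epochs.channel_labels), sub_epochs.subject_id)
        spec = power_spectrum(one, segment_s=min(segment_s, one.epoch_length_s))
        _, gpeak = peak_frequency(spec, search_range)
        peaks.append(gpeak)
    return float(np.std(peaks, ddof=ddof))


def theta_alpha_ratio(rel_power: dict[str, np.ndarray]) -> float:
    """theta / (theta + alpha1 + alpha2) from channel-mean relative powers."""
    theta = float(np.mean(rel_power["theta"]))
    alpha = float(np.mean(rel_power["alpha1"])) + float(np.mean(rel_power["alpha2"]))
    denom = theta + alpha
    if denom <= 0:
        raise ValueError("theta + alpha1 + alpha2 power is zero")
    return theta / denom


def spectral_summary(
    epochs: EpochSet,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    denominator_range: Band = BROADBAND,
    search_range: tuple[float, float] = PEAK_SEARCH_RANGE,
    sub_epochs: EpochSet | None = None,
) -> SpectralSummary:
    """Compute the full spectral feature block for one subject.

    ``sub_epochs`` (default: the epochs split into 2-s pieces) feed the
    peak-frequency variability estimate.
    """
    from qeeg.preprocess import split_epochs

    spectrum = power_spectrum(epochs)
    rel = relative_band_power(spectrum, bands, denominator_range)
    per_channel, global_peak = peak_frequency(spectrum, search_range)
    if sub_epochs is None:
        sub_epochs = split_epochs(epochs, piece_length_s=2.0)
    variability = peak_frequency_variability(sub_epochs, search_range)
    return SpectralSummary(
        rel_power=rel,
        peak_freq_per_channel=per_channel,
        global_peak_freq=global_peak,
        peak_freq_variability=variability,
        theta_alpha_ratio=theta_alpha_ratio(rel),
        channel_labels=list(epochs.channel_labels),
    )
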