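"""Spectral estimation contracts: Parseval, normalization, peaks, ratios."""

import numpy as np
import pytest

from qeeg.bands import ALPHA1, BROADBAND, DEFAULT_BANDS
from qeeg.recording import EpochSet
from qeeg.spectral import (
    peak_frequency,
    peak_frequency_variability,
    power_spectrum,
    relative_band_power,
    theta_alpha_ratio,
)
from tests.conftest import noise_epochs, sine_epochs


class TestPowerSpectrum:
    def test_sinusoid_mass_is_concentrated(self):
        es = sine_epochs(10.0)
        spec = power_spectrum(es)
        mask = (spec.freqs >= 9.5) & (spec.freqs <= 10.5)
        assert spec.density[0, mask].sum() / spec.density[0].sum() >= 0.95

    def test_zero_signal_zero_density(self):
        es = sine_epochs(10.0, amplitude=0.0)
        spec = power_spectrum(es)
        assert np.all(spec.density == 0)

    def test_resolution_at_most_half_hz(self):
        spec = power_spectrum(sine_epochs(10.0))
        assert spec.resolution <= 0.5

    def test_parseval_consistency(self, rng):
        es = noise_epochs(rng, n_epochs=8)
        spec = power_spectrum(es)
        integrated = spec.density.sum(axis=1) * spec.resolution
        variance = np.var(es.epochs, axis=-1).mean(axis=0)
        assert integrated[0] == pytest.approx(variance[0], rel=0.05)

    def test_white_noise_density_is_flat(self, rng):
        es = noise_epochs(rng, n_epochs=16)
        spec = power_spectrum(es)
        win_a = (spec.freqs >= 20) & (spec.freqs < 25)
        win_b = (spec.freqs >= 100) & (spec.freqs < 105)
        ratio = spec.density[0, win_a].mean() / spec.density[0, win_b].mean()
        assert 0.7 <= ratio <= 1.4

    def test_too_short_epochs_rejected(self, rng):
        es = noise_epochs(rng, epoch_s=1.0)
        with pytest.raises(ValueError, match="segment"):
            power_spectrum(es)


class TestRelativeBandPower:
    def test_pure_alpha1_tone(self):
        spec = power_spectrum(sine_epochs(9.0))
        rel = relative_band_power(spec)
        assert rel["alpha1"][0] >= 0.95

    def test_fractions_sum_to_one(self, rng):
        spec = power_spectrum(noise_epochs(rng, n_channels=3))
        rel = relative_band_power(spec)
        total = np.sum([rel[b.name] for b in DEFAULT_BANDS], axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_scale_invariance(self, rng):
        es = noise_epochs(rng, n_channels=2)
        rel1 = relative_band_power(power_spectrum(es))
        scaled = EpochSet(es.epochs * 37.5, es.fs, list(es.channel_labels))
        rel2 = relative_band_power(power_spectrum(scaled))
        for b in DEFAULT_BANDS:
            np.testing.assert_allclose(rel1[b.name], rel2[b.name], atol=1e-9)

    def test_white_noise_delta_fraction_matches_flat_spectrum(self, rng):
        # flat spectrum: delta share = (4-0.5)/(48-0.5) = 0.0737
        rels = []
        for k in range(4):
            es = noise_epochs(np.random.Generator(np.random.PCG64(k)), n_epochs=16)
            rels.append(relative_band_power(power_spectrum(es))["delta"][0])
        assert np.mean(rels) == pytest.approx(3.5 / 47.5, abs=0.02)

    def test_zero_power_rejected(self):
        spec = power_spectrum(sine_epochs(10.0, amplitude=0.0))
        with pytest.raises(ValueError, match="zero total power"):
            relative_band_power(spec)


class TestPeakFrequency:
    def test_single_tone(self):
        spec = power_spectrum(sine_epochs(7.0))
        per_channel, global_peak = peak_frequency(spec)
        assert per_channel[0] == pytest.approx(7.0, abs=0.25)
        assert global_peak == pytest.approx(7.0, abs=0.25)

    def test_larger_amplitude_component_wins(self):
        es = sine_epochs(6.0, amplitude=2.0)
        es.epochs = es.epochs + sine_epochs(10.0, amplitude=1.0).epochs
        _, global_peak = peak_frequency(power_spectrum(es))
        assert global_peak == pytest.approx(6.0, abs=0.25)

    def test_two_channels_peaking_apart(self):
        low = sine_epochs(6.0)
        high = sine_epochs(10.0)
        es = EpochSet(np.concatenate([low.epochs, high.epochs], axis=1),
                      low.fs, ["lo", "hi"])
        per_channel, global_peak = peak_frequency(power_spectrum(es))
        assert sorted(per_channel) == [6.0, 10.0]
        assert global_peak in (6.0, 10.0)

    def test_exact_tie_breaks_toward_lower_frequency(self):
        from qeeg.spectral import PowerSpectrum

        freqs = np.arange(0, 20.5, 0.5)
        dens = np.zeros((2, freqs.size))
        dens[0, freqs == 6.0] = 1.0   # channel peaks at 6 Hz
        dens[1, freqs == 10.0] = 1.0  # channel peaks at 10 Hz, equal power
        spec = PowerSpectrum(freqs, dens, ["lo", "hi"], 0.5)
        per_channel, global_peak = peak_frequency(spec)
        assert sorted(per_channel) == [6.0, 10.0]
        assert global_peak == 6.0  # channel-mean spectrum ties; lower wins

    def test_empty_search_range_rejected(self):
        spec = power_spectrum(sine_epochs(7.0))
        with pytest.raises(ValueError, match="search range"):
            peak_frequency(spec, search_range=(4.1, 4.2))


class TestPeakFrequencyVariability:
    def test_identical_sub_epochs_have_zero_variability(self):
        es = sine_epochs(7.0, n_epochs=16, epoch_s=2.0)
        assert peak_frequency_variability(es) == 0.0

    def test_two_point_distribution(self):
        lows = sine_epochs(6.0, n_epochs=8, epoch_s=2.0)
        highs = sine_epochs(8.0, n_epochs=8, epoch_s=2.0)
        es = EpochSet(np.concatenate([lows.epochs, highs.epochs]), lows.fs, ["ch0"])
        # population SD of eight 6s and eight 8s
        assert peak_frequency_variability(es) == pytest.approx(1.0, abs=1e-12)

    def test_stationary_subject_low_variability(self):
        from qeeg.preprocess import extract_epochs, split_epochs
        from qeeg.synthetic import SubjectSpec, generate_subject

        spec = SubjectSpec(
            dominant_freq=7.0,
            band_fractions={"delta": 0.2, "theta": 0.5, "alpha1": 0.1,
                            "alpha2": 0.1, "beta": 0.05, "gamma": 0.05},
            noise_sd=0.2, n_channels=2, seed=3)
        rec = generate_subject(spec)
        pieces = split_epochs(extract_epochs(rec))
        assert peak_frequency_variability(pieces) < 1.0

    def test_single_sub_epoch_rejected(self):
        es = sine_epochs(7.0, n_epochs=1, epoch_s=2.0)
        with pytest.raises(ValueError, match="sub-epochs"):
            peak_frequency_variability(es)


class TestThetaAlphaRatio:
    @pytest.mark.parametrize("theta, a1, a2, expected", [
        (0.18, 0.15, 0.09, 0.18 / 0.42),   # ~0.429, the conventional slowing index
        (0.0, 0.2, 0.1, 0.0),
        (0.3, 0.2, 0.1, 0.5),
    ])
    def test_formula(self, theta, a1, a2, expected):
        rel = {"theta": np.array([theta]), "alpha1": np.array([a1]),
               "alpha2": np.array([a2])}
        assert theta_alpha_ratio(rel) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_rejected(self):
        rel = {"theta": np.array([0.0]), "alpha1": np.array([0.0]),
               "alpha2": np.array([0.0])}
        with pytest.raises(ValueError):
            theta_alpha_ratio(rel)

    def test_monotone_in_generated_theta_fraction(self):
        """Raising the generator's theta share (others rescaled) strictly
        raises the measured theta/alpha ratio (averaged over seeds)."""
        from qeeg.preprocess import extract_epochs
        from qeeg.spectral import power_spectrum, relative_band_power
        from qeeg.synthetic import SubjectSpec, generate_subject

        base = {"delta": 0.3, "theta": 0.2, "alpha1": 0.2, "alpha2": 0.1,
                "beta": 0.1, "gamma": 0.1}
        ratios = []
        for theta in (0.1, 0.2, 0.3, 0.4, 0.5):
            rest = 1.0 - theta
            scale = rest / (1.0 - 0.2)
            fr = {k: (theta if k == "theta" else v * scale) for k, v in base.items()}
            vals = []
            for seed in range(3):
                spec = SubjectSpec(dominant_freq=6.5, band_fractions=fr,
                                   noise_sd=0.05, n_channels=2, seed=seed)
                es = extract_epochs(generate_subject(spec))
                vals.append(theta_alpha_ratio(relative_band_power(power_spectrum(es))))
            ratios.append(np.mean(vals))
        assert all(a < b for a, b in zip(ratios, ratios[1:])), ratios
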