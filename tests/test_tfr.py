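"""Morlet wavelet family, convolution, dB normalization, bands, metrics."""

import numpy as np
import pandas as pd
import pytest

from ictalab import tfr
from ictalab.signal_io import Recording
from ictalab.tfr import (BANDS, TFRStack, aggregate, band_power,
                         baseline_power, build_wavelet_family, eeg_metrics,
                         epoch_trials, extract_power, power_db, tfr_stack,
                         wavelet_kernels, wavelet_transform)


@pytest.fixture(scope="module")
def family():
    return build_wavelet_family(1.0, 200.0, 200, 1.0, 30.0, fs=1000.0)


class TestWaveletFamily:
    def test_sigma_formula_exact_for_all_bins(self, family):
        np.testing.assert_array_equal(
            family.sigmas, family.cycles / (2 * np.pi * family.freqs))

    def test_axis_endpoints(self, family):
        assert family.freqs[0] == 1.0 and family.freqs[-1] == 200.0
        assert family.cycles[0] == 1.0 and family.cycles[-1] == 30.0
        assert family.freqs.size == 200

    def test_sigma_closed_forms(self):
        fam = build_wavelet_family(1 / (2 * np.pi), 200.0, 2, 1.0, 30.0,
                                   fs=1000.0)
        assert fam.sigmas[0] == pytest.approx(1.0)       # n=1, f=1/2pi
        assert fam.sigmas[-1] == pytest.approx(30 / (400 * np.pi))

    def test_kernel_length_odd_and_covers_support(self, family):
        assert family.kernel_length % 2 == 1
        assert family.kernel_length >= 6 * family.sigmas.max() * family.fs - 1

    def test_fmax_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            build_wavelet_family(1.0, 500.0, 10, fs=1000.0)


class TestWaveletTransform:
    def test_fft_matches_direct_convolution(self, family):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        kernels = wavelet_kernels(family)
        W = wavelet_transform(x, family)
        pad = int(np.ceil(3 * family.sigmas.max() * family.fs))
        xp = np.pad(x, pad, mode="reflect")
        for fi in (0, 40, 99, 150, 199):
            direct = np.convolve(xp, kernels[fi], mode="same")[pad: pad + x.size]
            err = np.max(np.abs(direct - W[fi])) / np.max(np.abs(direct))
            assert err <= 1e-6

    @pytest.mark.parametrize("f0", [5.0, 10.0, 40.0, 120.0])
    def test_tone_peaks_at_nearest_bin(self, family, f0):
        t = np.arange(4000) / 1000.0
        W = wavelet_transform(np.cos(2 * np.pi * f0 * t), family)
        profile = np.abs(W[:, 1000:3000]).mean(axis=1)
        nearest = np.argmin(np.abs(family.freqs - f0))
        assert np.argmax(profile) == nearest
        assert profile[nearest] == pytest.approx(1.0, rel=0.05)

    def test_linearity_in_amplitude(self, family):
        rng = np.random.default_rng(4)
        x = rng.normal(size=3000)
        W1 = wavelet_transform(x, family)
        W2 = wavelet_transform(3.5 * x, family)
        np.testing.assert_allclose(np.abs(W2), 3.5 * np.abs(W1), rtol=1e-9)

    def test_signal_shorter_than_kernel_rejected(self, family):
        with pytest.raises(ValueError):
            wavelet_transform(np.zeros(100), family)

    def test_white_noise_power_tracks_kernel_energy(self):
        # Parseval-style: time-averaged |W|^2 of white noise is
        # proportional to each kernel's spectral energy
        fam = build_wavelet_family(2.0, 80.0, 25, 2.0, 12.0, fs=1000.0)
        rng = np.random.default_rng(11)
        x = rng.normal(size=200_000)
        W = wavelet_transform(x, fam)
        mean_sq = (np.abs(W) ** 2).mean(axis=1)
        kernels = wavelet_kernels(fam)
        energy = (np.abs(np.fft.fft(kernels, 8192, axis=1)) ** 2).mean(axis=1)
        ratio = mean_sq / energy
        assert ratio.std() / ratio.mean() < 0.10


class TestPower:
    def test_magnitude_and_squared(self):
        W = np.array([[3 + 4j, 0.0]])
        np.testing.assert_allclose(extract_power(W), [[5.0, 0.0]])
        np.testing.assert_allclose(extract_power(W, "squared"), [[25.0, 0.0]])

    def test_unknown_units_rejected(self):
        with pytest.raises(ValueError):
            extract_power(np.zeros(3), "amps")

    def test_db_identities(self):
        ref = np.array([2.0, 4.0])
        P = np.column_stack([ref, 10 * ref, ref / 10]).T
        db = power_db(P.T, ref)
        np.testing.assert_allclose(db[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(db[:, 1], 10.0, atol=1e-12)
        np.testing.assert_allclose(db[:, 2], -10.0, atol=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            power_db(np.ones((2, 3)), np.array([1.0, 0.0]))


@pytest.fixture(scope="module")
def noise_rec():
    rng = np.random.default_rng(8)
    return Recording(rng.normal(0, 20, size=(1, 1_300_000)), 1000.0, ["ch0"])


@pytest.fixture(scope="module")
def small_family():
    return build_wavelet_family(2.0, 60.0, 20, 2.0, 10.0, fs=1000.0)


@pytest.fixture(scope="module")
def epoch_rec():
    rng = np.random.default_rng(2)
    return Recording(rng.normal(size=(1, 200_000)), 1000.0, ["ch0"])


class TestBaselinePower:
    def test_stationarity_between_disjoint_intervals(self, noise_rec,
                                                     small_family):
        r1 = baseline_power(noise_rec, (0.0, 600.0), small_family, "ch0")
        r2 = baseline_power(noise_rec, (650.0, 1250.0), small_family, "ch0")
        np.testing.assert_allclose(r1, r2, rtol=0.10)

    def test_doubling_amplitude_doubles_reference(self, noise_rec,
                                                  small_family):
        doubled = noise_rec.copy()
        doubled.samples *= 2
        r1 = baseline_power(noise_rec, (0.0, 60.0), small_family, "ch0")
        r2 = baseline_power(doubled, (0.0, 60.0), small_family, "ch0")
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-9)

    def test_baseline_interval_self_normalizes(self, noise_rec, small_family):
        # dB of the (time-averaged) baseline power against a reference
        # from a disjoint interval of the same stationary process
        ref = baseline_power(noise_rec, (0.0, 600.0), small_family, "ch0")
        other = baseline_power(noise_rec, (650.0, 1250.0), small_family, "ch0")
        db = 10 * np.log10(other / ref)
        assert np.max(np.abs(db)) <= 0.5

    def test_too_short_interval_rejected(self, noise_rec, small_family):
        with pytest.raises(ValueError):
            baseline_power(noise_rec, (0.0, 1.0), small_family, "ch0")


class TestEpoching:
    def test_window_contract(self, epoch_rec):
        rec = epoch_rec
        trials, times, kept = epoch_trials(rec, [(100.0, 120.0)], (-5, 40),
                                           "ch0")
        assert trials.shape == (1, 45_001)
        assert times[0] == -5.0 and times[-1] == pytest.approx(40.0)

    def test_out_of_bounds_trial_dropped(self, epoch_rec):
        rec = epoch_rec
        trials, _, kept = epoch_trials(rec, [(2.0, 10.0), (100.0, 120.0)],
                                       (-5, 40), "ch0")
        assert len(kept) == 1 and trials.shape[0] == 1

    def test_all_dropped_raises(self, epoch_rec):
        rec = epoch_rec
        with pytest.raises(ValueError):
            epoch_trials(rec, [(1.0, 2.0)], (-5, 40), "ch0")

    def test_no_events_raises(self, epoch_rec):
        rec = epoch_rec
        with pytest.raises(ValueError):
            epoch_trials(rec, [], (-5, 40), "ch0")

    def test_trial_count(self, epoch_rec):
        rec = epoch_rec
        trials, _, _ = epoch_trials(
            rec, [(50.0, 60.0), (100.0, 110.0), (150.0, 160.0)], (-5, 30),
            "ch0")
        assert trials.shape[0] == 3


class TestBandPower:
    def _flat_stack(self, value_db=7.0):
        freqs = np.linspace(1, 200, 50)
        ref = np.ones(50)
        power = np.full((2, 50, 100), 10 ** (value_db / 10))
        times = np.linspace(-5, 40, 100)
        return TFRStack(power, times, freqs, "magnitude", baseline_ref=ref)

    def test_flat_db_returns_constant_for_every_band(self):
        stack = self._flat_stack(7.0)
        for band in BANDS.values():
            _, scalars = band_power(stack, band)
            np.testing.assert_allclose(scalars, 7.0, atol=1e-9)

    def test_theta_tone_beats_delta(self):
        fam = build_wavelet_family(1.0, 40.0, 40, 2.0, 8.0, fs=1000.0)
        rng = np.random.default_rng(9)
        x = rng.normal(0, 5, size=120_000)
        t = np.arange(30_000) / 1000.0
        x[60_000:90_000] += 40 * np.sin(2 * np.pi * 6 * t)
        rec = Recording(x[None, :], 1000.0, ["ch0"])
        ref = baseline_power(rec, (0.0, 50.0), fam, "ch0")
        stack = tfr_stack(rec, [(60.0, 90.0)], fam, (-5, 30), "ch0",
                          baseline_ref=ref)
        _, theta = band_power(stack, BANDS["theta"])
        _, delta = band_power(stack, BANDS["delta"])
        assert theta[0] > delta[0]

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_power(self._flat_stack(), (0.1, 0.5))

    def test_scalar_uses_post_onset_only(self):
        stack = self._flat_stack(0.0)
        # +10 dB only before onset must not move the scalar
        stack.power[:, :, stack.times < 0] *= 10
        _, scalars = band_power(stack, (1, 200))
        np.testing.assert_allclose(scalars, 0.0, atol=1e-9)


class TestAggregate:
    def _table(self):
        return pd.DataFrame({
            "animal_id": ["a", "a", "b", "b"],
            "group": ["g1", "g1", "g1", "g1"],
            "value": [1.0, 3.0, 5.0, 9.0],
        })

    def test_per_seizure_keeps_rows(self):
        assert len(aggregate(self._table(), "per_seizure")) == 4

    def test_per_animal_averages_trials(self):
        out = aggregate(self._table(), "per_animal")
        assert out.set_index("animal_id")["value"].to_dict() == \
               {"a": 2.0, "b": 7.0}

    def test_single_trial_identical_under_both_modes(self):
        df = self._table().iloc[:1]
        a = aggregate(df, "per_seizure")["value"].tolist()
        b = aggregate(df, "per_animal")["value"].tolist()
        assert a == b

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self._table(), "per_slice")


class TestEEGMetrics:
    def test_unit_sine_closed_forms(self):
        fs = 1000.0
        t = np.arange(10_000) / fs
        m = eeg_metrics(np.sin(2 * np.pi * 8 * t), fs)
        assert m["zero_crossing_rate"] == pytest.approx(16.0, abs=1.0)
        assert m["rms"] == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_gaussian_noise_moments(self):
        x = np.random.default_rng(12).normal(size=100_000)
        m = eeg_metrics(x, 1000.0)
        assert abs(m["kurtosis"]) < 0.2
        assert abs(m["skewness"]) < 0.1

    def test_constant_segment_flags(self):
        m = eeg_metrics(np.full(2000, 4.0), 1000.0)
        assert m["sd"] == 0.0 and m["rms"] == 4.0
        assert m["zero_crossing_rate"] == 0.0
        assert np.isnan(m["kurtosis"]) and np.isnan(m["skewness"])
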