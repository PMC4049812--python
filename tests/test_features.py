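"""Feature oracles: energies, wavelet bands, spectra, moments, dynamics."""

import numpy as np
import pytest

from asppr import (FeatureConfig, SynthConfig, accumulated_energy,
                   correlation_dimension, dwt_band_energies,
                   extract_feature_matrix, generate_record, max_lyapunov,
                   moments, signal_energy, spectral_band_power,
                   spectral_edge_frequency)
from asppr.eeg_io import EEGRecord
from asppr.exceptions import ConfigurationError, ValidationError, WindowError
from asppr.features import dwt_subband_signals

FS = 256.0


def sine(freq, n, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestSignalEnergy:
    @pytest.mark.parametrize("x,w,expected", [
        (np.full(100, 2.0), 100, 4.0),
        (np.array([1.0, 2.0, 3.0]), 3, 14.0 / 3.0),
        (np.zeros(50), 50, 0.0),
    ])
    def test_values(self, x, w, expected):
        assert signal_energy(x, w) == pytest.approx(expected)

    def test_wrong_window_length(self):
        with pytest.raises(WindowError):
            signal_energy(np.ones(10), 20)


class TestAccumulatedEnergy:
    @pytest.mark.parametrize("e,offset,expected", [
        ([1, 1, 1], 0.0, [1, 2, 3]),
        ([2, 3, 5], 0.0, [2, 5, 10]),
        ([1, 1], 10.0, [11, 12]),
    ])
    def test_values(self, e, offset, expected):
        np.testing.assert_allclose(accumulated_energy(e, offset), expected)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValidationError):
            accumulated_energy([1.0, -0.5])

    def test_non_decreasing(self):
        rng = np.random.default_rng(0)
        ae = accumulated_energy(rng.random(100), 3.0)
        assert np.all(np.diff(ae) >= 0)


class TestDWT:
    def test_dc_signal_energy_in_approximation(self):
        x = np.full(2304, 3.0)
        e = dwt_band_energies(x, FS, "ste")
        dc_energy = 9.0
        assert e[0] == pytest.approx(dc_energy, rel=1e-9)
        assert np.all(e[1:] <= 1e-9 * dc_energy)

    def test_sinusoid_lands_in_dyadic_band(self):
        # 20 Hz lies in the level-4 dyadic sub-band D3 (16-32 Hz), the
        # second of the four reported bands (A4+D4, D3, D2, D1)
        x = sine(20.0, 2304)
        e = dwt_band_energies(x, FS, "ste")
        assert e[1] / e.sum() >= 0.80

    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2304)
        bands = dwt_subband_signals(x)
        np.testing.assert_allclose(np.sum(bands, axis=0), x, rtol=0,
                                   atol=1e-6 * np.std(x))

    def test_window_too_short(self):
        with pytest.raises(WindowError):
            dwt_band_energies(np.ones(32), FS, "ste")


class TestSpectralBandPower:
    def test_pure_tone_concentrated(self):
        x = sine(10.0, 2304)
        p_alpha = spectral_band_power(x, FS, (8.0, 13.0))
        total = spectral_band_power(x, FS, (0.0, FS / 2))
        assert p_alpha / total >= 0.95

    def test_white_noise_flat_spectrum_ratio(self):
        # flat PSD: trial-averaged power(4-8) / power(8-13) = 4/5
        rng = np.random.default_rng(11)
        lo = [spectral_band_power(x, FS, (4.0, 8.0))
              for x in rng.normal(size=(100, 2304))]
        hi = [spectral_band_power(x, FS, (8.0, 13.0))
              for x in rng.normal(size=(100, 2304))]
        assert np.mean(lo) / np.mean(hi) == pytest.approx(4.0 / 5.0, rel=0.10)

    def test_zero_signal(self):
        assert spectral_band_power(np.zeros(2304), FS, (4.0, 8.0)) == 0.0

    def test_band_outside_nyquist(self):
        with pytest.raises(ValidationError):
            spectral_band_power(np.ones(256), FS, (100.0, 200.0))


class TestSpectralEdgeFrequency:
    def test_pure_tone_median_frequency(self):
        x = sine(10.0, 2304)
        df = FS / 2304
        assert spectral_edge_frequency(x, FS, 50) == pytest.approx(10.0, abs=2 * df)

    def test_white_noise_closed_form(self):
        # flat spectrum from 0.5 Hz to Nyquist: SEF-90 = 0.5 + 0.9*127.5
        rng = np.random.default_rng(12)
        est = np.mean([spectral_edge_frequency(x, FS, 90)
                       for x in rng.normal(size=(100, 2304))])
        assert est == pytest.approx(115.25, abs=2.0)

    def test_two_tone_median_between(self):
        x = sine(5.0, 2304) + sine(15.0, 2304, phase=1.0)
        assert 5.0 <= spectral_edge_frequency(x, FS, 50) <= 15.0

    def test_zero_signal_flagged(self):
        value, flag = spectral_edge_frequency(np.zeros(2304), FS, 90,
                                              return_flag=True)
        assert value == 0.5 and flag


class TestMoments:
    def test_simple_mean(self):
        mean, _, _ = moments(np.array([1.0, 2.0, 3.0]))
        assert mean == pytest.approx(2.0)

    def test_gaussian_symmetry(self):
        rng = np.random.default_rng(2)
        _, skew, kurt = moments(rng.normal(size=46080))
        assert abs(skew) < 0.05
        assert kurt == pytest.approx(3.0, abs=0.15)

    def test_constant_window_flagged(self):
        mean, skew, kurt, flag = moments(np.full(100, 7.0), return_flag=True)
        assert (mean, skew, kurt, flag) == (7.0, 0.0, 0.0, True)


class TestMaxLyapunov:
    def test_logistic_map_ln2(self):
        # r=4 logistic map has lambda = ln 2; oracle: mean log |f'| over orbit
        x = np.empty(1280)
        x[0] = 0.3
        for i in range(1279):
            x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
        oracle = np.mean(np.log(np.abs(4.0 - 8.0 * x)))
        assert oracle == pytest.approx(np.log(2.0), abs=0.02)
        est = max_lyapunov(x, embed_dim=2, delay=1, theiler=5, fit_steps=5)
        assert est == pytest.approx(np.log(2.0), abs=0.15)

    def test_sinusoid_non_chaotic(self):
        assert max_lyapunov(sine(10.0, 1280)) <= 0.05

    def test_noise_exceeds_sinusoid(self):
        s = max_lyapunov(sine(10.0, 1280))
        wins = 0
        for seed in range(20):
            n = np.random.default_rng(seed).normal(size=1280)
            wins += max_lyapunov(n) > s
        assert wins == 20

    def test_window_too_short(self):
        with pytest.raises(WindowError):
            max_lyapunov(np.ones(40))


class TestCorrelationDimension:
    @staticmethod
    def brute_force_slope(x, embed_dim, delay, radii, theiler):
        """Independent pair-count oracle: explicit O(n^2) loop in float64."""
        pts = np.array([x[i:i + (embed_dim - 1) * delay + 1:delay]
                        for i in range(len(x) - (embed_dim - 1) * delay)])
        n = len(pts)
        dists = []
        for i in range(n):
            for j in range(i + theiler + 1, n):
                dists.append(np.sqrt(np.sum((pts[i] - pts[j]) ** 2)))
        dists = np.array(dists)
        c = np.array([np.mean(dists < r) for r in radii])
        ok = (c * len(dists) >= 10) & (c < 1)
        return float(np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0])

    def test_sinusoid_one_dimensional(self):
        x = sine(10.0, 1280)
        radii = np.std(x) * np.logspace(-1.5, -0.3, 10)
        est = correlation_dimension(x, embed_dim=3, delay=6, radii=radii)
        assert est == pytest.approx(1.0, abs=0.3)

    def test_matches_brute_force_oracle(self):
        x = sine(10.0, 400)
        radii = np.std(x) * np.logspace(-1.2, -0.3, 8)
        est = correlation_dimension(x, embed_dim=3, delay=6, radii=radii,
                                    theiler=20)
        oracle = self.brute_force_slope(x, 3, 6, radii, 20)
        assert est == pytest.approx(oracle, abs=1e-3)

    def test_quasiperiodic_torus_two_dimensional(self):
        t = np.arange(2560) / FS
        x = (np.sin(2 * np.pi * 10 * t)
             + np.sin(2 * np.pi * 10 * np.sqrt(2) * t))
        radii = np.std(x) * np.logspace(-1.2, -0.2, 10)
        est = correlation_dimension(x, embed_dim=5, delay=6, radii=radii)
        assert est == pytest.approx(2.0, abs=0.4)

    def test_constant_window_flagged(self):
        est, flag = correlation_dimension(np.ones(1280), return_flag=True)
        assert est == 0.0 and flag


class TestExtractFeatureMatrix:
    @pytest.fixture(scope="class")
    def small_extraction(self):
        cfg = SynthConfig(duration_s=400.0, seizure_onset_s=200.0,
                          seizure_offset_s=260.0, seed=17)
        record, ann = generate_record(cfg)
        return record, ann, extract_feature_matrix(record, ann, seed=17)

    def test_tick_count_and_columns(self, small_extraction):
        _, _, m = small_extraction
        assert m.values.shape == (80, 204)
        assert m.timestamps[0] == 5.0 and m.timestamps[-1] == 400.0

    def test_short_record_two_ticks(self):
        rng = np.random.default_rng(0)
        rec = EEGRecord(samples=rng.normal(size=(6, 2560)), fs=FS)
        m = extract_feature_matrix(rec)
        assert m.n_instances == 2

    def test_channel_count_enforced(self):
        rec = EEGRecord(samples=np.random.default_rng(0).normal(size=(5, 2560)),
                        fs=FS)
        with pytest.raises(ConfigurationError):
            extract_feature_matrix(rec)
        m = extract_feature_matrix(rec, allow_channel_mismatch=True)
        assert m.n_features == 5 * 34

    def test_no_missing_values_anywhere(self, small_extraction):
        _, _, m = small_extraction
        assert np.isfinite(m.values).all()

    def test_accumulated_energy_non_decreasing(self, small_extraction):
        _, _, m = small_extraction
        for ch in range(6):
            col = m.column_names.index(f"ch{ch + 1}__ae")
            assert np.all(np.diff(m.values[:, col]) >= 0)

    def test_windowed_features_local_to_their_windows(self, small_extraction):
        """Perturbing data outside a tick's windows leaves that tick's
        windowed features unchanged (accumulated energy excepted: it is a
        running sum over the whole file by construction)."""
        record, ann, m = small_extraction
        perturbed = record.samples.copy()
        rng = np.random.default_rng(99)
        fs = int(FS)
        # tick at t=300 s uses at most [120 s, 300 s); perturb outside
        perturbed[:, :110 * fs] += rng.normal(size=(6, 110 * fs))
        perturbed[:, 310 * fs:] += rng.normal(
            size=(6, perturbed.shape[1] - 310 * fs))
        m2 = extract_feature_matrix(
            EEGRecord(samples=perturbed, fs=FS,
                      channel_names=record.channel_names), ann, seed=17)
        row = np.flatnonzero(m.timestamps == 300.0)[0]
        keep = [i for i, name in enumerate(m.column_names)
                if not name.endswith("__ae")]
        np.testing.assert_allclose(m2.values[row, keep], m.values[row, keep],
                                   rtol=1e-9, atol=1e-12)

    def test_determinism_under_seed(self, small_extraction):
        record, ann, m = small_extraction
        m2 = extract_feature_matrix(record, ann, seed=17)
        np.testing.assert_array_equal(m.values, m2.values)
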