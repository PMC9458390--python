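"""Feature blocks: WP band energies, statistics, entropies, MFCCs."""

import numpy as np
import pytest

import korosound as ks
from korosound.features import (BandEnergies, BeatFeatureSeries, FEATURE_NAMES,
                                mel_filterbank, mfcc_frame)

RATE = 800.0


def fft_band_energies(signal, rate=RATE):
    """Independent FFT oracle for the eight 50 Hz band energies."""
    spectrum = np.abs(np.fft.rfft(signal)) ** 2
    freqs = np.fft.rfftfreq(len(signal), 1 / rate)
    return np.array([np.sum(spectrum[(freqs >= lo) & (freqs < hi)])
                     for lo, hi in ks.BAND_EDGES])


def _tone(freq, seconds=2.0, rate=RATE):
    t = np.arange(0, seconds, 1 / rate)
    return np.sin(2 * np.pi * freq * t)


class TestWaveletPacketBands:
    def test_zero_signal(self):
        bands = ks.wp_band_energies(np.zeros(800))
        assert np.all(bands.node_energies == 0)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096)
        bands = ks.wp_band_energies(x)
        total = np.sum(x ** 2)
        assert abs(np.sum(bands.node_energies) - total) / total < 1e-6

    def test_tone_lands_in_its_band(self):
        bands = ks.wp_band_energies(_tone(75.0))
        share = bands.node_energies[1] / bands.node_energies.sum()
        assert share >= 0.6  # leakage into neighbours is wavelet-dependent

    def test_white_noise_spreads_evenly(self):
        rng = np.random.default_rng(1)
        bands = ks.wp_band_energies(rng.standard_normal(8000))
        shares = bands.node_energies / bands.node_energies.sum()
        assert np.all(shares < 3 / 8) and np.all(shares > 1 / 24)

    def test_wp_agrees_with_fft_oracle(self):
        # band-limited fixtures: WP and FFT band shares within 10 points
        for freq in (75.0, 175.0, 325.0):
            x = _tone(freq)
            wp_shares = ks.wp_band_energies(x).node_energies
            wp_shares = wp_shares / wp_shares.sum()
            fft_shares = fft_band_energies(x)
            fft_shares = fft_shares / fft_shares.sum()
            assert np.max(np.abs(wp_shares - fft_shares)) <= 0.10

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            ks.wp_band_energies(np.zeros(100), "not-a-wavelet")
        with pytest.raises(ValueError, match="too short"):
            ks.wp_band_energies(np.zeros(4))


class TestBandRatios:
    def test_equal_band_energies(self):
        bands = BandEnergies(node_energies=np.array([0.0] + [2.0] * 7))
        np.testing.assert_allclose(ks.global_band_ratios(bands), np.full(7, 1 / 7))

    def test_single_band(self):
        e = np.zeros(8)
        e[3] = 5.0  # 150-200 Hz
        ratios = ks.global_band_ratios(BandEnergies(node_energies=e))
        np.testing.assert_allclose(ratios, np.eye(7)[2])

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="zero energy"):
            ks.global_band_ratios(BandEnergies(node_energies=np.zeros(8)))

    def test_ratios_sum_to_one(self):
        rng = np.random.default_rng(2)
        bands = ks.wp_band_energies(rng.standard_normal(2048))
        assert np.sum(ks.global_band_ratios(bands)) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("freq,low_dominant", [(75.0, True), (300.0, False)])
    def test_beat_ratio_follows_tone_band(self, freq, low_dominant):
        en, en_h, _ = ks.beat_band_ratios(_tone(freq, seconds=0.4))
        if low_dominant:
            assert en >= 0.6 and en_h <= 0.1
        else:
            assert en_h >= 0.6 and en <= 0.1

    def test_partition_identity(self):
        rng = np.random.default_rng(3)
        beat = rng.standard_normal(320)
        en, en_h, Et = ks.beat_band_ratios(beat)
        bands = ks.wp_band_energies(beat)
        mid = bands.node_energies[2] / Et
        assert en + mid + en_h == pytest.approx(1.0, abs=1e-9)


class TestVariability:
    def test_constant_series(self):
        np.testing.assert_allclose(ks.variability_series(np.full(5, 3.0)), np.ones(5))

    def test_two_values(self):
        np.testing.assert_allclose(ks.variability_series(np.array([2.0, 4.0])),
                                   [2 / 3, 4 / 3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks.variability_series(np.array([]))

    def test_mean_is_one(self):
        rng = np.random.default_rng(4)
        v = ks.variability_series(rng.uniform(0.5, 2.0, 40))
        assert np.mean(v) == pytest.approx(1.0, abs=1e-9)


class TestEnergyBlock:
    def _bands(self):
        return BandEnergies(node_energies=np.array([0.0] + [1.0] * 7))

    def test_regular_train_degenerates(self):
        series = BeatFeatureSeries(en=np.full(5, 0.6), en_h=np.full(5, 0.2),
                                   Et=np.full(5, 2.0), Ti=np.full(4, 0.8))
        block = ks.energy_feature_block(series, self._bands())
        assert block["std_enr"] == block["std_Ep"] == block["std_TM"] == 0.0
        assert block["TM_max"] == block["TM_min"] == pytest.approx(100.0)

    def test_ep_extrema_arithmetic(self):
        series = BeatFeatureSeries(en=np.array([0.5, 0.5]), en_h=np.array([0.2, 0.2]),
                                   Et=np.array([1.0, 3.0]), Ti=np.array([0.8]))
        block = ks.energy_feature_block(series, self._bands())
        assert block["Ep_max"] == pytest.approx(150.0)
        assert block["Ep_min"] == pytest.approx(50.0)

    def test_single_beat_rejected(self):
        series = BeatFeatureSeries(en=np.array([0.5]), en_h=np.array([0.2]),
                                   Et=np.array([1.0]), Ti=np.empty(0))
        with pytest.raises(ValueError, match="insufficient beats"):
            ks.energy_feature_block(series, self._bands())

    def test_interval_spread_is_recovered(self):
        # records programmed with 15 % beat-period spread must yield
        # std_TM near 15 through the full pipeline (anchor quantization
        # adds ~20 ms of measurement noise)
        spec = ks.SyntheticSpec(mean_period=0.8, period_jitter_sd=0.12,
                                artifact_rate=0.0)
        values = []
        for seed in range(40):
            record, _ = ks.generate_record(spec, seed)
            fv = ks.extract_features(record)
            values.append(fv.values["std_TM"])
        assert abs(np.mean(values) - 15.0) <= 3.0


class TestStatisticalFeatures:
    def test_constant_signal_degenerates(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stats = ks.statistical_features(np.full(100, 0.5), RATE)
        assert stats["std"] == stats["mean_abs_dev"] == stats["iqr"] == 0.0
        assert stats["skewness"] == stats["kurtosis"] == 0.0

    def test_pure_tone_dominant_frequency(self):
        x = _tone(100.0, seconds=4.0)
        stats = ks.statistical_features(x, RATE)
        assert abs(stats["dom_freq"] - 100.0) <= 0.25  # one bin at 4 s
        assert stats["dom_freq_ratio"] >= 0.9

    def test_gaussian_moments(self):
        rng = np.random.default_rng(5)
        stats = ks.statistical_features(rng.standard_normal(100_000), RATE)
        assert abs(stats["skewness"]) <= 0.05
        assert abs(stats["kurtosis"] - 3.0) <= 0.1  # Pearson convention


class TestEntropyFeatures:
    def test_uniform_histogram_maximal(self):
        x = np.linspace(0.0, 1.0, 128 * 10)  # exactly 10 samples per bin
        h_signal, _ = ks.entropy_features(x, RATE, bins=128)
        assert h_signal == pytest.approx(np.log2(128), abs=1e-9)

    def test_single_bin_zero(self):
        h_signal, _ = ks.entropy_features(np.full(256, 0.3), RATE, bins=128)
        assert h_signal == 0.0

    def test_tone_more_ordered_than_noise(self):
        rng = np.random.default_rng(6)
        _, h_tone = ks.entropy_features(_tone(120.0), RATE)
        _, h_noise = ks.entropy_features(rng.standard_normal(1600), RATE)
        assert h_tone < h_noise


class TestMFCC:
    def test_length_is_13(self):
        rng = np.random.default_rng(7)
        coeffs = ks.mfcc_features(rng.standard_normal(1600), RATE)
        assert coeffs.shape == (13,)

    def test_gain_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(1600)
        a = ks.mfcc_features(x, RATE)
        b = ks.mfcc_features(7.3 * x, RATE)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_filter_count_must_cover_dct_order(self):
        with pytest.raises(ValueError, match="DCT order"):
            ks.mfcc_features(np.ones(1600), RATE, n_filters=10)

    def test_matches_brute_force_oracle(self):
        # independent double-loop evaluation of the log-filterbank DCT on a
        # fixed 32-sample frame
        rng = np.random.default_rng(9)
        frame = rng.standard_normal(32)
        M, nfft = 26, 256
        fb = mel_filterbank(M, nfft, RATE)
        got = mfcc_frame(frame, fb, nfft)

        power = np.abs(np.fft.rfft(frame, n=nfft)) ** 2
        # oracle filterbank from the documented triangle construction
        mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
        imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
        pts = imel(np.linspace(mel(0.0), mel(400.0), M + 2))
        freqs = np.arange(nfft // 2 + 1) * RATE / nfft
        log_e = np.zeros(M)
        energies = np.zeros(M)
        for m in range(1, M + 1):
            acc = 0.0
            for k, f in enumerate(freqs):
                if pts[m - 1] <= f <= pts[m]:
                    w = (f - pts[m - 1]) / (pts[m] - pts[m - 1])
                elif pts[m] < f <= pts[m + 1]:
                    w = (pts[m + 1] - f) / (pts[m + 1] - pts[m])
                else:
                    w = 0.0
                acc += w * power[k]
            energies[m - 1] = acc
        floor = 1e-10 * energies.max()
        for m in range(M):
            log_e[m] = np.log(max(energies[m], floor))
        expected = np.zeros(13)
        for n1 in range(1, 14):
            s = 0.0
            for m in range(1, M + 1):
                s += log_e[m - 1] * np.cos((m - 0.5) / M * n1 * np.pi)
            expected[n1 - 1] = s
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestExtractFeatures:
    def test_full_vector_contract(self, healthy_record, config):
        record, _ = healthy_record
        fv = ks.extract_features(record, config)
        assert list(fv.values) == FEATURE_NAMES
        assert np.all(np.isfinite(fv.array("C")))
        assert fv.array("A").size == 33
        assert fv.array("B").size == 27
        assert fv.array("C").size == 46

    def test_gain_invariance_of_full_vector(self, healthy_record, config):
        record, _ = healthy_record
        scaled = ks.AudioRecord(0.5 * record.samples, record.rate,
                                source_id=record.source_id)
        a = ks.extract_features(record, config).array("C")
        b = ks.extract_features(scaled, config).array("C")
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-6)

    def test_single_beat_record_rejected(self, config):
        # silence with one damped burst: segmentation finds one anchor only
        rng = np.random.default_rng(10)
        x = 1e-4 * rng.standard_normal(4000)
        t = np.arange(80) / RATE
        x[1600:1680] += np.exp(-t / 0.02) * np.sin(2 * np.pi * 75 * t)
        record = ks.AudioRecord(x, RATE)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="insufficient beats"):
                ks.extract_features(record, config)
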