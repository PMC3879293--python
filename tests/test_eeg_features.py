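"""EEG preprocessing and feature extraction stages."""

import numpy as np
import pytest
from scipy import signal

from evicomb.eeg_features import (TrialSet, butterworth_bandpass, csp_features,
                                  downsample_first_of_k, extract_epoch,
                                  fit_csp_ovr, psd_features, read_trialset,
                                  surface_laplacian, unit_normalize,
                                  write_trialset)
from evicomb.synthetic_data import make_synthetic_trials


def tone_trials(freq_hz, fs=250.0, n_samples=750, n_channels=1, amp=1.0):
    t = np.arange(n_samples) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    trials = np.tile(x, (1, n_channels, 1))
    return TrialSet(trials, fs, np.array([1]))


class TestSurfaceLaplacian:
    NAMES = ("c", "n1", "n2", "n3", "n4")
    MAP = {"c": ("n1", "n2", "n3", "n4")}

    def trialset(self, values):
        trials = np.asarray(values, dtype=float)[None, :, None] * np.ones((1, 1, 4))
        return TrialSet(trials, 250.0, np.array([1]), self.NAMES)

    def test_constant_signal_maps_to_zero(self):
        with pytest.warns(UserWarning, match="pass through"):
            out = surface_laplacian(self.trialset([3, 3, 3, 3, 3]), self.MAP)
        np.testing.assert_allclose(out.trials[0, 0], 0.0)

    def test_center_minus_neighbor_mean(self):
        with pytest.warns(UserWarning):
            out = surface_laplacian(self.trialset([4, 1, 1, 1, 1]), self.MAP)
        np.testing.assert_allclose(out.trials[0, 0], 3.0)
        with pytest.warns(UserWarning):
            out = surface_laplacian(self.trialset([2, 1, 0, -1, 2]), self.MAP)
        np.testing.assert_allclose(out.trials[0, 0], 1.5)

    def test_unmapped_channels_pass_through(self):
        ts = self.trialset([2, 1, 0, -1, 2])
        with pytest.warns(UserWarning):
            out = surface_laplacian(ts, self.MAP)
        np.testing.assert_array_equal(out.trials[0, 1:], ts.trials[0, 1:])

    def test_unknown_neighbor_rejected(self):
        with pytest.raises(ValueError, match="not in the montage"):
            surface_laplacian(self.trialset([0] * 5), {"c": ("n1", "n2", "n3", "zz")})


class TestBandpass:
    def test_passband_tone_preserved(self):
        ts = tone_trials(10.0)
        out = butterworth_bandpass(ts, 5.0, 30.0, order=6)
        mid = slice(100, -100)  # ignore filter edge transients
        ratio = out.trials[0, 0, mid].std() / ts.trials[0, 0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_attenuated(self):
        ts = tone_trials(2.0, n_samples=2500)
        out = butterworth_bandpass(ts, 5.0, 30.0, order=6)
        mid = slice(250, -250)
        ratio = out.trials[0, 0, mid].std() / ts.trials[0, 0, mid].std()
        # oracle: squared magnitude response of the designed filter at 2 Hz
        sos = signal.butter(6, (5.0, 30.0), btype="bandpass", fs=250.0,
                            output="sos")
        _, h = signal.sosfreqz(sos, worN=[2.0], fs=250.0)
        expected = abs(h[0]) ** 2  # forward-backward doubles the attenuation
        assert ratio <= 0.1
        assert ratio == pytest.approx(expected, rel=0.5)

    def test_zero_in_zero_out(self):
        ts = TrialSet(np.zeros((2, 3, 500)), 250.0, np.array([1, 2]))
        out = butterworth_bandpass(ts, 5.0, 30.0)
        np.testing.assert_allclose(out.trials, 0.0)

    def test_invalid_band_rejected(self):
        ts = tone_trials(10.0)
        with pytest.raises(ValueError):
            butterworth_bandpass(ts, 30.0, 5.0)
        with pytest.raises(ValueError):
            butterworth_bandpass(ts, 5.0, 200.0)


class TestEpoch:
    def test_motor_imagery_window_sample_count(self):
        ts = TrialSet(np.random.default_rng(0).normal(size=(2, 3, 1000)),
                      250.0, np.array([1, 2]))
        out = extract_epoch(ts, 0.5, 2.5)
        assert out.n_samples == 500
        np.testing.assert_array_equal(out.trials, ts.trials[:, :, 125:625])

    def test_full_window_is_identity(self):
        ts = TrialSet(np.ones((1, 2, 100)), 100.0, np.array([1]))
        np.testing.assert_array_equal(extract_epoch(ts, 0.0, 1.0).trials, ts.trials)

    def test_zero_or_out_of_range_window_rejected(self):
        ts = TrialSet(np.ones((1, 2, 100)), 100.0, np.array([1]))
        with pytest.raises(ValueError):
            extract_epoch(ts, 0.5, 0.5)
        with pytest.raises(ValueError):
            extract_epoch(ts, 0.5, 2.0)


class TestCSP:
    def two_class_toy(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        trials, labels = [], []
        for c, scales in ((1, (np.sqrt(10), 1.0)), (2, (1.0, np.sqrt(10)))):
            for _ in range(n):
                x = rng.standard_normal((2, 200)) * np.array(scales)[:, None]
                trials.append(x)
                labels.append(c)
        return TrialSet(np.asarray(trials), 250.0, np.asarray(labels))

    def test_diagonal_toy_recovers_axes(self):
        model = fit_csp_ovr(self.two_class_toy(), m=1)
        assert model.n_features == 4
        # class-1 block: last filter maximizes class-1 variance -> axis 1
        w_max = model.filters[1] / np.linalg.norm(model.filters[1])
        assert abs(w_max @ np.array([1.0, 0.0])) > 0.99

    def test_four_class_22_channel_filter_count(self):
        ts, _ = make_synthetic_trials(4, 22, 250.0, 1.0, n_trials_per_class=6,
                                      seed=1)
        model = fit_csp_ovr(ts, m=3)
        assert model.n_features == 24
        assert model.filters.shape == (24, 22)

    def test_identical_distributions_flagged_not_fatal(self):
        rng = np.random.default_rng(2)
        ts = TrialSet(rng.standard_normal((40, 4, 100)), 250.0,
                      np.repeat([1, 2], 20))
        with pytest.warns(UserWarning, match="0.5"):
            model = fit_csp_ovr(ts, m=1)
        for w in model.eigenvalues:
            assert np.all(np.abs(w - 0.5) < 0.2)

    def test_recovers_planted_spatial_pattern(self):
        ts, truth = make_synthetic_trials(
            2, 8, 250.0, 2.0, n_trials_per_class=25, seed=3, noise_std=0.3)
        model = fit_csp_ovr(ts, m=1)
        # generator patterns are orthonormal and the sensor noise white, so
        # the class-1 max-variance filter points along class 1's pattern
        w = model.filters[1] / np.linalg.norm(model.filters[1])
        target = truth["spatial_patterns"][0]
        target = target / np.linalg.norm(target)
        assert abs(w @ target) > 0.95

    def test_scaling_invariance_up_to_sign(self):
        ts = self.two_class_toy()
        m1 = fit_csp_ovr(ts, m=1)
        m2 = fit_csp_ovr(ts.replace_trials(ts.trials * 7.5), m=1)
        for a, b in zip(m1.filters, m2.filters):
            a = a / np.linalg.norm(a)
            b = b / np.linalg.norm(b)
            assert abs(a @ b) == pytest.approx(1.0, abs=1e-6)


class TestCSPFeatures:
    def test_hand_computed_log_variance_ratio(self):
        from evicomb.eeg_features import CSPModel

        model = CSPModel(np.eye(2), (1, 2), m=1)
        trial = np.array([[1.0, -1.0, 1.0, -1.0], [2.0, -2.0, 2.0, -2.0]])
        v = trial.var(axis=1)
        feats = csp_features(model, trial)
        np.testing.assert_allclose(feats, np.log(v / v.sum()), atol=1e-12)

    def test_amplitude_rescaling_invariance(self):
        ts, _ = make_synthetic_trials(2, 6, 250.0, 1.0, n_trials_per_class=10,
                                      seed=4)
        model = fit_csp_ovr(ts, m=1)
        f1 = csp_features(model, ts.trials[0])
        f2 = csp_features(model, ts.trials[0] * 3.0)
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_channel_count_mismatch_rejected(self):
        from evicomb.eeg_features import CSPModel

        model = CSPModel(np.eye(2), (1, 2), m=1)
        with pytest.raises(ValueError):
            csp_features(model, np.zeros((3, 10)))


class TestPSD:
    def test_reference_recipe_dimensionality(self):
        rng = np.random.default_rng(0)
        ts = TrialSet(rng.standard_normal((3, 8, 1024)), 512.0,
                      np.array([1, 2, 3]))
        feats = psd_features(ts, band=(8.0, 30.0), resolution_hz=2.0,
                             window_s=1.0)
        assert feats.shape == (3, 96)

    def test_pure_tone_concentrates_in_nearest_bin(self):
        ts = tone_trials(10.0, fs=512.0, n_samples=1024)
        feats = psd_features(ts)[0]
        assert int(np.argmax(feats)) == 1  # bins at 8, 10, 12, ... Hz
        assert feats[1] / feats.sum() >= 0.8

    def test_zero_signal_gives_zero_features(self):
        ts = TrialSet(np.zeros((1, 2, 600)), 512.0, np.array([1]))
        np.testing.assert_allclose(psd_features(ts), 0.0)

    def test_short_trial_rejected(self):
        ts = TrialSet(np.zeros((1, 2, 100)), 512.0, np.array([1]))
        with pytest.raises(ValueError, match="shorter"):
            psd_features(ts, window_s=1.0)


class TestNormalization:
    def test_three_four_five(self):
        np.testing.assert_allclose(unit_normalize([3.0, 4.0]), [0.6, 0.8])

    def test_random_vectors_have_unit_norm(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = unit_normalize(rng.normal(size=10))
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            unit_normalize(np.zeros(4))

    def test_downsample_first_of_each_eight(self):
        out = downsample_first_of_k(np.arange(16), k=8)
        np.testing.assert_array_equal(out, [0, 8])


def test_trialset_round_trip(tmp_path):
    ts, _ = make_synthetic_trials(2, 3, 100.0, 0.5, n_trials_per_class=2, seed=0)
    write_trialset(ts, tmp_path / "trials")
    back = read_trialset(tmp_path / "trials")
    assert back.fs == ts.fs
    assert back.channel_names == ts.channel_names
    np.testing.assert_array_equal(back.labels, ts.labels)
    np.testing.assert_allclose(back.trials, ts.trials, atol=1e-12)
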