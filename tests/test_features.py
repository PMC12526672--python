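"""Time/frequency features, spectral-moment identities, table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asft.features import (Spectrum, extract_features, features_for_recording,
                           freq_features, segment_features, spectrum,
                           time_features)
from asft.io import FEATURES, Recording
from asft.preprocess import preprocess_recording

FS = 500.0

finite_arrays = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=64,
).map(np.asarray)


class TestTimeFeatures:
    def test_constant_signal(self):
        f = time_features(np.full(10, 3.0))
        assert f["MEA"] == pytest.approx(3.0)
        assert f["ENE"] == pytest.approx(90.0)
        assert f["VAR"] == pytest.approx(0.0)
        assert f["RMS"] == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        f = time_features(np.array([1.0, 2.0, 3.0]))
        assert f["MEA"] == pytest.approx(2.0)
        assert f["ENE"] == pytest.approx(14.0)
        assert f["VAR"] == pytest.approx(2.0 / 3.0)
        assert f["RMS"] == pytest.approx(np.sqrt(14.0 / 3.0))

    @settings(deadline=None, max_examples=50)
    @given(finite_arrays)
    def test_algebraic_identities(self, x):
        f = time_features(x)
        n = len(x)
        assert f["RMS"] ** 2 == pytest.approx(f["ENE"] / n, rel=1e-9, abs=1e-9)
        assert f["VAR"] == pytest.approx(f["RMS"] ** 2 - f["MEA"] ** 2,
                                         rel=1e-6, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_features(np.array([]))

    def test_vectorised_matches_per_row(self, rng):
        X = rng.standard_normal((5, 100))
        batch = time_features(X)
        for i in range(5):
            single = time_features(X[i])
            for name in ("MEA", "ENE", "VAR", "RMS"):
                assert batch[name][i] == pytest.approx(single[name])


class TestSpectrum:
    def test_bin_aligned_tone_concentrates(self):
        n = 1000
        t = np.arange(n) / FS
        spec = spectrum(np.sin(2 * np.pi * 10.0 * t), FS)  # 10 Hz = bin 20
        k = int(np.argmax(spec.power))
        assert spec.freqs[k] == pytest.approx(10.0)
        assert spec.power[k] / spec.power.sum() > 0.99

    def test_zero_input(self):
        spec = spectrum(np.zeros(100), FS)
        assert np.all(spec.power == 0)

    def test_parseval(self, rng):
        x = rng.standard_normal(256)
        spec = spectrum(x, FS)
        # reassemble the two-sided sum from the one-sided |S(k)|²
        two_sided = 2 * spec.power.sum() - spec.power[0] - spec.power[-1]
        assert np.sum(x ** 2) == pytest.approx(two_sided / len(x), rel=1e-9)


class TestFreqFeatures:
    def test_tone_moments(self):
        t = np.arange(1000) / FS
        f = freq_features(spectrum(np.sin(2 * np.pi * 10.0 * t), FS), "alpha")
        assert f["CF"] == pytest.approx(10.0, abs=1e-6)
        assert f["FV"] == pytest.approx(0.0, abs=1e-6)
        assert f["MSF"] == pytest.approx(100.0, abs=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_moment_identity_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        spec = Spectrum(freqs=np.linspace(0, 250, 129),
                        power=rng.uniform(0, 1, 129))
        f = freq_features(spec, "alpha")
        assert f["MSF"] == pytest.approx(f["FV"] + f["CF"] ** 2, rel=1e-9)

    def test_flat_band_centroid_is_mean_bin_frequency(self):
        freqs = np.linspace(0, 250, 501)
        spec = Spectrum(freqs=freqs, power=np.ones_like(freqs))
        mask = spec.band_bins("alpha")
        f = freq_features(spec, "alpha")
        assert f["CF"] == pytest.approx(freqs[mask].mean())
        assert f["PSD"] == pytest.approx(1.0)

    def test_zero_band_power(self, caplog):
        freqs = np.linspace(0, 250, 100)
        spec = Spectrum(freqs=freqs, power=np.zeros_like(freqs))
        f = freq_features(spec, "alpha")
        assert f["PSD"] == 0.0
        assert np.isnan(f["CF"]) and np.isnan(f["FV"]) and np.isnan(f["MSF"])

    def test_psd_averages_over_band_bins(self):
        freqs = np.linspace(0, 250, 251)  # 1 Hz spacing
        power = np.zeros_like(freqs)
        power[9] = 5.0  # 9 Hz, inside alpha [8, 13)
        spec = Spectrum(freqs=freqs, power=power)
        n_bins = spec.band_bins("alpha").sum()
        assert freq_features(spec, "alpha")["PSD"] == pytest.approx(5.0 / n_bins)


class TestScaleCovariance:
    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 100.0))
    def test_feature_scaling_laws(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        base = segment_features(x, FS, "alpha")
        scaled = segment_features(c * x, FS, "alpha")
        assert scaled["MEA"] == pytest.approx(c * base["MEA"], rel=1e-8, abs=1e-12)
        assert scaled["RMS"] == pytest.approx(c * base["RMS"], rel=1e-8)
        for quad in ("ENE", "VAR", "PSD"):
            assert scaled[quad] == pytest.approx(c ** 2 * base[quad], rel=1e-8)
        for inv in ("CF", "FV", "MSF"):
            assert scaled[inv] == pytest.approx(base[inv], rel=1e-8)


class TestExtraction:
    def test_single_channel_single_segment_width(self, rng):
        rec = Recording("S", "pre", "alert", FS, ("O1",),
                        rng.standard_normal((1, 1000)))
        table = extract_features(preprocess_recording(rec), FS,
                                 meta={"subject_id": "S", "session": "pre",
                                       "state": "alert"})
        assert table.X.shape == (1, 32)  # 4 bands × 8 features × 1 channel

    def test_recording_table_shape_and_order(self, tiny_recording):
        table = features_for_recording(tiny_recording)
        assert table.X.shape == (9, 4 * 8 * 4)
        # canonical order: bands outer, features inner, channels innermost
        assert table.keys[0] == ("delta", "MEA", "FP1")
        assert table.keys[1] == ("delta", "MEA", "FP2")
        assert table.keys[4] == ("delta", "ENE", "FP1")

    def test_fast_path_matches_segment_path(self, tiny_recording):
        fast = features_for_recording(tiny_recording)
        slow = extract_features(
            preprocess_recording(tiny_recording), tiny_recording.fs,
            meta={"subject_id": tiny_recording.subject_id,
                  "session": tiny_recording.session,
                  "state": tiny_recording.state})
        assert fast.keys == slow.keys
        np.testing.assert_allclose(fast.X, slow.X, rtol=1e-12)

    def test_deterministic(self, tiny_recording):
        a = features_for_recording(tiny_recording)
        b = features_for_recording(tiny_recording)
        np.testing.assert_array_equal(a.X, b.X)

    def test_msf_identity_on_every_row(self, small_study_table):
        t = small_study_table
        idx = t.key_index()
        for band in ("delta", "theta", "alpha", "beta"):
            for ch in ("FP1", "O2"):
                cf = t.X[:, idx[("%s" % band, "CF", ch)]]
                fv = t.X[:, idx[(band, "FV", ch)]]
                msf = t.X[:, idx[(band, "MSF", ch)]]
                np.testing.assert_allclose(msf, fv + cf ** 2, rtol=1e-9)

    def test_mismatched_grids_rejected(self, tiny_recording):
        segs = preprocess_recording(tiny_recording)
        with pytest.raises(ValueError):
            extract_features(segs[:-1], tiny_recording.fs)
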