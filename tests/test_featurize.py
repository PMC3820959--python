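"""Derived signals, windowing and the 126-feature extraction vs oracles."""

import math

import numpy as np
import pytest

from ethotrack.featurize import (
    DEFAULT_MANIFEST,
    FeatureDataset,
    NormalizationParams,
    Window,
    apply_normalizer,
    cut_windows,
    derive_signals,
    extract_features,
    fit_normalizer,
    load_manifest,
    read_features,
    save_manifest,
    write_features,
)
from ethotrack.sensor_io import (
    BehaviorCategory,
    InertialRecording,
    LabelInterval,
    LabelTrack,
    ValidationError,
)

from conftest import toy_dataset

B = BehaviorCategory
RATE = 100.0


def recording_from(acc, gyro, rate=RATE, **meta):
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    t = np.arange(len(acc)) / rate
    return InertialRecording(t, acc[:, 0], acc[:, 1], acc[:, 2],
                             gyro[:, 0], gyro[:, 1], gyro[:, 2],
                             sample_rate=rate, **meta)


class TestDerivedSignals:
    def test_constant_angular_velocity_has_zero_angular_acceleration(self):
        n = 200
        gyro = np.column_stack([np.full(n, 10.0), np.zeros(n), np.zeros(n)])
        sig = derive_signals(recording_from(np.zeros((n, 3)), gyro))
        np.testing.assert_allclose(sig["alpha_roll"], 0.0, atol=1e-12)

    def test_static_gravity_posture(self):
        n = 100
        acc = np.tile([0.0, 0.0, -1.0], (n, 1))
        sig = derive_signals(recording_from(acc, np.zeros((n, 3))))
        np.testing.assert_allclose(sig["a_mag"], 1.0, atol=1e-12)
        np.testing.assert_allclose(sig["d"], 0.0, atol=1e-12)
        np.testing.assert_allclose(sig["r_xz"], 0.0, atol=1e-12)
        np.testing.assert_allclose(sig["c"], 0.0, atol=1e-12)  # |w| = 0 convention

    def test_angular_acceleration_matches_analytic_derivative(self):
        """w(t) = 100 sin(2*pi*2*t) deg/s has alpha amplitude 400*pi deg/s^2."""
        n = 500
        t = np.arange(n) / RATE
        w = 100.0 * np.sin(2 * np.pi * 2.0 * t)
        gyro = np.column_stack([w, np.zeros(n), np.zeros(n)])
        sig = derive_signals(recording_from(np.zeros((n, 3)), gyro))
        analytic = 2 * np.pi * 2.0 * 100.0 * np.cos(2 * np.pi * 2.0 * t)
        # interior samples: central differences of a smooth sinusoid
        np.testing.assert_allclose(
            sig["alpha_roll"][1:-1], analytic[1:-1],
            atol=0.01 * 2 * np.pi * 2.0 * 100.0,
        )

    def test_tangent_ratio_clamps_small_az(self):
        acc = np.array([[0.5, 0.0, 0.001], [0.5, 0.0, -0.001], [0.5, 0.0, 0.0]])
        sig = derive_signals(recording_from(acc, np.zeros((3, 3))))
        np.testing.assert_allclose(sig["r_xz"], [10.0, -10.0, 10.0])  # eps 0.05

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValidationError):
            derive_signals(recording_from(np.zeros((1, 3)), np.zeros((1, 3))))


def brute_force_windows(rec, track, window, stride):
    """Independent enumeration over all end samples, per interval."""
    n_win = int(round(window * rec.sample_rate))
    out = []
    for iv in track.intervals:
        i0 = max(int(math.floor(iv.start * rec.sample_rate + 1e-9)), 0)
        i1 = min(int(math.floor(iv.end * rec.sample_rate + 1e-9)), len(rec))
        ends = [k for k in range(n_win, len(rec) + 1)
                if k - n_win >= i0 and k <= i1]
        for j, k in enumerate(ends):
            if j % stride == 0:
                out.append(Window(k - n_win, k, iv.category))
    return out


class TestWindowing:
    def test_five_second_interval_yields_41_windows(self):
        rec = recording_from(np.zeros((2000, 3)), np.zeros((2000, 3)))
        track = LabelTrack((LabelInterval(10.0, 15.0, B.TROT),))
        wins = cut_windows(rec, track, window=1.0, stride=10)
        assert len(wins) == 41
        assert wins[0] == Window(1000, 1100, B.TROT)
        assert wins[-1] == Window(1400, 1500, B.TROT)

    def test_interval_shorter_than_window_yields_none(self):
        rec = recording_from(np.zeros((500, 3)), np.zeros((500, 3)))
        track = LabelTrack((LabelInterval(1.0, 1.8, B.SIT),))
        assert cut_windows(rec, track) == []

    def test_no_window_straddles_a_category_boundary(self):
        rec = recording_from(np.zeros((1000, 3)), np.zeros((1000, 3)))
        track = LabelTrack(
            (LabelInterval(0.0, 4.0, B.WALK), LabelInterval(4.0, 8.0, B.TROT))
        )
        for w in cut_windows(rec, track):
            first, last = w.start / RATE, (w.stop - 1) / RATE
            cat_first = track.category_at(first)
            cat_last = track.category_at(last)
            assert cat_first is cat_last is w.category

    def test_nonpositive_stride_rejected(self):
        rec = recording_from(np.zeros((200, 3)), np.zeros((200, 3)))
        with pytest.raises(ValueError):
            cut_windows(rec, LabelTrack(()), stride=0)

    def test_matches_brute_force_enumeration_on_random_tracks(self):
        rng = np.random.default_rng(42)
        rec = recording_from(np.zeros((3000, 3)), np.zeros((3000, 3)))
        cats = list(B)
        for _ in range(15):
            cursor, intervals = 0.0, []
            while cursor < 25.0 and len(intervals) < 8:
                start = cursor + rng.uniform(0.0, 2.0)
                dur = rng.uniform(0.3, 6.0)
                intervals.append(
                    LabelInterval(round(start, 3), round(start + dur, 3),
                                  cats[rng.integers(7)])
                )
                cursor = intervals[-1].end
            track = LabelTrack(tuple(intervals))
            stride = int(rng.integers(1, 25))
            assert cut_windows(rec, track, stride=stride) == \
                brute_force_windows(rec, track, 1.0, stride)


def naive_moments(x):
    """Two-pass oracle for mean/std/skewness/kurtosis (population moments)."""
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    std = math.sqrt(m2)
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    return mean, std, skew, kurt


def direct_dft_magnitudes(x):
    """O(n^2) textbook DFT, amplitude-scaled: 2|X_k|/n for k = 0..n//2."""
    n = len(x)
    mags = []
    for k in range(n // 2 + 1):
        re = sum(x[j] * math.cos(2 * math.pi * k * j / n) for j in range(n))
        im = -sum(x[j] * math.sin(2 * math.pi * k * j / n) for j in range(n))
        mags.append(2.0 * math.hypot(re, im) / n)
    return mags


def extract_single_window(values):
    """Features of one 100-sample window fed through the full extractor."""
    n = len(values)
    acc = np.column_stack([values, values, values])
    rec = recording_from(acc, acc)
    sig = derive_signals(rec)
    ds = extract_features(sig, [Window(0, n, B.WALK)])
    return {name: ds.X[0, i] for i, name in enumerate(ds.feature_names)}


class TestFeatureExtraction:
    def test_manifest_partition(self):
        groups = [s.group for s in DEFAULT_MANIFEST]
        assert len(DEFAULT_MANIFEST) == 126
        assert groups.count("gyro_only") == 69
        assert groups.count("acc_only") == 45
        assert groups.count("mixed") == 12
        assert len({s.name for s in DEFAULT_MANIFEST}) == 126

    def test_manifest_csv_roundtrip(self, tmp_path):
        save_manifest(tmp_path / "m.csv")
        assert load_manifest(tmp_path / "m.csv") == DEFAULT_MANIFEST

    def test_constant_window_conventions(self):
        feats = extract_single_window(np.full(100, 3.25))
        assert feats["a_x_std"] == 0.0
        assert feats["a_x_min"] == feats["a_x_max"] == feats["a_x_mean"] == 3.25
        assert feats["a_x_skew"] == feats["a_x_kurt"] == 0.0
        assert feats["a_x_mcross"] == 0.0

    def test_pure_sinusoid_dominant_frequency_and_magnitude(self):
        t = np.arange(100) / RATE
        x = 0.8 * np.sin(2 * np.pi * 3.0 * t)
        feats = extract_single_window(x)
        assert feats["a_x_fdom"] == pytest.approx(3.0)
        oracle = direct_dft_magnitudes(list(x))
        k = int(np.argmax(oracle[1:51])) + 1
        assert k == 3
        assert feats["a_x_fmag"] == pytest.approx(oracle[k], abs=1e-9)

    def test_moments_and_spectrum_match_oracles_on_random_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            x = rng.normal(scale=rng.uniform(0.1, 5.0), size=100)
            feats = extract_single_window(x)
            mean, std, skew, kurt = naive_moments(list(x))
            assert feats["a_x_mean"] == pytest.approx(mean, abs=1e-9)
            assert feats["a_x_std"] == pytest.approx(std, abs=1e-9)
            assert feats["a_x_skew"] == pytest.approx(skew, abs=1e-9)
            assert feats["a_x_kurt"] == pytest.approx(kurt, abs=1e-9)
            mags = direct_dft_magnitudes(list(x))
            k = int(np.argmax(mags[1:51])) + 1
            assert feats["a_x_fdom"] == pytest.approx(k * RATE / 100)
            assert feats["a_x_fmag"] == pytest.approx(mags[k], abs=1e-9)

    def test_mean_crossing_count(self):
        x = np.zeros(100)
        x[::2] = 1.0  # alternates around its mean every sample
        feats = extract_single_window(x)
        assert feats["a_x_mcross"] == 99.0

    def test_extraction_is_deterministic(self, one_measurement):
        from ethotrack.featurize import featurize_session

        m = one_measurement
        a = featurize_session(m.recording, m.track, stride=20)
        b = featurize_session(m.recording, m.track, stride=20)
        assert np.array_equal(a.X, b.X)

    def test_nonfinite_window_identified(self):
        acc = np.zeros((200, 3))
        acc[150, 0] = np.nan
        rec = recording_from(acc, np.zeros((200, 3)))
        sig = derive_signals(rec)
        with pytest.raises(ValidationError, match="window 1"):
            extract_features(sig, [Window(0, 100, B.WALK), Window(100, 200, B.WALK)])


class TestNormalization:
    def test_affine_map_to_unit_interval(self):
        ds = toy_dataset({B.WALK: 3}, seed=1)
        ds.X[:, 0] = [2.0, 4.0, 6.0]
        params = fit_normalizer(ds)
        out = apply_normalizer(params, ds)
        np.testing.assert_allclose(out.X[:, 0], [0.0, 0.5, 1.0])
        assert out.X.min() >= 0.0 and out.X.max() <= 1.0

    def test_constant_column_maps_to_zero(self):
        ds = toy_dataset({B.WALK: 2}, seed=1)
        ds.X[:, 5] = 5.0
        out = apply_normalizer(fit_normalizer(ds), ds)
        np.testing.assert_allclose(out.X[:, 5], 0.0)

    def test_out_of_range_validation_values_clip(self):
        train = toy_dataset({B.WALK: 3}, seed=1)
        train.X[:, 0] = [2.0, 4.0, 6.0]
        val = toy_dataset({B.WALK: 1}, seed=2)
        val.X[:, 0] = 8.0
        out = apply_normalizer(fit_normalizer(train), val)
        assert out.X[0, 0] == 1.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            NormalizationParams.fit(np.empty((0, 126)))


def test_feature_csv_roundtrip(tmp_path, one_measurement):
    from ethotrack.featurize import featurize_session

    m = one_measurement
    ds = featurize_session(m.recording, m.track, stride=25)
    write_features(ds, tmp_path / "f.csv")
    back = read_features(tmp_path / "f.csv")
    np.testing.assert_allclose(back.X, ds.X, rtol=0, atol=1e-12)
    assert all(a is b for a, b in zip(back.y, ds.y))
    assert back.provenance.equals(ds.provenance.astype(back.provenance.dtypes))
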