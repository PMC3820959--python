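"""The synthetic canine-motion generator: structure, realism, determinism."""

import numpy as np
import pytest

from ethotrack import simulate
from ethotrack.featurize import cut_windows, derive_signals, featurize_session
from ethotrack.sensor_io import (
    BehaviorCategory,
    LabelTrack,
    ValidationError,
    activity_level,
    apply_margin,
)
from ethotrack.simulate import (
    default_templates,
    generate_session,
    generate_study,
    make_population,
    short_script,
    simulate_second_coder,
)

B = BehaviorCategory


class TestPopulation:
    def test_deterministic_under_seed(self):
        assert make_population(4, 0.2, seed=9) == make_population(4, 0.2, seed=9)

    def test_zero_sigma_makes_same_breed_dogs_identical(self):
        pop = make_population(3, 0.0, seed=1)
        by_breed = {}
        for p in pop:
            by_breed.setdefault(p.breed, []).append(p)
        for dogs in by_breed.values():
            ref = dogs[0]
            for d in dogs[1:]:
                assert (d.freq_factor, d.amp_factor, d.attitude_jitter) == \
                    (ref.freq_factor, ref.amp_factor, ref.attitude_jitter)

    def test_study_design_counts(self):
        pop = make_population(12, seed=0)
        assert len(pop) == 24
        meas = generate_study(pop[:2] + pop[12:14], short_script(5.0),
                              sessions_per_dog=2, seed=3)
        assert len(meas) == 8  # dogs x sessions


class TestSessions:
    def test_stand_is_pure_gravity_when_noiseless(self):
        tpl = {**default_templates()}
        tpl[B.STAND] = simulate.BehaviorTemplate(
            B.STAND, "static", attitude_pitch=0.0, noise_acc_sd=0.0,
            noise_gyro_sd=0.0,
        )
        profile = simulate.DogProfile("X01", "none")  # no breed offset
        m = generate_session(
            profile, simulate.SessionScript(((B.STAND, 5.0),)),
            seed=0, templates=tpl,
        )
        iv = m.track.intervals[0]
        sl = slice(int(iv.start * 100), int(iv.end * 100))
        np.testing.assert_allclose(m.recording.a_x[sl], 0.0, atol=1e-12)
        np.testing.assert_allclose(m.recording.a_z[sl], -1.0, atol=1e-12)
        sig = derive_signals(m.recording)
        np.testing.assert_allclose(sig["a_mag"][sl], 1.0, atol=1e-12)

    def test_trot_dominant_frequency_tracks_profile(self):
        pop = make_population(4, 0.15, seed=2)
        for profile in pop[:2] + pop[4:6]:
            m = generate_session(
                profile, simulate.SessionScript(((B.TROT, 10.0),)), seed=11
            )
            iv = m.track.intervals[0]
            sl = slice(int(iv.start * 100), int(iv.end * 100))
            az = m.recording.a_z[sl] - np.mean(m.recording.a_z[sl])
            spec = np.abs(np.fft.rfft(az))
            freqs = np.fft.rfftfreq(len(az), d=0.01)
            f_peak = freqs[np.argmax(spec)]
            base = (3.0 * simulate.BREED_OFFSETS[profile.breed].freq_factor
                    * profile.freq_factor)
            # per-segment lognormal jitter has sd 0.04 in log space
            assert abs(np.log(f_peak / base)) < 0.15

    def test_angular_velocity_variance_orders_gaits(self):
        pop = make_population(3, 0.15, seed=4)
        script = simulate.SessionScript(((B.WALK, 8.0), (B.GALLOP, 8.0)))
        for profile in pop:
            m = generate_session(profile, script, seed=7)
            sig = derive_signals(m.recording)
            segs = {iv.category: slice(int(iv.start * 100), int(iv.end * 100))
                    for iv in m.track.intervals}
            assert np.var(sig["w_mag"][segs[B.GALLOP]]) > \
                np.var(sig["w_mag"][segs[B.WALK]])

    def test_labels_exactly_tile_behaviour_segments(self):
        pop = make_population(1, 0.15, seed=6)
        script = short_script(5.0, gap=2.0)
        m = generate_session(pop[0], script, seed=8)
        assert len(m.track) == len(script.items)
        cursor = 0.0
        for iv, (cat, dur) in zip(m.track.intervals, script.items):
            assert iv.category is cat
            assert iv.start == pytest.approx(cursor + script.gap)
            assert iv.duration == pytest.approx(dur)
            cursor = iv.end
        assert len(m.recording) == int(round(cursor * 100))

    def test_empty_script_rejected(self):
        with pytest.raises(ValidationError):
            simulate.SessionScript(())

    def test_mean_window_std_of_acceleration_increases_with_activity(self):
        """|a| variability must rise strictly along activity levels 0-3."""
        pop = make_population(2, 0.15, seed=3)
        for profile in pop:
            m = generate_session(profile, short_script(8.0), seed=13)
            sig = derive_signals(m.recording)
            trimmed = apply_margin(m.track, 1.0)
            per_level: dict[int, list[float]] = {0: [], 1: [], 2: [], 3: []}
            for w in cut_windows(m.recording, trimmed, stride=20):
                per_level[activity_level(w.category)].append(
                    float(np.std(sig["a_mag"][w.start:w.stop]))
                )
            means = [np.mean(per_level[k]) for k in range(4)]
            assert means[0] < means[1] < means[2] < means[3]


class TestStudy:
    def test_stream_level_determinism(self):
        pop = make_population(2, 0.15, seed=5)
        m1 = generate_study(pop, short_script(4.0), 2, seed=9)
        m2 = generate_study(pop, short_script(4.0), 2, seed=9)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.recording.a_x, b.recording.a_x)
            np.testing.assert_array_equal(a.recording.w_yaw, b.recording.w_yaw)
            assert a.track.intervals == b.track.intervals

    def test_same_dog_sessions_closer_than_different_dogs(self):
        """Mean feature vectors: within-dog distance < between-dog distance
        on average, for 3 independent study seeds."""
        for seed in (31, 32, 33):
            pop = make_population(3, 0.15, seed=seed)
            meas = generate_study(pop, short_script(6.0), 2, seed=seed + 100)
            datasets = [featurize_session(m.recording, m.track, stride=25)
                        for m in meas]
            centroids: dict[tuple[str, int], np.ndarray] = {}
            for ds in datasets:
                key = next(iter(ds.measurement_keys()))
                centroids[key] = ds.X.mean(axis=0)
            scale = np.std(np.vstack(list(centroids.values())), axis=0) + 1e-12
            within, between = [], []
            dogs = sorted({k[0] for k in centroids})
            for d in dogs:
                within.append(np.linalg.norm(
                    (centroids[(d, 1)] - centroids[(d, 2)]) / scale))
            for i, d1 in enumerate(dogs):
                for d2 in dogs[i + 1:]:
                    between.append(np.linalg.norm(
                        (centroids[(d1, 1)] - centroids[(d2, 1)]) / scale))
            assert np.mean(within) < np.mean(between)


class TestSecondCoder:
    def test_high_but_imperfect_agreement(self):
        pop = make_population(1, 0.15, seed=2)
        m = generate_session(pop[0], simulate.default_script(), seed=3)
        other = simulate_second_coder(m.track, seed=4)
        from ethotrack.evaluate import intercoder_agreement

        a = apply_margin(m.track, 1.0)
        b = apply_margin(other, 1.0)
        res = intercoder_agreement(a, b)
        assert res.has_common
        assert 80.0 < res.pct_common_agree < 100.0

    def test_track_remains_valid(self):
        pop = make_population(1, 0.15, seed=2)
        m = generate_session(pop[0], short_script(6.0), seed=3)
        other = simulate_second_coder(m.track, seed=9, boundary_jitter_sd=1.0)
        assert isinstance(other, LabelTrack)  # non-overlap enforced on build
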