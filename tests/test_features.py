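import math

import numpy as np
import pytest
import scipy.fft

from evplankton.exceptions import ConfigError, InsufficientDataError
from evplankton.features import (
    FEATURE_NAMES,
    FeatureConfig,
    PowerSpectrum,
    centre_trajectory,
    compute_features,
    coord_fft_features,
    coordinate_series,
    count_peaks,
    dominant_event_peak,
    event_fft_features,
    event_increment_series,
    power_spectrum,
    shape_features,
    velocity_features,
)
from evplankton.synth import ParticleSpec, SceneSpec, simulate
from evplankton.tracking import track_events
from conftest import make_track


def _main_track(scene):
    stream, _ = simulate(scene)
    res = track_events(stream)
    return max(res.tracks, key=lambda t: len(t.ev_x))


class TestCentreTrajectory:
    def test_constant_events_constant_centres(self):
        track = make_track([[(10, 10, 1)]] * 12)
        _, centres, observed = centre_trajectory(track)
        assert np.allclose(centres, [[10, 10]] * 3)
        assert observed.all()

    def test_centroid_of_two_events(self):
        ticks = [[(0, 0, 1), (2, 0, 1)], [], [], []] + [[(4, 0, 1)]] * 4
        _, centres, _ = centre_trajectory(make_track(ticks))
        assert tuple(centres[0]) == (1.0, 0.0)

    def test_empty_segment_carries_previous_centre(self):
        ticks = [[(5, 5, 1)]] * 4 + [[]] * 4 + [[(9, 9, 1)]] * 4
        _, centres, observed = centre_trajectory(make_track(ticks))
        assert tuple(centres[1]) == (5.0, 5.0)
        assert not observed[1] and observed[0] and observed[2]

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            centre_trajectory(make_track([[(1, 1, 1)]] * 3))

    def test_drifter_displacement_matches_speed(self):
        """Simulated drifter at 0.5 pxl/ms: recovered mean speed within 10%."""
        for seed in range(5):
            scene = SceneSpec(
                geometry=(800, 128), duration_ms=1000,
                particles=[ParticleSpec(
                    kind="drifter", start=(60, 60), velocity=(0.5, 0.0),
                    lifetime_ms=1000,
                )],
                seed=seed,
            )
            tr = _main_track(scene)
            _, centres, _ = centre_trajectory(tr)
            f01, _, _, _ = velocity_features(centres)
            assert abs(f01 - 0.5) / 0.5 < 0.10


class TestVelocityFeatures:
    def test_constant_speed(self):
        centres = np.array([[0, 0], [2, 0], [4, 0]], float)
        f01, f05, f06, _ = velocity_features(centres)
        assert f01 == 0.5 and f06 == 0.0 and f05 == 0

    def test_acceleration_peaks_hand_computed(self):
        """Speed series {1,1,1,1,10,1,1,1,1,1} px/ms at 4 ms steps: the two
        jumps give |dv|/dt = 2.25, mean acceleration 0.5, threshold 2.5 —
        so no acceleration peak qualifies."""
        speeds = np.array([1, 1, 1, 1, 10, 1, 1, 1, 1, 1], float)
        x = np.concatenate([[0.0], np.cumsum(speeds * 4)])
        centres = np.column_stack([x, np.zeros_like(x)])
        f01, f05, f06, got_speeds = velocity_features(centres)
        assert np.allclose(got_speeds, speeds)
        assert f05 == 0
        assert math.isclose(f06, speeds.var())
        assert math.isclose(f01, speeds.mean())

    def test_single_outlier_detected(self):
        speeds = np.array([1] * 20 + [30] + [1] * 20, float)
        x = np.concatenate([[0.0], np.cumsum(speeds * 4)])
        centres = np.column_stack([x, np.zeros_like(x)])
        _, f05, _, _ = velocity_features(centres)
        # oracle: explicit comparison of each |dv|/4 against 5x its mean
        accel = np.abs(np.diff(speeds)) / 4
        assert f05 == int((accel > 5 * accel.mean()).sum()) > 0

    def test_f06_zero_for_constant_velocity_exactly(self):
        centres = np.column_stack([np.arange(10) * 3.0, np.arange(10) * 4.0])
        _, _, f06, _ = velocity_features(centres)
        assert f06 == 0.0

    def test_too_few_centres(self):
        with pytest.raises(InsufficientDataError):
            velocity_features(np.array([[0.0, 0.0]]))


def _square_blob_track(n_segments=6, size=4, step=1):
    """size x size blob, static within each 4 ms segment, hopping ``step``
    px along +x between segments."""
    ticks = []
    for s in range(n_segments):
        tick = [
            (10 + s * step + dx, 10 + dy, 1 if dx >= size // 2 else -1)
            for dx in range(size)
            for dy in range(size)
        ]
        ticks.extend([tick] * 4)
    return make_track(ticks)


class TestShapeFeatures:
    def test_square_blob_length_width(self):
        track = _square_blob_track()
        _, centres, _ = centre_trajectory(track)
        vals, valid = shape_features(track, centres)
        f02, f03 = vals[0], vals[1]
        assert f02 == 4.0 and f03 == 4.0
        assert valid.all()

    def test_on_axis_events_have_no_orthogonal_spread(self):
        ticks = []
        for s in range(6):
            tick = [(10 + s + dx, 20, 1 if dx >= 2 else -1) for dx in range(4)]
            ticks.extend([tick] * 4)
        track = make_track(ticks)
        _, centres, _ = centre_trajectory(track)
        vals, _ = shape_features(track, centres)
        f04, f08, f10 = vals[2], vals[4], vals[6]
        assert f04 == 0.0 and f08 == 0.0 and f10 == 0.0

    def test_zero_velocity_flags_shape_features(self):
        track = make_track([[(10, 10, 1)]] * 12)
        _, centres, _ = centre_trajectory(track)
        vals, valid = shape_features(track, centres)
        assert not valid.any() and not vals.any()

    def test_antenna_raises_f04(self):
        """A forward antenna puts events beyond the body width with positive
        along-velocity inner product; paired runs differ only in antenna."""
        wins = 0
        for seed in range(20):
            f04 = {}
            for antenna in (0.0, 10.0):
                scene = SceneSpec(
                    geometry=(700, 128), duration_ms=1000,
                    particles=[ParticleSpec(
                        kind="drifter", start=(60, 60), velocity=(0.4, 0.0),
                        antenna_px=antenna, lifetime_ms=1000,
                    )],
                    seed=seed,
                )
                tr = _main_track(scene)
                _, centres, _ = centre_trajectory(tr)
                vals, _ = shape_features(tr, centres)
                f04[antenna] = vals[2]
            wins += f04[10.0] > f04[0.0]
        assert wins == 20

    def test_scale_behaviour(self):
        """Doubling all coordinates doubles extents (F02, F03) and the
        variance ratios F07-F10 (variance/length), and leaves the
        distance ratios F11/F12 invariant."""
        rng = np.random.default_rng(5)
        ticks = []
        for s in range(8):
            tick = [
                (20 + 2 * s + int(rng.integers(0, 6)),
                 30 + int(rng.integers(0, 4)),
                 1 if rng.random() < 0.5 else -1)
                for _ in range(40)
            ]
            ticks.extend([tick] * 4)
        base = make_track(ticks)
        doubled = make_track(
            [[(2 * x, 2 * y, p) for x, y, p in tick] for tick in ticks]
        )
        res = {}
        for name, track in (("base", base), ("x2", doubled)):
            _, centres, _ = centre_trajectory(track)
            vals, valid = shape_features(track, centres)
            assert valid.all()
            res[name] = vals
        b, d = res["base"], res["x2"]
        for i in (0, 1):  # F02, F03 double (up to the +1 pixel convention)
            assert d[i] / b[i] == pytest.approx(2.0, rel=0.15)
        for i in (3, 4, 5, 6):  # F07-F10 scale like variance/length
            assert d[i] / b[i] == pytest.approx(2.0, rel=0.25)
        for i in (7, 8):  # F11, F12 are ratios: invariant
            assert d[i] == pytest.approx(b[i], rel=0.15, abs=0.02)


class TestSeries:
    def test_unit_rate_positive_series(self):
        track = make_track([[(5, 5, 1)]] * 10)
        pos, neg, tot = event_increment_series(track)
        assert (pos == 1).all() and (neg == 0).all() and (tot == 1).all()

    def test_total_is_sum_of_polarities(self, rng):
        ticks = [
            [(int(rng.integers(0, 30)), int(rng.integers(0, 30)),
              1 if rng.random() < 0.5 else -1)
             for _ in range(int(rng.integers(0, 6)))]
            for _ in range(50)
        ]
        pos, neg, tot = event_increment_series(make_track(ticks))
        assert np.array_equal(tot, pos + neg)

    def test_linear_drift_detrends_to_zero(self):
        ticks = [[(10 + t, 20 + 2 * t, 1)] for t in range(0, 64)]
        series = coordinate_series(make_track(ticks))
        for s in series.values():
            assert np.allclose(s, 0.0, atol=1e-9)

    def test_detrended_endpoints_exactly_zero(self, rng):
        ticks = [
            [(int(rng.integers(0, 50)), int(rng.integers(0, 50)), 1),
             (int(rng.integers(0, 50)), int(rng.integers(0, 50)), -1)]
            for _ in range(64)
        ]
        series = coordinate_series(make_track(ticks))
        for s in series.values():
            assert s[0] == 0.0 and s[-1] == 0.0

    def test_sinusoid_survives_detrending(self):
        n = 64
        xs = 100 + 0.5 * np.arange(n * 4) + 10 * np.sin(
            2 * np.pi * 6.0 * np.arange(n * 4) / 1000
        )
        ticks = [[(int(round(x)), 50, 1)] for x in xs]
        series = coordinate_series(make_track(ticks))["total_x"]
        # detrended series stays close to the sinusoid (endpoints near zero
        # phase): correlation with the pure tone is strong
        tone = np.sin(2 * np.pi * 6.0 * np.arange(n) * 4 / 1000)
        r = np.corrcoef(series, tone)[0, 1]
        assert abs(r) > 0.9


class TestPowerSpectrum:
    def test_constant_series_floor(self):
        ps = power_spectrum(np.full(64, 3.0), 1.0)
        assert (ps.power_db[1:] < -100).all()

    def test_pure_tone_peak_location(self):
        t = np.arange(1024) / 1000.0
        ps = power_spectrum(np.sin(2 * np.pi * 10 * t), 1.0)
        peak = ps.frequencies[1:][np.argmax(ps.power_db[1:])]
        expected = ps.frequencies[np.argmin(np.abs(ps.frequencies - 10))]
        assert peak == expected

    def test_two_tones_two_maxima(self):
        t = np.arange(1000) / 1000.0
        series = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 16 * t)
        ps = power_spectrum(series, 1.0)
        count, freqs = count_peaks(ps)
        assert count == 2
        assert sorted(np.round(freqs).astype(int)) == [8, 16]

    def test_parseval(self, rng):
        """Total spectral power equals series energy (transform oracle)."""
        x = rng.normal(size=512)
        ps = power_spectrum(x, 1.0)
        power = 10 ** (ps.power_db / 10)
        # one-sided: double all bins except DC and Nyquist
        full = power.copy()
        full[1:-1] *= 2
        assert np.isclose(full.sum() / len(x), (x**2).sum(), rtol=1e-9)

    def test_nyquist_grid(self):
        ps1 = power_spectrum(np.ones(100), 1.0)
        ps4 = power_spectrum(np.ones(100), 4.0)
        assert ps1.frequencies[-1] == pytest.approx(500.0)
        assert ps4.frequencies[-1] == pytest.approx(125.0)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            power_spectrum(np.ones(7), 1.0)


class TestCountPeaks:
    def _spectrum(self, power_db):
        p = np.asarray(power_db, float)
        return PowerSpectrum(np.arange(len(p), dtype=float), p)

    def test_flat_spectrum_no_peaks(self):
        assert count_peaks(self._spectrum([50.0] * 40))[0] == 0

    def test_tone_above_threshold_counted(self):
        p = np.zeros(40)
        p[12] = 16.0
        count, freqs = count_peaks(self._spectrum(p))
        assert count == 1 and freqs[0] == 12.0

    def test_tone_below_threshold_ignored(self):
        p = np.zeros(40)
        p[12] = 10.0
        assert count_peaks(self._spectrum(p))[0] == 0

    def test_adjacent_superthreshold_bins_count_once(self):
        p = np.zeros(60)
        p[20], p[21], p[22] = 18.0, 20.0, 18.0
        assert count_peaks(self._spectrum(p))[0] == 1

    def test_local_background_absorbs_decaying_baseline(self):
        """A smooth 1/k^2 low-frequency baseline (the detrending artifact)
        must not register as peaks."""
        k = np.arange(1, 80, dtype=float)
        p = np.concatenate([[60.0], 20 - 20 * np.log10(k)])
        assert count_peaks(self._spectrum(p))[0] == 0

    def test_global_median_background_option(self):
        p = np.zeros(40)
        p[12] = 16.0
        cfg = FeatureConfig(background="median")
        assert count_peaks(self._spectrum(p), cfg)[0] == 1


class TestFftFeatureBinning:
    def _rate_modulated_track(self, freq_hz, n_ticks=2000, base=10, amp=8):
        t = np.arange(n_ticks) / 1000.0
        counts = np.round(base + amp * np.sin(2 * np.pi * freq_hz * t)).astype(int)
        ticks = [[(50, 50, 1)] * max(0, c) for c in counts]
        return make_track(ticks)

    def test_peak_at_8_1_hz_bins_into_f16(self):
        counts, freqs = event_fft_features(self._rate_modulated_track(8.1))
        assert counts[3] >= 1  # the [4.6, 10) Hz segment
        assert any(abs(f - 8.0) < 0.6 for f in freqs)

    def test_peak_at_16_hz_bins_into_f17(self):
        track = self._rate_modulated_track(16.0)
        counts, _ = event_fft_features(track)
        assert counts[4] >= 1  # the [10, 22) Hz segment
        dom = dominant_event_peak(track)
        assert 10 <= dom < 22

    def test_constant_rate_no_peaks(self):
        track = make_track([[(50, 50, 1)] * 5] * 600)
        counts, _ = event_fft_features(track)
        assert not counts.any()

    def test_half_open_edges(self):
        cfg = FeatureConfig()
        from evplankton.features import _bin_peaks

        counts = _bin_peaks([4.6], cfg.event_fft_edges, 6)
        assert counts[3] == 1  # 4.6 goes to [4.6, 10), not [2.2, 4.6)
        counts = _bin_peaks([4.6], cfg.coord_fft_edges, 4)
        assert counts[3] == 1  # and to the >= 4.6 coordinate segment


class TestCoordFft:
    def test_lateral_oscillator_hits_f20(self):
        """1.5 Hz lateral oscillation lands in the [1, 2.2) Hz segment."""
        scene = SceneSpec(
            geometry=(800, 200), duration_ms=4000,
            particles=[ParticleSpec(
                kind="oscillator", start=(60, 100), velocity=(0.15, 0.0),
                freq_hz=1.5, osc_amplitude_px=4.0, lifetime_ms=4000,
            )],
            seed=11,
        )
        counts, freqs = coord_fft_features(_main_track(scene))
        assert counts[1] >= 1
        assert any(abs(f - 1.5) < 0.3 for f in freqs)

    def test_ballistic_drifter_no_peaks(self):
        scene = SceneSpec(
            geometry=(800, 200), duration_ms=3000,
            particles=[ParticleSpec(
                kind="drifter", start=(60, 100), velocity=(0.11, 0.043),
                lifetime_ms=3000,
            )],
            seed=4,
        )
        counts, _ = coord_fft_features(_main_track(scene))
        assert not counts.any()

    def test_6_hz_oscillation_hits_f22(self):
        scene = SceneSpec(
            geometry=(800, 200), duration_ms=4000,
            particles=[ParticleSpec(
                kind="oscillator", start=(60, 100), velocity=(0.15, 0.0),
                freq_hz=6.0, osc_amplitude_px=4.0, lifetime_ms=4000,
            )],
            seed=12,
        )
        counts, freqs = coord_fft_features(_main_track(scene))
        assert counts[3] >= 1
        assert any(abs(f - 6.0) < 0.5 for f in freqs)


class TestComputeFeatures:
    def test_beater_7hz_event_peak_in_f16(self):
        from evplankton.synth import make_beater_scene

        fv = compute_features(_main_track(make_beater_scene(7.0, seed=2)))
        assert fv["F16"] >= 1
        dom = dominant_event_peak(_main_track(make_beater_scene(7.0, seed=2)))
        assert 4.6 <= dom < 10

    def test_stationary_unmodulated_blob_is_all_quiet(self):
        ticks = [
            [(30 + dx, 30 + dy, 1 if dx > 1 else -1)
             for dx in range(4) for dy in range(4)]
        ] * 64
        fv = compute_features(make_track(ticks))
        assert fv["F01"] == 0.0 and fv["F05"] == 0.0
        assert not fv.values[12:22].any()

    def test_deterministic(self):
        from evplankton.synth import make_beater_scene

        tr = _main_track(make_beater_scene(3.0, seed=9))
        a = compute_features(tr)
        b = compute_features(tr)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.valid, b.valid)

    def test_degenerate_track_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_features(make_track([[(1, 1, 1)]] * 4))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            FeatureConfig(segment_period_ms=2.5).validate()
        with pytest.raises(ConfigError):
            FeatureConfig(event_fft_edges=(2.2, 1.0)).validate()
        with pytest.raises(ConfigError):
            FeatureConfig(background="mode").validate()

    def test_feature_names(self):
        assert len(FEATURE_NAMES) == 22
        assert FEATURE_NAMES[0] == "F01" and FEATURE_NAMES[-1] == "F22"
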