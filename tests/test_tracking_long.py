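"""Long-axis tracker: point tracking, motion compensation, edges, diameters."""

import math

import numpy as np
import pytest

from cavatrack.errors import InputError, TrackingLostError
from cavatrack.phantom import (
    PhantomSpec,
    PressureDrivers,
    PressureVolumeCurve,
    generate_long_axis,
    preset,
)
from cavatrack.tracking_long import (
    LongAxisConfig,
    apply_transform,
    compensate_motion,
    compute_diameters,
    detect_edges_long,
    estimate_midline,
    run_long_axis,
    track_reference_points,
)
from cavatrack.video_io import VideoSequence

FPS = 30.0


def _speckled_spec(**kw):
    base = dict(view="long_axis", shape=(128, 256), D0=40.0,
                speckle_sigma=0.35, noise_sigma=2.0, psf_sigma=1.0, seed=5)
    base.update(kw)
    return PhantomSpec(**base)


def _static_drivers():
    return PressureDrivers(A_card=0.0, A_resp=0.0)


class TestReferencePointTracking:
    def test_static_phantom_positions_constant(self, static_long):
        _, video, truth = static_long
        p1, p2 = truth.reference_points[0]
        refs = track_reference_points(video, tuple(p1), tuple(p2))
        assert np.abs(refs.p1 - refs.p1[0]).max() < 0.1
        assert np.abs(refs.p2 - refs.p2[0]).max() < 0.1

    def test_drift_recovered(self):
        """0.5 px/frame rightward drift: 20 px displacement after 40 frames."""
        spec = _speckled_spec(drift=(0.0, 0.5))
        video, truth = generate_long_axis(spec, PressureVolumeCurve(),
                                          _static_drivers(), 41, fps=FPS)
        p1, p2 = truth.reference_points[0]
        refs = track_reference_points(video, tuple(p1), tuple(p2))
        assert refs.p1[-1, 1] - refs.p1[0, 1] == pytest.approx(20.0, abs=0.5)
        assert refs.p2[-1, 1] - refs.p2[0, 1] == pytest.approx(20.0, abs=0.5)

    def test_rotation_recovered_from_segment_angle(self):
        """0.2 deg/frame about the centre: 8 deg change after 40 frames."""
        spec = _speckled_spec(rotation_rate=0.2)
        video, truth = generate_long_axis(spec, PressureVolumeCurve(),
                                          _static_drivers(), 41, fps=FPS)
        p1, p2 = truth.reference_points[0]
        refs = track_reference_points(video, tuple(p1), tuple(p2))

        def angle(a, b):
            v = b - a
            return math.degrees(math.atan2(v[0], v[1]))

        d_angle = angle(refs.p1[-1], refs.p2[-1]) - angle(refs.p1[0], refs.p2[0])
        assert abs(d_angle) == pytest.approx(8.0, abs=0.5)

    def test_seed_near_border_rejected(self, static_long):
        _, video, _ = static_long
        with pytest.raises(InputError, match="border"):
            track_reference_points(video, (2.0, 5.0), (60.0, 200.0))


class TestMotionCompensation:
    def test_static_video_identity(self, static_long):
        _, video, truth = static_long
        p1, p2 = truth.reference_points[0]
        refs = track_reference_points(video, tuple(p1), tuple(p2))
        tr = compensate_motion(refs)
        np.testing.assert_allclose(tr, 0.0, atol=0.05)

    def test_pure_translation_recovered(self):
        spec = _speckled_spec(drift=(3 / 40, 4 / 40))
        video, truth = generate_long_axis(spec, PressureVolumeCurve(),
                                          _static_drivers(), 41, fps=FPS)
        p1, p2 = truth.reference_points[0]
        refs = track_reference_points(video, tuple(p1), tuple(p2))
        tr = compensate_motion(refs)
        assert tr[-1, 1] == pytest.approx(-3.0, abs=0.3)
        assert tr[-1, 2] == pytest.approx(-4.0, abs=0.3)
        assert tr[-1, 0] == pytest.approx(0.0, abs=0.2)

    def test_transform_composed_with_inverse_is_identity(self):
        transform = np.array([7.5, 3.2, -1.4])
        pts = np.array([[10.0, 20.0], [55.5, 91.25]])
        fwd = apply_transform(pts, transform)
        phi = math.radians(-transform[0])
        ct, st = math.cos(phi), math.sin(phi)
        shifted = fwd - transform[1:]
        back = np.stack([ct * shifted[:, 0] - st * shifted[:, 1],
                         st * shifted[:, 0] + ct * shifted[:, 1]], axis=1)
        np.testing.assert_allclose(back, pts, atol=1e-6)


class TestEdgeDetection:
    def test_noise_free_edges_at_true_wall_rows(self, static_long):
        spec, video, truth = static_long
        cols = np.arange(40, 216)
        mid = (video.shape[0] - 1) / 2.0
        prev_u = np.full(len(cols), mid - spec.D0 / 2)
        prev_l = np.full(len(cols), mid + spec.D0 / 2)
        up, lo, ok = detect_edges_long(video.frames[0].astype(float),
                                       prev_u, prev_l, cols)
        assert ok.all()
        np.testing.assert_allclose(up, mid - spec.D0 / 2, atol=0.5)
        np.testing.assert_allclose(lo, mid + spec.D0 / 2, atol=0.5)

    def test_equal_gradient_peaks_break_toward_previous_edge(self):
        """Two identical dark-to-bright steps: the nearer one wins."""
        frame = np.full((64, 8), 20.0)
        frame[10:18] = 200.0   # upper wall
        frame[30:38] = 200.0   # lower-wall candidate near the previous edge
        frame[50:58] = 200.0   # identical candidate further away
        cols = np.arange(8)
        prev_u = np.full(8, 17.0)
        prev_l = np.full(8, 33.0)
        up, lo, ok = detect_edges_long(frame, prev_u, prev_l, cols,
                                       LongAxisConfig(edge_band=25))
        assert ok.all()
        assert np.all(np.abs(up - 17.5) < 2.0)
        assert np.all(np.abs(lo - 29.5) < 2.0)

    def test_uniform_frame_is_tracking_lost(self):
        frame = np.full((64, 32), 90.0)
        cols = np.arange(32)
        prev = np.full(32, 20.0), np.full(32, 44.0)
        with pytest.raises(TrackingLostError):
            detect_edges_long(frame, prev[0], prev[1], cols, frame_index=7)


class TestMidline:
    def test_horizontal_edges_give_flat_midline(self):
        cols = np.arange(100)
        up, lo = np.full(100, 40.0), np.full(100, 80.0)
        coeffs = estimate_midline(up, lo, cols, np.ones(100, bool), degree=2)
        assert np.polyval(coeffs, 50) == pytest.approx(60.0, abs=1e-9)
        assert np.all(np.abs(coeffs[:-1]) < 1e-6)

    def test_tilted_edges_recover_slope(self):
        cols = np.arange(100)
        up = 40.0 + 0.1 * cols
        lo = 80.0 + 0.1 * cols
        coeffs = estimate_midline(up, lo, cols, np.ones(100, bool), degree=1)
        assert coeffs[0] == pytest.approx(0.1, abs=1e-6)

    def test_curved_phantom_quadratic_coefficient_recovered(self):
        spec = PhantomSpec(view="long_axis", shape=(128, 256), D0=40.0,
                           midline_curv=8.0, psf_sigma=1.0, seed=0)
        video, truth = generate_long_axis(spec, PressureVolumeCurve(),
                                          _static_drivers(), 5, fps=FPS)
        p1, p2 = truth.reference_points[0]
        trace = run_long_axis(video, tuple(p1), tuple(p2))
        # generator works in x̂ = 2c/(cols-1) - 1, so c2_px = 8 * (2/255)²
        c2_true = spec.midline_curv * (2.0 / (video.shape[1] - 1)) ** 2
        assert trace.midline_coeffs[0][0] == pytest.approx(c2_true, rel=0.05)

    def test_insufficient_columns_error(self):
        cols = np.arange(10)
        ok = np.zeros(10, bool)
        ok[:2] = True
        with pytest.raises(InputError):
            estimate_midline(np.zeros(10), np.ones(10), cols, ok, degree=2)


class TestDiameters:
    def test_parallel_edges_give_constant_diameter(self):
        cols = np.arange(120)
        up, lo = np.full(120, 40.0), np.full(120, 80.0)
        coeffs = estimate_midline(up, lo, cols, np.ones(120, bool), 2)
        diam, ok, _ = compute_diameters(up, lo, coeffs, cols, n_stations=15)
        assert ok.all()
        np.testing.assert_allclose(diam, 40.0, atol=1e-6)

    def test_rigid_rotation_leaves_diameters_unchanged(self):
        """Edges tilted by 10 degrees still measure the true 40 px lumen."""
        cols = np.arange(200, dtype=float)
        slope = math.tan(math.radians(10.0))
        half = 20.0 / math.cos(math.radians(10.0))  # vertical half-spacing
        mid = 60.0 + slope * cols
        up, lo = mid - half, mid + half
        coeffs = estimate_midline(up, lo, cols, np.ones(200, bool), 1)
        diam, ok, _ = compute_diameters(up, lo, coeffs, cols, n_stations=11)
        np.testing.assert_allclose(diam[ok], 40.0, atol=0.2)

    def test_tapered_phantom_matches_linear_profile(self):
        spec = PhantomSpec(view="long_axis", shape=(128, 300), D0=40.0,
                           taper=0.2, psf_sigma=1.0, seed=0)
        video, truth = generate_long_axis(spec, PressureVolumeCurve(),
                                          _static_drivers(), 5, fps=FPS)
        p1, p2 = truth.reference_points[0]
        trace = run_long_axis(video, tuple(p1), tuple(p2))
        xhat = 2.0 * trace.station_cols / (video.shape[1] - 1) - 1.0
        expect = spec.D0 * (1.0 + spec.taper * xhat)
        ok = trace.station_ok[0]
        np.testing.assert_allclose(trace.diameters[0][ok], expect[ok], rtol=0.02)


class TestFullPipeline:
    def test_static_phantom_diameters_equal_d0(self, static_long):
        spec, video, truth = static_long
        p1, p2 = truth.reference_points[0]
        trace = run_long_axis(video, tuple(p1), tuple(p2))
        d = trace.diameters[trace.station_ok]
        np.testing.assert_allclose(d, spec.D0, atol=0.5)

    def test_dynamic_speckled_mae_under_two_percent(self, dynamic_long):
        spec, video, truth = dynamic_long
        p1, p2 = truth.reference_points[0]
        trace = run_long_axis(video, tuple(p1), tuple(p2))
        mae = np.nanmean(np.abs(trace.mean_diameter - truth.size_series))
        assert mae / spec.D0 < 0.02

    def test_time_reversal_consistency(self, dynamic_long):
        """Tracking backwards must agree with the forward trace within 1%."""
        spec, video, truth = dynamic_long
        sub = video.frames[:200]
        fwd_video = VideoSequence(sub, FPS)
        rev_video = VideoSequence(sub[::-1].copy(), FPS)
        p1, p2 = truth.reference_points[0]
        fwd = run_long_axis(fwd_video, tuple(p1), tuple(p2))
        p1r, p2r = truth.reference_points[199]
        rev = run_long_axis(rev_video, tuple(p1r), tuple(p2r))
        a = fwd.mean_diameter
        b = rev.mean_diameter[::-1]
        assert np.nanmean(np.abs(a - b) / a) < 0.01

    def test_translation_equivariance(self, dynamic_long):
        """Integer-shifting every frame shifts edges, not diameters."""
        spec, video, truth = dynamic_long
        sub = video.frames[:60]
        shifted = np.roll(sub, (6, 9), axis=(1, 2))
        p1, p2 = truth.reference_points[0]
        t0 = run_long_axis(VideoSequence(sub, FPS), tuple(p1), tuple(p2))
        t1 = run_long_axis(VideoSequence(shifted, FPS),
                           (p1[0] + 6, p1[1] + 9), (p2[0] + 6, p2[1] + 9))
        d0, d1 = t0.mean_diameter, t1.mean_diameter
        assert np.nanmax(np.abs(d0 - d1)) <= 0.1
        both = t0.col_ok & t1.col_ok
        np.testing.assert_allclose(t1.upper[both] - t0.upper[both], 6.0,
                                   atol=0.2)

    def test_speckle_stress_never_helps_on_average(self):
        """More speckle noise cannot reduce the mean tracking error."""
        maes = {0.15: [], 0.6: []}
        for sigma in maes:
            for seed in range(3):
                spec = _speckled_spec(speckle_sigma=sigma, seed=seed,
                                      shape=(128, 192))
                video, truth = generate_long_axis(
                    spec, PressureVolumeCurve(),
                    PressureDrivers(A_resp=4.5), 90, fps=FPS)
                p1, p2 = truth.reference_points[0]
                trace = run_long_axis(video, tuple(p1), tuple(p2))
                maes[sigma].append(np.nanmean(
                    np.abs(trace.mean_diameter - truth.size_series)))
        assert np.mean(maes[0.6]) >= np.mean(maes[0.15])
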