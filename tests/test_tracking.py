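"""Contour tracking and strain: recovery against cine ground truth."""

import numpy as np
import pytest

from cmrmulti.synthetic import CineSpec, circle_contour, simulate_cine
from cmrmulti.tracking import (
    StrainCurve,
    TrackedContour,
    global_strain,
    peak_value,
    strain_from_contour,
    track_contour,
)
from tests.conftest import sine_squared_strain


def circle_tracked(radii, n_points=48, dt_ms=33.0, center=(64.0, 64.0)):
    """Analytic tracked contour: circles of given per-frame radii."""
    pts = np.array(
        [np.asarray(circle_contour(center, r, n_points)) for r in radii]
    )
    times = np.arange(len(radii)) * dt_ms
    return TrackedContour(points=pts, frame_times=times, closed=True)


class TestTrackContour:
    def test_static_frames_give_zero_displacement(self):
        spec = CineSpec(
            n_frames=6,
            contour=circle_contour((64.0, 64.0), 25.0, 48),
            strain_curve=(0.0,) * 6,
        )
        cine = simulate_cine(spec)
        tracked = track_contour(cine.frames, cine.contours[0])
        for t in range(6):
            np.testing.assert_allclose(tracked.points[t], tracked.points[0], atol=1e-9)

    def test_pure_translation_recovered(self):
        # rigid drift of (0.8, -0.6) px/frame, noiseless; no cyclic closure
        # since the motion deliberately does not return to start
        n = 8
        trans = tuple((0.8 * t, -0.6 * t) for t in range(n))
        spec = CineSpec(
            n_frames=n,
            contour=circle_contour((50.0, 70.0), 22.0, 48),
            strain_curve=(0.0,) * n,
            translation=trans,
        )
        cine = simulate_cine(spec)
        tracked = track_contour(cine.frames, cine.contours[0], cyclic_closure=False)
        for t in range(1, n):
            disp = (tracked.points[t] - tracked.points[t - 1]).mean(axis=0)
            assert abs(disp[0] - 0.8) < 0.2
            assert abs(disp[1] + 0.6) < 0.2

    def test_contracting_ring_strain_recovered(self, contracting_cine):
        tracked = track_contour(
            contracting_cine.frames,
            contracting_cine.contours[0],
            frame_times=contracting_cine.frame_times,
        )
        curve = strain_from_contour(tracked)
        assert abs(peak_value(curve.epsilon) - (-25.0)) < 2.0

    def test_cyclic_closure_returns_to_start(self, contracting_cine):
        tracked = track_contour(
            contracting_cine.frames,
            contracting_cine.contours[0],
            frame_times=contracting_cine.frame_times,
        )
        rms = np.sqrt(np.mean(np.sum((tracked.points[-1] - tracked.points[0]) ** 2, axis=1)))
        # the last tracked frame is one step before closing the cycle; after
        # drift redistribution it must sit within the closure tolerance of
        # the end-diastolic contour (plus one frame of true motion)
        true_last = contracting_cine.contours[-1]
        rms_truth = np.sqrt(
            np.mean(np.sum((tracked.points[-1] - true_last) ** 2, axis=1))
        )
        assert rms_truth < 0.5 or rms < 0.5

    def test_rigid_motion_changes_strain_little(self):
        base = simulate_cine(
            CineSpec(
                n_frames=16,
                contour=circle_contour((64.0, 64.0), 24.0, 48),
                strain_curve=sine_squared_strain(16, -20.0),
                noise_sd=1.0,
                seed=3,
            )
        )
        # the same rigid offset applied to every frame: the deformation is
        # unchanged, so the strain curve must be too
        moved = simulate_cine(
            CineSpec(
                n_frames=16,
                contour=circle_contour((64.0, 64.0), 24.0, 48),
                strain_curve=sine_squared_strain(16, -20.0),
                translation=((7.3, -4.6),) * 16,
                noise_sd=1.0,
                seed=3,
            )
        )
        eps_a = strain_from_contour(track_contour(base.frames, base.contours[0])).epsilon
        eps_b = strain_from_contour(track_contour(moved.frames, moved.contours[0])).epsilon
        assert np.max(np.abs(eps_a - eps_b)) < 0.5

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            track_contour(np.zeros((1, 32, 32)), np.zeros((20, 2)))


class TestStrainFromContour:
    def test_radius_30_to_21_is_minus_30_percent(self):
        curve = strain_from_contour(circle_tracked([30.0, 21.0]))
        np.testing.assert_allclose(curve.epsilon, [0.0, -30.0], atol=1e-9)

    def test_constant_contour_zero_strain_and_rate(self):
        curve = strain_from_contour(circle_tracked([25.0] * 5))
        assert np.all(curve.epsilon == 0.0)
        assert np.all(curve.strain_rate == 0.0)

    def test_strain_rate_matches_analytic_derivative(self):
        # eps(t) = -25 sin^2(pi t / T) %: d(eps_frac)/dt peaks at 0.25*pi/T
        n, cycle_s = 30, 1.0
        t = np.arange(n) / n * cycle_s
        radii = 25.0 * (1 - 0.25 * np.sin(np.pi * t / cycle_s) ** 2)
        tracked = circle_tracked(radii, dt_ms=1000.0 * cycle_s / n)
        curve = strain_from_contour(tracked)
        peak_sr = np.min(curve.strain_rate)
        analytic = -0.25 * np.pi / cycle_s
        assert abs(peak_sr - analytic) / abs(analytic) < 0.05

    def test_zero_length_contour_rejected(self):
        pts = np.zeros((3, 20, 2))
        tracked = TrackedContour(points=pts, frame_times=np.arange(3.0) + 1.0)
        with pytest.raises(ValueError):
            strain_from_contour(tracked)


class TestGlobalStrain:
    def _curve(self, peak, chamber="LV"):
        eps = np.array([0.0, peak / 2, peak, peak / 2])
        return StrainCurve(
            epsilon=eps,
            strain_rate=np.zeros(4),
            frame_times=np.arange(4.0) * 33.0,
            kind="circumferential",
            chamber=chamber,
        )

    def test_mean_of_slice_peaks(self):
        curves = [self._curve(p) for p in (-24.0, -26.0, -28.0)]
        summary = global_strain(circumferential=curves)
        assert summary.gcs_lv == -26.0

    def test_all_zero_curves_give_zero_summary(self):
        curves = [self._curve(0.0) for _ in range(3)]
        summary = global_strain(circumferential=curves)
        assert summary.gcs_lv == 0.0
        assert summary.peak_sr["circumferential_LV"] == 0.0

    def test_identical_curves_equal_single_slice_peak(self):
        curves = [self._curve(-22.0) for _ in range(3)]
        summary = global_strain(circumferential=curves)
        assert summary.gcs_lv == -22.0

    def test_longitudinal_from_single_four_chamber_curve(self):
        lv = self._curve(-17.0)
        lv.kind = "longitudinal"
        summary = global_strain(longitudinal={"LV": lv})
        assert summary.gls_lv == -17.0
        assert summary.gcs_lv is None

    def test_missing_slice_warns_but_computes(self):
        curves = [self._curve(-24.0), self._curve(-28.0)]
        with pytest.warns(UserWarning):
            summary = global_strain(circumferential=curves)
        assert summary.gcs_lv == -26.0

    def test_peak_is_signed_extremum(self):
        assert peak_value(np.array([0.0, 3.0, -10.0, 2.0])) == -10.0
        assert peak_value(np.array([0.0, 11.0, -10.0])) == 11.0
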