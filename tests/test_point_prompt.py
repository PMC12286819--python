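"""Point-prompt stage: scan lines, derivative profiles, boundary extrema."""

import numpy as np
import pytest

from laryngoseg import binarize, glottis_landmarks, phantom
from laryngoseg.glottis import GlottisLandmarks
from laryngoseg.point_prompt import (
    assemble_point_prompts,
    boundary_points,
    build_point_prompts,
    build_scan_lines,
    derivative_profile,
)


def _vertical_landmarks():
    return GlottisLandmarks(
        top=np.array([50.0, 20.0]),
        middle=np.array([50.0, 60.0]),
        bottom=np.array([50.0, 100.0]),
        axis_angle_deg=0.0,
    )


class TestScanLines:
    def test_vertical_axis_anchors_and_direction(self):
        lines = build_scan_lines(_vertical_landmarks(), (128, 128))
        anchors = [line.anchor for line in lines]
        assert np.allclose(anchors, [(50, 40), (50, 60), (50, 80)])
        for line in lines:
            assert np.allclose(line.direction, (1.0, 0.0))

    def test_orthogonality_for_tilted_axis(self, tilted_frame):
        lm = glottis_landmarks(tilted_frame.gt_glottis)
        for line in build_scan_lines(lm, tilted_frame.image.shape):
            assert abs(np.dot(line.direction, lm.axis_vector)) < 1e-6
            # anchor collinear with top and bottom
            d = lm.axis_vector / np.hypot(*lm.axis_vector)
            rel = line.anchor - lm.top
            assert abs(rel[0] * d[1] - rel[1] * d[0]) < 1e-9

    def test_degenerate_axis_rejected(self):
        lm = GlottisLandmarks(
            top=np.array([5.0, 5.0]),
            middle=np.array([5.0, 5.0]),
            bottom=np.array([5.0, 5.0]),
            axis_angle_deg=0.0,
        )
        with pytest.raises(ValueError):
            build_scan_lines(lm, (64, 64))


class TestDerivativeProfile:
    def _line(self, shape=(128, 128)):
        return build_scan_lines(_vertical_landmarks(), shape)[1]

    def test_constant_image_zero_derivative(self):
        img = np.full((128, 128), 90, dtype=np.uint8)
        glottis = np.zeros((128, 128), dtype=bool)
        glottis[55:66, 45:56] = True
        prof = derivative_profile(img, self._line(), glottis)
        assert np.abs(prof.derivative).max() < 1e-9

    def test_linear_ramp_unit_derivative(self):
        img = np.tile(np.arange(128, dtype=float), (128, 1))
        glottis = np.zeros((128, 128), dtype=bool)
        glottis[55:66, 45:56] = True
        prof = derivative_profile(img, self._line(), glottis)
        assert np.allclose(prof.derivative[5:-5], 1.0, atol=1e-6)

    def test_step_edge_localized_within_smoothing_halfwidth(self):
        img = np.zeros((128, 128), dtype=float)
        edge_x = 85
        img[:, edge_x:] = 200.0
        glottis = np.zeros((128, 128), dtype=bool)
        glottis[55:66, 45:56] = True
        smooth_window = 5
        prof = derivative_profile(img, self._line(), glottis, smooth_window)
        peak_station = prof.line.stations[np.argmax(prof.derivative)]
        edge_station = edge_x - prof.line.anchor[0]
        assert abs(peak_station - edge_station) <= (smooth_window - 1) / 2 + 1

    def test_even_window_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            derivative_profile(img, self._line((16, 16)), np.zeros((16, 16), bool), 4)


class TestBoundaryPoints:
    def test_recovers_outer_boundaries_on_phantom(self, default_frame):
        prob = phantom.emulate_probability_map(default_frame, seed=0)
        glottis = binarize(prob, 0.5)
        lm = glottis_landmarks(glottis)
        for line in build_scan_lines(lm, default_frame.image.shape):
            prof = derivative_profile(default_frame.image, line, glottis)
            left, right = boundary_points(prof)
            row = int(round(left[1]))
            lo, _li, _ri, ro = default_frame.analytic_boundaries[row]
            assert abs(left[0] - lo) <= 2.0
            assert abs(right[0] - ro) <= 2.0

    def test_symmetric_phantom_gives_symmetric_points(self, default_frame):
        prob = phantom.emulate_probability_map(default_frame, seed=0)
        glottis = binarize(prob, 0.5)
        lm = glottis_landmarks(glottis)
        cx = default_frame.params.center[0]
        for line in build_scan_lines(lm, default_frame.image.shape):
            prof = derivative_profile(default_frame.image, line, glottis)
            left, right = boundary_points(prof)
            assert abs((left[0] - cx) + (right[0] - cx)) <= 1.0

    def test_flat_background_yields_no_points(self):
        img = np.full((128, 128), 60, dtype=np.uint8)
        img[55:66, 45:56] = 20  # dark glottis only, no fold contrast... edges!
        glottis = img == 20
        lm = glottis_landmarks(glottis)
        line = build_scan_lines(lm, img.shape)[1]
        prof = derivative_profile(img, line, glottis)
        left, right = boundary_points(prof)
        # the only extrema are the glottis edges themselves: the left edge is
        # a falling/ rising pair oriented so no qualifying max lies left of
        # the glottis run and no qualifying min right of it
        assert left is None and right is None

    def test_missing_interval_raises(self):
        img = np.zeros((64, 64))
        lm = _vertical_landmarks()
        line = build_scan_lines(lm, (64, 64))[0]
        prof = derivative_profile(img, line, np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValueError):
            boundary_points(prof)

    def test_points_flank_the_glottis_interval(self, tilted_frame):
        prob = phantom.emulate_probability_map(tilted_frame, seed=1)
        glottis = binarize(prob, 0.5)
        lm = glottis_landmarks(glottis)
        for line in build_scan_lines(lm, tilted_frame.image.shape):
            prof = derivative_profile(tilted_frame.image, line, glottis)
            if prof.glottis_interval is None:
                continue
            i0, i1 = prof.glottis_interval
            left, right = boundary_points(prof)
            if left is not None:
                s_left = np.dot(left - line.anchor, line.direction)
                assert s_left < line.stations[i0]
            if right is not None:
                s_right = np.dot(right - line.anchor, line.direction)
                assert s_right > line.stations[i1]


class TestBoundaryRecoverySweep:
    @pytest.mark.parametrize("angle", [-20.0, 0.0, 20.0])
    @pytest.mark.parametrize("sigma", [0.0, 5.0])
    def test_mean_error_within_two_pixels(self, angle, sigma):
        errs = []
        params = phantom.PhantomParams(
            axis_angle_deg=angle, noise_sigma=sigma, seed=13,
            osc_amplitude=3.0, osc_frequency=0.13,
        )
        for t in range(8):
            frame = phantom.generate_frame(params, t)
            prob = phantom.emulate_probability_map(frame, seed=1)
            glottis = binarize(prob, 0.5)
            lm = glottis_landmarks(glottis)
            for line in build_scan_lines(lm, frame.image.shape):
                prof = derivative_profile(frame.image, line, glottis)
                if prof.glottis_interval is None:
                    continue
                left, right = boundary_points(prof)
                for pt, idx in ((left, 0), (right, 3)):
                    if pt is None:
                        continue
                    row = int(round(pt[1]))
                    if row in frame.analytic_boundaries:
                        errs.append(abs(pt[0] - frame.analytic_boundaries[row][idx]))
        assert len(errs) >= 30
        assert np.mean(errs) <= 2.0


class TestRotationEquivariance:
    def test_points_track_a_rigid_rotation_of_the_scene(self):
        """Rotating image + masks rotates the extracted points (<= 1.5 px)."""
        from scipy import ndimage

        from laryngoseg.box_prompt import RigidTransform

        frame = phantom.generate_frame(phantom.PhantomParams(), 0)
        prob = phantom.emulate_probability_map(frame, noise_rate=0.0)
        glottis = binarize(prob, 0.5)
        pts0 = _extract(frame.image, glottis)

        tf = RigidTransform(20.0, np.array([128.0, 128.0]), np.zeros(2))
        h, w = frame.image.shape
        ys, xs = np.mgrid[0:h, 0:w]
        src = tf.apply_inverse(
            np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        )
        image_rot = ndimage.map_coordinates(
            frame.image.astype(float), [src[:, 1], src[:, 0]], order=1,
            mode="nearest",
        ).reshape(h, w)
        glottis_rot = tf.warp_mask(glottis)
        pts1 = _extract(image_rot, glottis_rot)
        assert pts0.shape == pts1.shape
        expected = tf.apply(pts0)
        assert np.abs(expected - pts1).max() <= 1.5


def _extract(image, glottis):
    lm = glottis_landmarks(glottis)
    return build_point_prompts(image, glottis, lm).points


class TestAssemble:
    def test_full_prompt_has_nine_points(self, default_frame):
        prob = phantom.emulate_probability_map(default_frame, seed=0)
        glottis = binarize(prob, 0.5)
        lm = glottis_landmarks(glottis)
        prompt = build_point_prompts(default_frame.image, glottis, lm)
        assert len(prompt) == 9
        assert sum(t.startswith("boundary") for t in prompt.provenance) == 6
        assert (prompt.labels == 1).all()

    def test_counts_with_missing_sides(self):
        lm = _vertical_landmarks()
        p = np.array([10.0, 40.0])
        full = [(p, p), (p, p), (p, p)]
        assert len(assemble_point_prompts(full, lm)) == 9
        assert len(assemble_point_prompts([(None, None)] * 3, lm)) == 3
        one_absent = [(p, p), (p, None), (p, p)]
        assert len(assemble_point_prompts(one_absent, lm)) == 8
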