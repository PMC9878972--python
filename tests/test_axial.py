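"""Axial metrics (brightfield, astigmatism, double-helix) and calibration."""

import numpy as np
import pytest

from logradient.axial import (
    CalibrationCurve,
    apply_calibration,
    build_calibration,
    z_value_astigmatism,
    z_value_brightfield,
    z_value_doublehelix,
)
from logradient.errors import (
    CalibrationRangeError,
    ExtrapolationError,
    InsufficientDataError,
    NoParticleError,
    OutOfBoundsError,
    UndefinedOrientationError,
)
from logradient.gradients import local_gradients, magnitude, precompute_transforms
from logradient.synthetic import (
    render_astigmatic,
    render_bead_defocus,
    render_doublehelix,
    render_gaussian_spot,
)

BEAD_SHAPE = (128, 128)
BEAD_CENTER = (63.5, 63.5)


def bead_field(z, r=35):
    img = render_bead_defocus(BEAD_SHAPE, *BEAD_CENTER, z)
    return local_gradients(img, r)


class TestBrightfieldZ:
    def test_zero_at_focal_contrast_crossing(self):
        assert z_value_brightfield(bead_field(0.0), BEAD_CENTER) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_invariance(self):
        img = render_bead_defocus(BEAD_SHAPE, *BEAD_CENTER, 300.0)
        fld = local_gradients(img, 35)
        v = z_value_brightfield(fld, BEAD_CENTER)
        vx = z_value_brightfield(local_gradients(img[:, ::-1], 35), BEAD_CENTER)
        vy = z_value_brightfield(local_gradients(img[::-1, :], 35), BEAD_CENTER)
        assert vx == pytest.approx(v, rel=1e-9, abs=1e-9)
        assert vy == pytest.approx(v, rel=1e-9, abs=1e-9)

    def test_contrast_inversion_flips_sign(self):
        # bright<->dark ring inversion == the model's -z image
        v_pos = z_value_brightfield(bead_field(+400.0), BEAD_CENTER)
        v_neg = z_value_brightfield(bead_field(-400.0), BEAD_CENTER)
        assert v_pos * v_neg < 0

    def test_strictly_monotonic_over_stack(self):
        pc = precompute_transforms(BEAD_SHAPE, 35)
        zs = np.linspace(-500, 500, 101)
        vals = []
        for z in zs:
            img = render_bead_defocus(BEAD_SHAPE, *BEAD_CENTER, z)
            fld = local_gradients(img, 35, precomputed=pc)
            vals.append(z_value_brightfield(fld, BEAD_CENTER))
        d = np.diff(vals)
        assert np.all(d > 0) or np.all(d < 0)

    def test_center_outside_raster(self):
        with pytest.raises(OutOfBoundsError):
            z_value_brightfield(bead_field(100.0), (2.0, 2.0))


class TestAstigmatismZ:
    @staticmethod
    def metric(img, center, r=10, thr=0.5):
        fld = local_gradients(img, r)
        return z_value_astigmatism(fld, magnitude(fld, thr), center)

    def test_in_focus_round_psf_is_zero(self):
        img = render_astigmatic((100, 100), 49.5, 49.5, 0.0)
        assert abs(self.metric(img, (49.5, 49.5))) < 0.05

    def test_rot90_negates(self):
        img = render_astigmatic((100, 100), 49.5, 49.5, 300.0)
        v = self.metric(img, (49.5, 49.5))
        v_rot = self.metric(np.rot90(img), (49.5, 49.5))
        assert v_rot == pytest.approx(-v, rel=1e-6)

    def test_plus_minus_z_antisymmetric(self):
        vp = self.metric(render_astigmatic((100, 100), 49.5, 49.5, 250.0), (49.5, 49.5))
        vm = self.metric(render_astigmatic((100, 100), 49.5, 49.5, -250.0), (49.5, 49.5))
        assert vm == pytest.approx(-vp, rel=1e-6)

    def test_strictly_monotonic_over_stack(self):
        pc = precompute_transforms((100, 100), 10)
        zs = np.linspace(-500, 500, 101)
        vals = []
        for z in zs:
            img = render_astigmatic((100, 100), 49.5, 49.5, z)
            fld = local_gradients(img, 10, precomputed=pc)
            vals.append(z_value_astigmatism(fld, magnitude(fld, 0.5), (49.5, 49.5)))
        d = np.diff(vals)
        assert np.all(d > 0) or np.all(d < 0)

    def test_starved_half_plane_raises(self):
        img = render_astigmatic((100, 100), 49.5, 49.5, 0.0)
        fld = local_gradients(img, 10)
        with pytest.raises(InsufficientDataError):
            z_value_astigmatism(fld, magnitude(fld, 0.5), (10.0, 10.0))


class TestDoubleHelixZ:
    def test_horizontal_lobes_give_zero_angle(self):
        img = render_doublehelix((80, 80), 39.5, 39.5, 0.0)
        assert abs(z_value_doublehelix(img, 15, 1 / 1.3)) < 0.5

    def test_45_degree_axis(self):
        # rot_rate 0.1 deg/nm -> 45 deg at z=450
        img = render_doublehelix((80, 80), 39.5, 39.5, 450.0)
        assert z_value_doublehelix(img, 15, 1 / 1.3) == pytest.approx(45.0, abs=1.0)

    def test_rot90_shifts_angle_by_90(self):
        img = render_doublehelix((80, 80), 39.5, 39.5, 300.0)
        th = z_value_doublehelix(img, 15, 1 / 1.3)
        th_rot = z_value_doublehelix(np.rot90(img), 15, 1 / 1.3)
        delta = (th_rot - th) % 180.0
        assert min(delta, 180 - delta) == pytest.approx(90.0, abs=1.0)

    def test_linear_in_z_across_stack(self):
        zs = np.arange(-750, 751, 10.0)
        pc = precompute_transforms((80, 80), 15)
        th = [
            z_value_doublehelix(render_doublehelix((80, 80), 39.5, 39.5, z), 15, 1 / 1.3,
                                precomputed=pc)
            for z in zs
        ]
        th = np.unwrap(np.array(th), period=180.0)
        slope, intercept = np.polyfit(zs, th, 1)
        resid = th - (slope * zs + intercept)
        assert np.sqrt(np.mean(resid**2)) < 1.0
        assert slope == pytest.approx(0.1, rel=0.02)

    def test_blank_image_raises(self):
        with pytest.raises(NoParticleError):
            z_value_doublehelix(np.full((64, 64), 1.0), 15, 1 / 1.3)

    def test_isotropic_raises_undefined_orientation(self):
        # a centered circular spot on an odd raster has an exactly isotropic
        # moment tensor
        img = render_gaussian_spot((65, 65), 32.0, 32.0, 4.0, background=0.1)
        with pytest.raises(UndefinedOrientationError):
            z_value_doublehelix(img, 10, 1 / 1.3)


class TestCalibration:
    @staticmethod
    def astig_stack(n=21, zmax=400.0):
        zs = np.linspace(-zmax, zmax, n)
        return [render_astigmatic((100, 100), 49.5, 49.5, z) for z in zs], zs

    def test_lookup_round_trips_nodes_exactly(self):
        stack, zs = self.astig_stack()
        curve = build_calibration(stack, zs, metric="astig", r=10, threshold_frac=0.5)
        assert curve.mode == "lut" and len(curve.stage_z) == 21
        for z, v in zip(curve.stage_z, curve.values):
            assert apply_calibration(curve, v) == pytest.approx(z, abs=1e-9)

    def test_midpoint_interpolation(self):
        curve = CalibrationCurve(stage_z=np.array([0.0, 100.0]), values=np.array([1.0, 3.0]))
        assert apply_calibration(curve, 2.0) == pytest.approx(50.0)

    def test_extrapolation_refused(self):
        curve = CalibrationCurve(stage_z=np.array([0.0, 100.0]), values=np.array([1.0, 3.0]))
        with pytest.raises(ExtrapolationError):
            apply_calibration(curve, 3.5)

    def test_linear_fit_mode(self):
        # +-500 nm scan at 100 nm steps: 11 nodes plus slope/intercept
        zs = np.arange(-500.0, 501.0, 100.0)
        stack = [render_astigmatic((100, 100), 49.5, 49.5, z) for z in zs]
        curve = build_calibration(stack, zs, metric="astig", r=10, threshold_frac=0.5,
                                  mode="linear")
        assert len(curve.stage_z) == 11
        assert curve.fit_slope is not None and curve.fit_intercept is not None
        v = curve.fit_slope * 120.0 + curve.fit_intercept
        assert apply_calibration(curve, v) == pytest.approx(120.0, abs=1e-9)

    def test_two_plane_stack_rejected(self):
        stack, zs = self.astig_stack(n=21)
        with pytest.raises(CalibrationRangeError):
            build_calibration(stack[:2], zs[:2], metric="astig", r=10, threshold_frac=0.5)

    def test_non_monotonic_values_rejected_with_interval(self):
        stack, zs = self.astig_stack(n=9, zmax=200.0)
        shuffled = stack[:4] + [stack[7]] + stack[5:8] + [stack[4]]
        with pytest.raises(CalibrationRangeError, match="between z="):
            build_calibration(shuffled, zs, metric="astig", r=10, threshold_frac=0.5)

    def test_json_round_trip(self, tmp_path):
        stack, zs = self.astig_stack(n=11)
        curve = build_calibration(stack, zs, metric="astig", r=10, threshold_frac=0.5)
        path = tmp_path / "cal.json"
        curve.to_json(path)
        back = CalibrationCurve.from_json(path)
        np.testing.assert_allclose(back.stage_z, curve.stage_z)
        np.testing.assert_allclose(back.values, curve.values)
        assert back.mode == curve.mode and back.metric == "astig"

    def test_dh_calibration_unwraps_angles(self):
        zs = np.linspace(-700, 700, 29)
        stack = [render_doublehelix((80, 80), 39.5, 39.5, z) for z in zs]
        curve = build_calibration(stack, zs, metric="dh", r=15, threshold_frac=1 / 1.3)
        d = np.diff(curve.values)
        assert np.all(d > 0) or np.all(d < 0)
        assert np.ptp(curve.values) > 120  # unwrapped past the +-90 principal range
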