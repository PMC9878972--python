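"""Synthetic renderers: geometry, discretization, noise model, determinism."""

import numpy as np
import pytest

from logradient.axial import z_value_brightfield
from logradient.errors import InvalidParameterError, RangeError
from logradient.gradients import local_gradients
from logradient.localize import localize
from logradient.synthetic import (
    BeadParams,
    NoiseModel,
    SyntheticScene,
    add_noise,
    render_astigmatic,
    render_bead_defocus,
    render_doublehelix,
    render_gaussian_spot,
)


class TestGaussianSpot:
    def test_peak_position_and_value(self):
        img = render_gaussian_spot((100, 100), 50.0, 50.0, 3.0, amplitude=1.0)
        assert np.unravel_index(np.argmax(img), img.shape) == (50, 50)
        assert img[50, 50] == pytest.approx(1.0, rel=0.02)

    def test_supersampling_convergence(self):
        a = render_gaussian_spot((40, 40), 20.3, 19.6, 3.0, supersample=4)
        b = render_gaussian_spot((40, 40), 20.3, 19.6, 3.0, supersample=16)
        assert np.abs(a - b).max() < 1e-3

    def test_fully_outside_warns_and_returns_background(self):
        with pytest.warns(UserWarning):
            img = render_gaussian_spot((50, 50), 200.0, 200.0, 2.0, background=0.3)
        np.testing.assert_allclose(img, 0.3)

    def test_invalid_sigma(self):
        with pytest.raises(InvalidParameterError):
            render_gaussian_spot((50, 50), 25, 25, -1.0)


class TestBeadDefocus:
    def test_radially_symmetric_at_every_z(self):
        for z in (-400.0, 150.0, 500.0):
            img = render_bead_defocus((121, 121), 60.0, 60.0, z)
            np.testing.assert_allclose(img, np.rot90(img), atol=1e-3)

    def test_flat_at_focal_crossing_gives_zero_metric(self):
        img = render_bead_defocus((128, 128), 63.5, 63.5, 0.0)
        fld = local_gradients(img, 20)
        assert z_value_brightfield(fld, (63.5, 63.5)) == pytest.approx(0.0, abs=1e-9)

    def test_contrast_inversion_through_focus(self):
        p = BeadParams()
        up = render_bead_defocus((100, 100), 49.5, 49.5, 300.0, p)
        dn = render_bead_defocus((100, 100), 49.5, 49.5, -300.0, p)
        np.testing.assert_allclose(up - p.background, -(dn - p.background), atol=1e-12)

    def test_out_of_range_z(self):
        with pytest.raises(RangeError):
            render_bead_defocus((100, 100), 49.5, 49.5, 600.0)

    def test_round_trip_localization(self):
        rng = np.random.default_rng(50)
        errs = []
        for _ in range(10):
            x0, y0 = rng.uniform(55, 75, 2)
            z = rng.uniform(150, 500) * rng.choice([-1, 1])
            img = render_bead_defocus((128, 128), x0, y0, z)
            loc = localize(img, 35, 1 / 1.5, normalize=False)
            errs.append(np.hypot(loc.x - x0, loc.y - y0))
        assert np.mean(errs) < 0.05


class TestAstigmatic:
    def test_round_in_focus(self):
        img = render_astigmatic((100, 100), 49.5, 49.5, 0.0)
        np.testing.assert_allclose(img, img.T, atol=1e-12)

    def test_plus_minus_z_related_by_90_rotation(self):
        up = render_astigmatic((100, 100), 49.5, 49.5, 300.0)
        dn = render_astigmatic((100, 100), 49.5, 49.5, -300.0)
        np.testing.assert_allclose(up, np.rot90(dn), atol=1e-9)

    def test_clipping_raises_range_error(self):
        with pytest.raises(RangeError):
            render_astigmatic((100, 100), 49.5, 49.5, 900.0)

    def test_round_trip_localization_in_focus(self):
        rng = np.random.default_rng(60)
        errs = []
        for _ in range(10):
            x0, y0 = rng.uniform(40, 60, 2)
            img = render_astigmatic((100, 100), x0, y0, 0.0)
            loc = localize(img, 10, 0.5)
            errs.append(np.hypot(loc.x - x0, loc.y - y0))
        assert np.mean(errs) < 0.05


class TestDoubleHelix:
    def test_midpoint_symmetry(self):
        # equal lobes -> image invariant under 180-degree rotation about center
        img = render_doublehelix((80, 80), 39.5, 39.5, 330.0)
        np.testing.assert_allclose(img, img[::-1, ::-1], atol=1e-9)

    def test_zero_z_lobes_horizontal(self):
        img = render_doublehelix((81, 81), 40.0, 40.0, 0.0)
        rows, cols = np.unravel_index(np.argsort(img.ravel())[-2:], img.shape)
        assert set(rows) == {40}
        assert sorted(cols) == [30, 50]  # +-lobe_sep/2 around x0

    def test_angle_out_of_range(self):
        with pytest.raises(RangeError):
            render_doublehelix((80, 80), 39.5, 39.5, 901.0)  # 90.1 deg

    def test_round_trip_localization_of_midpoint(self):
        rng = np.random.default_rng(70)
        errs = []
        for _ in range(10):
            x0, y0 = rng.uniform(35, 45, 2)
            z = rng.uniform(-700, 700)
            img = render_doublehelix((80, 80), x0, y0, z)
            loc = localize(img, 15, 1 / 1.3, normalize=False)
            errs.append(np.hypot(loc.x - x0, loc.y - y0))
        assert np.mean(errs) < 0.3 and np.max(errs) < 0.5


class TestNoise:
    def test_additive_gaussian_sigma_matches_definition(self):
        img = np.full((128, 128), 2.0)  # max signal 2.0 -> sigma = 2/snr
        noisy = add_noise(img, NoiseModel(snr=5.0), seed=11)
        assert noisy.std() == pytest.approx(2.0 / 5.0, rel=0.05)

    def test_infinite_snr_limit(self):
        img = render_gaussian_spot((64, 64), 32, 32, 3.0)
        noisy = add_noise(img, NoiseModel(snr=1e12), seed=1)
        assert np.abs(noisy - img).max() < 1e-6

    def test_seeded_determinism(self):
        img = render_gaussian_spot((64, 64), 30.2, 33.8, 3.0)
        a = add_noise(img, NoiseModel(snr=5), seed=42)
        b = add_noise(img, NoiseModel(snr=5), seed=42)
        np.testing.assert_array_equal(a, b)
        c = add_noise(img, NoiseModel(snr=5), seed=43)
        assert not np.array_equal(a, c)

    def test_poisson_peak_snr(self):
        img = np.full((200, 200), 4.0)
        noisy = add_noise(img, NoiseModel(kind="poisson", snr=10.0), seed=3)
        # peak expectation snr^2 counts -> relative std 1/snr at the peak
        assert noisy.std() / 4.0 == pytest.approx(0.1, rel=0.05)
        assert noisy.mean() == pytest.approx(4.0, rel=0.01)

    def test_invalid_noise_params(self):
        with pytest.raises(InvalidParameterError):
            NoiseModel(kind="speckle", snr=5)
        with pytest.raises(InvalidParameterError):
            NoiseModel(snr=0.0)


class TestScene:
    def test_bit_reproducible_rendering(self):
        sc = SyntheticScene(shape=(80, 80), noise=NoiseModel(snr=10), seed=5)
        sc.add("spot", 30.5, 40.2, amplitude=1.0, sigma=3.0)
        sc.add("spot", 60.1, 20.9, amplitude=0.8, sigma=3.0)
        np.testing.assert_array_equal(sc.render(), sc.render())

    def test_noiseless_max_at_brightest_particle(self):
        sc = SyntheticScene(shape=(80, 80))
        sc.add("spot", 30.0, 40.0, amplitude=1.0, sigma=3.0)
        sc.add("spot", 60.0, 20.0, amplitude=0.5, sigma=3.0)
        img = sc.render(noiseless=True)
        assert np.unravel_index(np.argmax(img), img.shape) == (40, 30)

    def test_ground_truth_table(self):
        sc = SyntheticScene().add("spot", 10, 20).add("dh", 30, 40, z=100.0)
        gt = sc.ground_truth()
        assert list(gt["model"]) == ["spot", "dh"]
        assert gt.loc[1, "z"] == 100.0
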