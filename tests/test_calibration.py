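import numpy as np
import pytest

from prawnvision.calibration import (
    LinearisationCurve,
    MultispectralImage,
    StandardPatch,
    equalise,
    extract_roi,
    fit_linearisation,
    linearise,
    read_multispectral_tiff,
    write_multispectral_tiff,
)
from prawnvision.synthetic import green_prawn_model, render_fixture, sample_reflectance

NOMINALS = (0.02, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.99)


def _calibrate(fixture):
    """Full standard-based workflow: fit linearisation from the grey patches,
    linearise, then equalise with the dark/light standards."""
    img = fixture.image
    samples = {
        ch: [
            (float(img.data[fixture.masks[name], i].mean()), nominal)
            for name, nominal in fixture.linearisation_nominals.items()
        ]
        for i, ch in enumerate(img.channel_names)
    }
    curve = fit_linearisation(samples)
    lin = linearise(img, curve)
    eq = equalise(
        lin,
        StandardPatch(0.085, fixture.masks[fixture.dark_name]),
        StandardPatch(0.95, fixture.masks[fixture.light_name]),
    )
    return curve, lin, eq


class TestFitLinearisation:
    def test_linear_samples_give_near_zero_residuals(self):
        px = np.array(NOMINALS) * 1000.0
        samples = {"g": list(zip(px, NOMINALS))}
        curve = fit_linearisation(samples)
        np.testing.assert_allclose(curve.map_values("g", px), NOMINALS, rtol=1e-8)

    def test_gamma_encoded_samples_recovered_within_one_percent(self):
        """Pixel = reflectance^(1/2.2) * 255 is exactly inverted by the
        log-space fit; the analytic inverse is the oracle."""
        refl = np.array(NOMINALS)
        px = refl ** (1 / 2.2) * 255.0
        curve = fit_linearisation({"g": list(zip(px, refl))})
        test_px = np.linspace(px.min(), px.max(), 50)
        analytic = (test_px / 255.0) ** 2.2
        np.testing.assert_allclose(curve.map_values("g", test_px), analytic, atol=0.01)

    def test_three_samples_insufficient(self):
        with pytest.raises(ValueError, match="insufficient standards"):
            fit_linearisation({"g": [(10.0, 0.1), (50.0, 0.5), (90.0, 0.9)]})

    def test_non_monotone_samples_rejected_with_pair(self):
        samples = {"g": [(10.0, 0.1), (50.0, 0.5), (60.0, 0.4), (90.0, 0.9)]}
        with pytest.raises(ValueError, match="non-monotone"):
            fit_linearisation(samples)


def _flat_image(value, shape=(8, 8), channels=("a", "b"), role="equalised"):
    data = np.full(shape + (len(channels),), value, dtype=float)
    return MultispectralImage(data, channels, role=role)


class TestEqualise:
    def _image_with_patches(self, dark_val, light_val, body_val):
        data = np.full((10, 10, 2), body_val, dtype=float)
        data[0:2, 0:2] = dark_val
        data[0:2, 8:10] = light_val
        img = MultispectralImage(data, ("a", "b"), role="linearised")
        dark_mask = np.zeros((10, 10), bool)
        dark_mask[0:2, 0:2] = True
        light_mask = np.zeros((10, 10), bool)
        light_mask[0:2, 8:10] = True
        return img, StandardPatch(0.085, dark_mask), StandardPatch(0.95, light_mask)

    def test_standards_at_nominals_give_identity(self):
        img, dark, light = self._image_with_patches(0.085, 0.95, 0.4)
        out = equalise(img, dark, light)
        np.testing.assert_allclose(out.data, img.data, atol=1e-12)

    def test_affine_relighting_cancels_exactly(self):
        img, dark, light = self._image_with_patches(0.085, 0.95, 0.4)
        ref = equalise(img, dark, light)
        relit = MultispectralImage(1.7 * img.data + 0.03, img.channel_names, role="linearised")
        out = equalise(relit, dark, light)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-10)

    def test_idempotent_with_own_standards(self):
        img, dark, light = self._image_with_patches(0.2, 0.8, 0.5)
        once = equalise(img, dark, light)
        twice = equalise(once, dark, light)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_degenerate_standards_rejected(self):
        img, dark, light = self._image_with_patches(0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="degenerate standards"):
            equalise(img, dark, light)


class TestExtractRoi:
    def test_constant_plane_mean(self):
        img = _flat_image(0.4)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        means, n = extract_roi(img, mask)
        assert means["a"] == pytest.approx(0.4)
        assert means["b"] == pytest.approx(0.4)
        assert n == 9

    def test_two_pixel_mean(self):
        data = np.zeros((2, 2, 1))
        data[0, 0, 0], data[0, 1, 0] = 0.2, 0.6
        img = MultispectralImage(data, ("a",), role="equalised")
        mask = np.array([[True, True], [False, False]])
        means, n = extract_roi(img, mask)
        assert means["a"] == pytest.approx(0.4)
        assert n == 2

    def test_empty_and_misshapen_masks_rejected(self):
        img = _flat_image(0.4)
        with pytest.raises(ValueError, match="empty ROI"):
            extract_roi(img, np.zeros((8, 8), bool))
        with pytest.raises(ValueError, match="mask shape"):
            extract_roi(img, np.zeros((4, 4), bool))

    def test_saturated_pixels_excluded(self):
        raw = np.full((4, 4, 1), 1000.0)
        raw[0, 0, 0] = 255 * 256  # would saturate at 16-bit... use explicit curve
        raw[0, 0, 0] = 0.995 * (2**16 - 1)
        img = MultispectralImage(raw, ("a",), bit_depth=16, role="raw")
        curve = LinearisationCurve(
            coefficients={"a": np.array([1.0, -np.log(2**16 - 1)])},
            domains={"a": (1.0, 2**16 - 1)},
            degree=1,
        )
        lin = linearise(img, curve)
        eq = MultispectralImage(lin.data, ("a",), role="equalised", saturated=lin.saturated)
        means, n = extract_roi(eq, np.ones((4, 4), bool))
        assert n == 15  # the saturated pixel is dropped


class TestEndToEnd:
    def test_rendered_fixture_round_trip_recovers_ground_truth(self):
        """Render -> linearise -> equalise -> extract recovers the subject's
        true camera-band reflectances within 2% (generator ground truth)."""
        spec = sample_reflectance(green_prawn_model(), 5, name="subj")
        fixture = render_fixture({"subj": spec}, rng_seed=5)
        _, _, eq = _calibrate(fixture)
        means, _ = extract_roi(eq, fixture.masks["subj"])
        truth = fixture.camera_truth["subj"]
        for got, expected in zip(means.values(), truth):
            assert got == pytest.approx(expected, abs=0.02)

    def test_noise_free_unit_gamma_round_trip_is_quantisation_exact(self):
        spec = sample_reflectance(green_prawn_model(), 2, name="subj")
        fixture = render_fixture(
            {"subj": spec}, gamma=1.0, noise_sd=0.0, gain=1.0, rng_seed=2
        )
        _, _, eq = _calibrate(fixture)
        means, _ = extract_roi(eq, fixture.masks["subj"])
        truth = fixture.camera_truth["subj"]
        for got, expected in zip(means.values(), truth):
            assert got == pytest.approx(expected, abs=2e-4)  # one quantisation step

    def test_same_seed_renders_identical_fixture(self):
        spec = sample_reflectance(green_prawn_model(), 3, name="s")
        f1 = render_fixture({"s": spec}, rng_seed=11)
        f2 = render_fixture({"s": spec}, rng_seed=11)
        np.testing.assert_array_equal(f1.image.data, f2.image.data)


def test_tiff_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    img = MultispectralImage(rng.uniform(0, 1, (6, 5, 3)), ("r", "g", "b"), role="equalised")
    path = tmp_path / "stack.tif"
    write_multispectral_tiff(path, img)
    back = read_multispectral_tiff(path)
    assert back.channel_names == img.channel_names
    assert back.role == "equalised"
    np.testing.assert_allclose(back.data, img.data, atol=1e-6)
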