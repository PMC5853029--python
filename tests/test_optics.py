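"""The defocus PSF, sensor noise and photometric augmentation."""

import numpy as np
import pytest

from focusqc.optics import (OpticalParams, PSFKernel, SensorModel,
                            airy_pattern, apply_poisson_noise,
                            augment_gain_offset, compute_psf, defocus_image,
                            energy_diameter, generate_defocus_stack)


class TestComputePsf:
    def test_in_focus_kernel_matches_airy_closed_form(self, optical_params):
        """At z=0 the diffraction integral reduces to (2 J1(v)/v)^2."""
        kernel = compute_psf(optical_params, 0.0, radius=8)
        airy = airy_pattern(optical_params, radius=8)
        assert np.abs(kernel.weights - airy).max() < 1e-3

    @pytest.mark.parametrize("z", [2.0, 4.0, 10.0])
    def test_kernel_even_in_z(self, optical_params, z):
        plus = compute_psf(optical_params, z, check_truncation=False)
        minus = compute_psf(optical_params, -z, check_truncation=False)
        np.testing.assert_array_equal(plus.weights, minus.weights)

    @pytest.mark.parametrize("z", [0.0, 2.0, 8.0, 20.0])
    def test_unit_sum(self, optical_params, z):
        kernel = compute_psf(optical_params, z, check_truncation=False)
        assert abs(kernel.weights.sum() - 1.0) < 1e-9
        assert np.all(kernel.weights >= 0)

    def test_radial_symmetry(self, optical_params):
        w = compute_psf(optical_params, 6.0, check_truncation=False).weights
        assert np.allclose(w, w[::-1, :])
        assert np.allclose(w, w[:, ::-1])
        assert np.allclose(w, w.T)

    def test_level10_blur_diameter_in_printed_range(self, optical_params):
        """The most defocused level spans roughly a 30-pixel blur."""
        z10 = 10 * optical_params.z_step_um
        kernel = compute_psf(optical_params, z10)
        assert 20.0 <= energy_diameter(kernel, 0.8) <= 40.0

    def test_blur_diameter_linear_in_z(self, optical_params):
        """80%-energy diameter grows ~linearly over levels 1..10."""
        zs = np.arange(1, 11) * optical_params.z_step_um
        diams = np.array([
            energy_diameter(compute_psf(optical_params, z,
                                        check_truncation=False))
            for z in zs])
        slope, intercept = np.polyfit(zs, diams, 1)
        fit = slope * zs + intercept
        assert np.max(np.abs(diams - fit) / diams) < 0.25

    def test_quadrature_converged(self, optical_params):
        a = compute_psf(optical_params, 6.0, radius=10, n_nodes=201,
                        check_truncation=False)
        b = compute_psf(optical_params, 6.0, radius=10, n_nodes=401,
                        check_truncation=False)
        assert np.abs(a.weights - b.weights).max() < 1e-6

    def test_truncation_warning(self, optical_params):
        with pytest.warns(UserWarning, match="truncat"):
            compute_psf(optical_params, 20.0, radius=4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            OpticalParams(numerical_aperture=1.5, refractive_index=1.0)
        with pytest.raises(ValueError):
            OpticalParams(wavelength_nm=-1.0)
        with pytest.raises(ValueError):
            compute_psf(OpticalParams(), float("nan"))

    def test_wavenumber_definition(self):
        p = OpticalParams(wavelength_nm=500.0)
        assert p.wavenumber == pytest.approx(2 * np.pi / 500.0)


class TestDefocusImage:
    def test_constant_image_unchanged(self, optical_params):
        kernel = compute_psf(optical_params, 4.0, check_truncation=False)
        img = np.full((64, 64), 37.0)
        out = defocus_image(img, kernel)
        assert np.allclose(out, 37.0)

    def test_impulse_reproduces_kernel(self, optical_params):
        kernel = compute_psf(optical_params, 2.0, radius=5,
                             check_truncation=False)
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = defocus_image(img, kernel)
        np.testing.assert_allclose(out[15:26, 15:26], kernel.weights,
                                   atol=1e-10)

    def test_blob_radius_nondecreasing_in_z(self, optical_params):
        yy, xx = np.mgrid[:96, :96]
        blob = 1000.0 * np.exp(-((yy - 48.0) ** 2 + (xx - 48.0) ** 2) / 18.0)

        def r80(img):
            d2 = (yy - 48.0) ** 2 + (xx - 48.0) ** 2
            order = np.argsort(d2.ravel())
            cum = np.cumsum(img.ravel()[order]) / img.sum()
            return np.sqrt(d2.ravel()[order][np.searchsorted(cum, 0.8)])

        radii = [r80(blob)]
        for z in [4.0, 8.0, 12.0]:
            k = compute_psf(optical_params, z, check_truncation=False)
            radii.append(r80(defocus_image(blob, k)))
        assert np.all(np.diff(radii) >= -1e-9)

    def test_intensity_conserved_for_interior_blob(self, optical_params):
        kernel = compute_psf(optical_params, 4.0, check_truncation=False)
        yy, xx = np.mgrid[:128, :128]
        blob = 500.0 * np.exp(-((yy - 64.0) ** 2 + (xx - 64.0) ** 2) / 8.0)
        out = defocus_image(blob, kernel)
        assert abs(out.sum() / blob.sum() - 1.0) < 0.01

    def test_kernel_larger_than_image_rejected(self, optical_params):
        kernel = compute_psf(optical_params, 20.0, check_truncation=False)
        with pytest.raises(ValueError, match="larger"):
            defocus_image(np.ones((16, 16)), kernel)


class TestPoissonNoise:
    def test_offset_only_image_is_fixed_point(self, sensor):
        img = np.full((32, 32), sensor.offset)
        out = apply_poisson_noise(img, sensor, seed=0)
        np.testing.assert_array_equal(out, img)

    def test_variance_matches_gain_scaled_poisson(self):
        """Var(out) = gain * (mean - offset) for a uniform scene."""
        sensor = SensorModel(offset=100.0, gain=3.0)
        img = np.full((400, 250), 4100.0)  # 1e5 pixels
        out = apply_poisson_noise(img, sensor, seed=5)
        expected_var = sensor.gain * (4100.0 - sensor.offset)
        assert abs(out.var() / expected_var - 1.0) < 0.05

    def test_seed_reproducibility(self, sensor, rng):
        img = rng.uniform(0, 10000, (50, 50))
        a = apply_poisson_noise(img, sensor, seed=42)
        b = apply_poisson_noise(img, sensor, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            SensorModel(offset=0.0, gain=0.0)


class TestDefocusStack:
    def test_levels_and_depths(self, optical_params, sensor):
        img = np.full((168, 168), 200.0)
        stack = generate_defocus_stack(img, optical_params, sensor, seed=1)
        levels = [lvl for _, lvl in stack]
        assert levels == list(range(11))
        np.testing.assert_allclose(optical_params.z_depths_um(),
                                   np.arange(11) * 2.0)


class TestAugmentGainOffset:
    def test_neutral_parameters_identity(self, rng):
        img = rng.uniform(0, 1000, (20, 20))
        out = augment_gain_offset(img, gain_range=(1.0, 1.0),
                                  offset_range=(1e-12, 1e-12), seed=0)
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_geometric_mean_of_gains_is_one(self):
        """sqrt(0.2 * 5.0) = 1: log-uniform draws center on unit gain."""
        from focusqc.optics import sample_log_uniform
        rng = np.random.default_rng(7)
        draws = np.array([sample_log_uniform(rng, 0.2, 5.0)
                          for _ in range(10_000)])
        assert abs(np.exp(np.mean(np.log(draws))) - 1.0) < 0.03
        assert draws.min() >= 0.2 and draws.max() <= 5.0

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            augment_gain_offset(np.ones((4, 4)), gain_range=(0.0, 5.0),
                                seed=0)


def test_kernel_invariants_reject_bad_weights(optical_params):
    with pytest.raises(ValueError):
        PSFKernel(weights=np.ones((3, 3)), z_um=0.0, params=optical_params)
    with pytest.raises(ValueError):
        PSFKernel(weights=np.full((4, 4), 1 / 16), z_um=0.0,
                  params=optical_params)
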