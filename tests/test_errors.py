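"""Use-error corruptions and the augmentation suite."""

import numpy as np
import pytest

from wirdrs.errors import (
    ErrorConfig,
    AUGMENTATION_ROWS,
    add_gaussian_noise,
    apply_error_row,
    build_augmented_training_set,
    compress_spectrum,
    make_condition_dataset,
    rotate_spectrum,
    scale_spectrum,
    shift_wavelength,
)
from wirdrs.spectra import Spectrum, WavelengthGrid


class TestGaussianNoise:
    def test_none_is_identity_and_seed_reproducible(self, gaussian_spectrum):
        same = add_gaussian_noise(gaussian_spectrum, None)
        np.testing.assert_array_equal(same.intensity, gaussian_spectrum.intensity)
        a = add_gaussian_noise(gaussian_spectrum, 35.0, seed=5)
        b = add_gaussian_noise(gaussian_spectrum, 35.0, seed=5)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_empirical_rms_ratio_matches_target(self, gaussian_spectrum):
        # Monte-Carlo estimate of the SNR contract over 1000 draws
        signal = gaussian_spectrum.intensity
        rms_signal = np.sqrt((signal**2).mean())
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(1000):
            noisy = add_gaussian_noise(gaussian_spectrum, 35.0, seed=rng)
            noise = noisy.intensity - signal
            ratios.append(rms_signal / np.sqrt((noise**2).mean()))
        assert 33.0 < np.mean(ratios) < 37.0

    def test_nonpositive_snr_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            add_gaussian_noise(gaussian_spectrum, 0.0)


class TestShift:
    def test_zero_shift_identity(self, gaussian_spectrum):
        out = shift_wavelength(gaussian_spectrum, 0.0)
        np.testing.assert_array_equal(out.intensity, gaussian_spectrum.intensity)

    def test_round_trip_exact_for_linear_spectra(self, grid):
        # linear interpolation reproduces linear-in-wavelength content exactly
        ramp = Spectrum(grid, np.linspace(1.0, 2.0, grid.n_columns))
        back = shift_wavelength(shift_wavelength(ramp, -4.8), 4.8)
        margin = int(np.ceil(4.8 / grid.spacing_nm)) + 1
        interior = slice(margin, -margin)
        np.testing.assert_allclose(
            back.intensity[interior], ramp.intensity[interior], rtol=1e-9
        )

    def test_round_trip_curvature_bound_for_smooth_spectra(self, gaussian_spectrum, grid):
        back = shift_wavelength(shift_wavelength(gaussian_spectrum, -4.8), 4.8)
        margin = int(np.ceil(4.8 / grid.spacing_nm)) + 1
        interior = slice(margin, -margin)
        err = np.abs(back.intensity - gaussian_spectrum.intensity)[interior]
        assert err.max() < 0.01 * gaussian_spectrum.intensity.max()

    def test_integer_pixel_shift_is_exact_relabeling(self, grid):
        rng = np.random.default_rng(8)
        y = rng.random(grid.n_columns)
        k = 7
        out = shift_wavelength(Spectrum(grid, y), -k * grid.spacing_nm)
        np.testing.assert_allclose(out.intensity[:-k], y[k:], rtol=1e-9)
        np.testing.assert_array_equal(out.intensity[-k:], 0.0)

    def test_shift_larger_than_band_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            shift_wavelength(gaussian_spectrum, -200.0)


class TestCompress:
    def test_zero_and_constant_identity(self, gaussian_spectrum, grid):
        out = compress_spectrum(gaussian_spectrum, 0.0)
        np.testing.assert_array_equal(out.intensity, gaussian_spectrum.intensity)
        const = Spectrum(grid, np.full(grid.n_columns, 2.0))
        np.testing.assert_allclose(compress_spectrum(const, 1.0).intensity, 2.0)

    def test_peak_relocates_by_affine_displacement(self, grid):
        lam = grid.wavelengths_nm
        peak_lam, t, span = 520.0, 1.0, grid.span_nm
        spec = Spectrum(grid, np.exp(-(((lam - peak_lam) / 6.0) ** 2)))
        out = compress_spectrum(spec, t)
        expected = 450.0 + t + (peak_lam - 450.0) * (span - 2 * t) / span
        got = lam[out.intensity.argmax()]
        assert abs(got - expected) <= grid.spacing_nm
        assert expected > peak_lam  # left-half peak moves towards band centre

    def test_margins_hold_edge_values(self, grid):
        y = np.linspace(5.0, 1.0, grid.n_columns)
        out = compress_spectrum(Spectrum(grid, y), 2.0)
        assert out.intensity[0] == pytest.approx(y[0])
        assert out.intensity[-1] == pytest.approx(y[-1])

    def test_excessive_compression_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            compress_spectrum(gaussian_spectrum, 95.0)


class TestRotateScale:
    def test_forced_rotation_endpoints_and_centre(self):
        grid = WavelengthGrid(np.linspace(450, 630, 181))  # odd N, exact centre
        y = np.full(181, 2.0)
        out = rotate_spectrum(Spectrum(grid, y), amount=0.05)
        assert out.intensity[0] == pytest.approx(2.0 * 1.05)
        assert out.intensity[-1] == pytest.approx(2.0 * 0.95)
        assert out.intensity[90] == pytest.approx(2.0)

    def test_rotation_preserves_constant_band_integral(self, grid):
        const = Spectrum(grid, np.full(grid.n_columns, 3.0))
        out = rotate_spectrum(const, amount=0.05)
        assert out.intensity.mean() == pytest.approx(3.0, rel=1e-12)

    def test_zero_magnitude_identity(self, gaussian_spectrum):
        out = rotate_spectrum(gaussian_spectrum, max_frac=0.0, seed=1)
        np.testing.assert_allclose(out.intensity, gaussian_spectrum.intensity)
        out = scale_spectrum(gaussian_spectrum, max_frac=0.0, seed=1)
        np.testing.assert_allclose(out.intensity, gaussian_spectrum.intensity)

    def test_scale_factor_bounds_and_exact_mean_scaling(self, gaussian_spectrum):
        for seed in range(20):
            out = scale_spectrum(gaussian_spectrum, 0.05, seed=seed)
            factor = out.intensity[0] / gaussian_spectrum.intensity[0]
            assert 0.95 <= factor <= 1.05
            assert out.intensity.mean() == pytest.approx(
                factor * gaussian_spectrum.intensity.mean(), rel=1e-12
            )


class TestRowSuite:
    def test_row_without_checks_is_identity(self, mini_dataset):
        out = apply_error_row(mini_dataset, 1, seed=3)
        np.testing.assert_array_equal(out.gray, mini_dataset.gray)
        assert all(tag == "row1" for tag in out.error_tag)

    def test_compounded_row_changes_data_but_not_labels(self, mini_dataset):
        out = apply_error_row(mini_dataset, 11, seed=3)
        assert len(out) == len(mini_dataset)
        assert not np.allclose(out.gray, mini_dataset.gray)
        np.testing.assert_array_equal(out.mu_a, mini_dataset.mu_a)
        np.testing.assert_array_equal(out.group_id, mini_dataset.group_id)
        assert len(AUGMENTATION_ROWS[11]) == 5  # every corruption marked

    def test_conservation_after_every_row(self, mini_dataset):
        for row in sorted(AUGMENTATION_ROWS):
            out = apply_error_row(mini_dataset, row, seed=row)
            np.testing.assert_allclose(
                out.gray, out.red + out.green + out.blue, rtol=1e-9, atol=1e-12
            )

    def test_unknown_row_rejected(self, mini_dataset):
        with pytest.raises(ValueError):
            apply_error_row(mini_dataset, 15)

    def test_seeded_reproducibility(self, mini_dataset):
        a = apply_error_row(mini_dataset, 11, seed=9)
        b = apply_error_row(mini_dataset, 11, seed=9)
        np.testing.assert_array_equal(a.gray, b.gray)
        np.testing.assert_array_equal(a.red, b.red)


class TestAugmentedTrainingSet:
    def test_small_base_proceeds_with_warning(self, mini_dataset):
        with pytest.warns(RuntimeWarning, match="canonical"):
            out = build_augmented_training_set(mini_dataset, seed=0)
        assert len(out) == 14 * 25
        row1 = out.error_tag == "row1"
        np.testing.assert_array_equal(out.gray[row1], mini_dataset.gray)
        assert set(out.error_tag) == {f"row{r}" for r in range(1, 15)}

    def test_gray_level_snr_contract_at_dataset_level(self, mini_dataset):
        # noise is drawn at the gray level, so the realised dataset-level
        # RMS SNR should sit near the configured 35:1
        out = make_condition_dataset(mini_dataset, "noise", ErrorConfig(), seed=11)
        noise = out.gray - mini_dataset.gray
        snr = np.sqrt((mini_dataset.gray**2).mean(axis=1)) / np.sqrt(
            (noise**2).mean(axis=1)
        )
        assert 31.0 < snr.mean() < 39.0

    def test_condition_datasets_preserve_counts_and_tags(self, mini_dataset):
        for cond in ("perfect", "shifted", "all"):
            ds = make_condition_dataset(mini_dataset, cond, seed=2)
            assert len(ds) == len(mini_dataset)
            assert all(tag == cond for tag in ds.error_tag)
        with pytest.raises(ValueError):
            make_condition_dataset(mini_dataset, "bogus")
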