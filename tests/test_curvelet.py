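import numpy as np
import pytest

from octa3d import (
    CurveletSystem,
    ThresholdParams,
    Tube,
    VesselPhantomSpec,
    denoise,
    estimate_sigma,
    fdct3,
    hard_threshold,
    ifdct3,
    make_vessel_volume,
    psnr,
    select_stripe_bands,
    stripe_filter,
)


@pytest.fixture(scope="module")
def system32():
    return CurveletSystem((32, 32, 32))


class TestTransform:
    def test_zero_volume_gives_zero_coefficients(self, system32):
        c = fdct3(np.zeros((32, 32, 32)), system32)
        assert all(np.all(b == 0) for b in c.blocks)

    def test_homogeneity(self, system32):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((32, 32, 32))
        c1 = fdct3(v, system32)
        c2 = fdct3(3.5 * v, system32)
        for b1, b2 in zip(c1.blocks, c2.blocks):
            assert np.allclose(3.5 * b1, b2, atol=1e-10)

    def test_parseval_energy_conservation(self, system32):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((32, 32, 32))
        c = fdct3(v, system32)
        ratio = c.energy() / np.sum(v ** 2)
        assert abs(ratio - 1.0) < 1e-6

    def test_roundtrip_impulse(self, system32):
        v = np.zeros((32, 32, 32))
        v[16, 10, 20] = 1.0
        rec = ifdct3(fdct3(v, system32))
        assert np.abs(rec - v).max() < 1e-6

    def test_roundtrip_tube_phantom(self, tube_phantom_clean):
        _, vol, _, _ = tube_phantom_clean
        rec = ifdct3(fdct3(vol))
        rel = np.linalg.norm(rec - vol) / np.linalg.norm(vol)
        assert rel < 1e-6

    def test_roundtrip_anisotropic_shape(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((16, 24, 40))
        system = CurveletSystem(v.shape)
        rec = ifdct3(fdct3(v, system))
        assert np.linalg.norm(rec - v) / np.linalg.norm(v) < 1e-6

    def test_zero_coeffs_invert_to_zero(self, system32):
        c = fdct3(np.zeros((32, 32, 32)), system32)
        assert np.all(ifdct3(c) == 0)

    def test_nonfinite_volume_rejected(self, system32):
        v = np.zeros((32, 32, 32))
        v[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            fdct3(v, system32)

    def test_shape_mismatch_rejected(self, system32):
        with pytest.raises(ValueError):
            fdct3(np.zeros((16, 16, 16)), system32)

    def test_coefficient_container_roundtrip(self, system32, tmp_path):
        rng = np.random.default_rng(13)
        v = rng.standard_normal((32, 32, 32))
        c = fdct3(v, system32)
        path = tmp_path / "coeffs.npz"
        c.save(path)
        from octa3d.curvelet import CurveletCoeffs
        back = CurveletCoeffs.load(path)
        assert back.system.shape == system32.shape
        for a, b in zip(c.blocks, back.blocks):
            assert np.array_equal(a, b)
        assert np.allclose(ifdct3(back), v, atol=1e-6)

    def test_tampered_block_shape_rejected(self, system32):
        c = fdct3(np.zeros((32, 32, 32)), system32)
        c.blocks[3] = np.zeros((8, 8, 8))
        with pytest.raises(ValueError):
            ifdct3(c)


class TestSigmaEstimate:
    def test_gaussian_noise_sigma_recovered(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((64, 64, 64))
        c = fdct3(v)
        est = estimate_sigma(c)
        # oracle: direct std of the gain-normalized finest coefficients
        bands = c.system.finest_scale_bands()
        pooled = np.concatenate([c.blocks[i].ravel() / c.system.band_gains[i]
                                 for i in bands])
        assert abs(est - pooled.std()) / pooled.std() < 0.10
        assert abs(est - 1.0) < 0.10

    def test_clean_smooth_volume_estimates_near_zero(self):
        z, x, y = np.meshgrid(*[np.linspace(-1, 1, 32)] * 3, indexing="ij")
        v = np.exp(-(z ** 2 + x ** 2 + y ** 2) / 0.2)
        c = fdct3(v)
        peak_coeff = max(np.abs(b).max() for b in c.blocks)
        assert estimate_sigma(c) < 0.01 * peak_coeff

    def test_estimate_scales_linearly_with_noise(self):
        rng = np.random.default_rng(6)
        noise = rng.standard_normal((32, 32, 32))
        e1 = estimate_sigma(fdct3(0.5 * noise))
        e2 = estimate_sigma(fdct3(1.0 * noise))
        assert abs(e2 / e1 - 2.0) < 0.10


class TestHardThreshold:
    def test_zero_threshold_is_identity(self, system32):
        rng = np.random.default_rng(7)
        v = rng.standard_normal((32, 32, 32))
        c = fdct3(v, system32)
        out = hard_threshold(c, ThresholdParams(c_default=0, c_finest=0,
                                                sigma=1.0))
        for a, b in zip(c.blocks, out.blocks):
            assert np.array_equal(a, b)

    def test_huge_threshold_kills_directional_content(self, system32):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((32, 32, 32))
        c = fdct3(v, system32)
        out = hard_threshold(c, ThresholdParams(c_default=1e9, c_finest=1e9,
                                                sigma=1.0))
        for i, b in enumerate(out.blocks):
            if system32.band_scales[i] is not None:
                assert np.all(b == 0)

    def test_support_shrinks_and_magnitudes_never_grow(self, system32):
        rng = np.random.default_rng(9)
        v = rng.standard_normal((32, 32, 32))
        c = fdct3(v, system32)
        lo = hard_threshold(c, ThresholdParams(c_default=1, c_finest=1))
        hi = hard_threshold(c, ThresholdParams(c_default=3, c_finest=4))
        for orig, a, b in zip(c.blocks, lo.blocks, hi.blocks):
            assert np.all(np.abs(a) <= np.abs(orig) + 0)
            # larger C(s) -> support subset of smaller C(s)
            assert np.all((b != 0) <= (a != 0))

    def test_denoising_improves_psnr(self, tube_phantom_clean,
                                     tube_phantom_noisy):
        _, clean, _, _ = tube_phantom_clean
        spec, noisy, _, _ = tube_phantom_noisy
        system = CurveletSystem(noisy.shape)
        den = denoise(noisy, ThresholdParams(sigma=spec.gaussian_sigma), None,
                      system)
        assert psnr(clean, den) > psnr(clean, noisy)


class TestStripeFilter:
    def test_empty_band_set_is_identity_with_warning(self, system32):
        from octa3d.curvelet import StripeBandSet
        rng = np.random.default_rng(10)
        c = fdct3(rng.standard_normal((32, 32, 32)), system32)
        with pytest.warns(UserWarning):
            out = stripe_filter(c, StripeBandSet((), 1, 15.0))
        for a, b in zip(c.blocks, out.blocks):
            assert np.array_equal(a, b)

    def test_below_mean_coefficients_kept_bit_identical(self, system32):
        rng = np.random.default_rng(11)
        c = fdct3(rng.standard_normal((32, 32, 32)), system32)
        bands = select_stripe_bands(system32, stripe_axis=1)
        out = stripe_filter(c, bands)
        for i in bands.band_indices:
            orig, filt = c.blocks[i], out.blocks[i]
            below = np.abs(orig) < np.mean(np.abs(orig))
            assert np.array_equal(orig[below], filt[below])
            assert np.all(filt[~below] == 0)

    def test_stripe_band_energy_reduced_by_half(self, tube_phantom_noisy):
        spec, noisy, _, _ = tube_phantom_noisy
        system = CurveletSystem(noisy.shape)
        bands = select_stripe_bands(system, stripe_axis=spec.stripe_axis)
        assert bands.band_indices
        c = fdct3(noisy, system)
        out = stripe_filter(c, bands)
        before = sum(np.sum(c.blocks[i] ** 2) for i in bands.band_indices)
        after = sum(np.sum(out.blocks[i] ** 2) for i in bands.band_indices)
        assert after <= 0.5 * before

    def test_untouched_bands_are_bit_identical(self, system32):
        rng = np.random.default_rng(12)
        c = fdct3(rng.standard_normal((32, 32, 32)), system32)
        bands = select_stripe_bands(system32, stripe_axis=1)
        out = stripe_filter(c, bands)
        for i in range(system32.n_bands):
            if i not in bands.band_indices:
                assert np.array_equal(c.blocks[i], out.blocks[i])


class TestDenoise:
    def test_disabled_filters_give_roundtrip_identity(self, tube_phantom_clean):
        _, vol, _, _ = tube_phantom_clean
        out = denoise(vol, None, None)
        assert np.linalg.norm(out - vol) / np.linalg.norm(vol) < 1e-6

    def test_contrast_and_background_improve(self, tube_phantom_clean,
                                             tube_phantom_noisy):
        _, _, mask, _ = tube_phantom_clean
        spec, noisy, _, _ = tube_phantom_noisy
        system = CurveletSystem(noisy.shape)
        bands = select_stripe_bands(system, stripe_axis=spec.stripe_axis)
        den = denoise(noisy, ThresholdParams(sigma=spec.gaussian_sigma),
                      bands, system)
        bg = ~mask
        assert den[bg].std() < noisy[bg].std()
        # background level as mean magnitude: the raw mean is ~0 by design
        contrast_before = noisy[mask].mean() / np.abs(noisy[bg]).mean()
        contrast_after = den[mask].mean() / np.abs(den[bg]).mean()
        assert contrast_after > contrast_before

    def test_output_finite_and_shape_preserved(self, tube_phantom_noisy):
        _, noisy, _, _ = tube_phantom_noisy
        den = denoise(noisy, ThresholdParams())
        assert den.shape == noisy.shape
        assert np.all(np.isfinite(den))

    def test_idempotent_with_frozen_sigma(self, tube_phantom_clean,
                                          tube_phantom_noisy):
        # the coefficient-domain rule is exactly idempotent; through the
        # redundant frame a second volume pass re-mixes bands, so the
        # volume-domain check asserts stability of the recovered quality
        _, clean, _, _ = tube_phantom_clean
        spec, noisy, _, _ = tube_phantom_noisy
        system = CurveletSystem(noisy.shape)
        params = ThresholdParams(sigma=spec.gaussian_sigma)
        c1 = hard_threshold(fdct3(noisy, system), params)
        c2 = hard_threshold(c1, params)
        assert all(np.array_equal(a, b) for a, b in zip(c1.blocks, c2.blocks))
        once = denoise(noisy, params, None, system)
        twice = denoise(once, params, None, system)
        assert psnr(clean, twice) > psnr(clean, noisy)
        assert abs(psnr(clean, twice) - psnr(clean, once)) < 1.5
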