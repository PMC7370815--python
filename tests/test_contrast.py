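import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from contraspect import (
    AcfMode,
    LuminanceField,
    RGBImage,
    ValidationError,
    autocorrelation_direct,
    autocorrelation_fft,
    generate_gaussian_field,
    image_contrast,
    mean_center,
    radial_acf_profile,
    rgb_to_luminance,
)

CHECKER_2x2 = np.array([[0.5, -0.5], [-0.5, 0.5]])


def pixel(r, g, b):
    return RGBImage(pixels=np.array([[[r, g, b]]], dtype=np.uint8))


class TestLuminance:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), 1.0),
            ((0, 0, 0), 0.0),
            ((255, 0, 0), 0.299),
            ((0, 255, 0), 0.587),
            ((0, 0, 255), 0.114),
        ],
    )
    def test_weights(self, rgb, expected):
        field = rgb_to_luminance(pixel(*rgb))
        assert field.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_range_and_mean(self, rng):
        px = rng.integers(0, 256, size=(20, 30, 3), dtype=np.uint8)
        field = rgb_to_luminance(RGBImage(pixels=px))
        assert field.values.min() >= 0 and field.values.max() <= 1
        assert field.mean_luminance == pytest.approx(field.values.mean(), abs=1e-12)

    def test_linearize_srgb_differs(self):
        plain = rgb_to_luminance(pixel(128, 128, 128))
        linear = rgb_to_luminance(pixel(128, 128, 128), linearize_srgb=True)
        assert linear.values[0, 0] < plain.values[0, 0]  # mid-gray decodes darker

    def test_field_validation(self):
        with pytest.raises(ValidationError):
            LuminanceField(values=np.array([[0.5, 1.5]]))
        with pytest.raises(ValidationError):
            LuminanceField(values=np.array([0.5]))


class TestMeanCenter:
    def test_uniform(self):
        out = mean_center(LuminanceField(values=np.full((3, 5), 0.7)))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_checkerboard(self):
        vals = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(
            mean_center(LuminanceField(values=vals)), vals - 0.5
        )

    def test_output_mean_zero(self, random_field):
        for _ in range(5):
            out = mean_center(random_field(11, 7))
            assert abs(out.mean()) < 1e-12


class TestAutocorrelationFFT:
    def test_zero_field(self):
        acf = autocorrelation_fft(np.zeros((4, 4)))
        np.testing.assert_array_equal(acf.values, 0.0)

    def test_checkerboard_hand_values(self):
        acf = autocorrelation_fft(CHECKER_2x2)
        np.testing.assert_allclose(
            acf.values, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-14
        )

    def test_lag0_is_mean_square(self, rng):
        c = rng.standard_normal((8, 8))
        c -= c.mean()
        acf = autocorrelation_fft(c)
        assert acf.at_origin == pytest.approx(np.mean(c**2), abs=1e-12)

    def test_circular_negation_symmetry(self, rng):
        c = rng.standard_normal((6, 9))
        c -= c.mean()
        v = autocorrelation_fft(c).values
        h, w = v.shape
        for a in range(h):
            for b in range(w):
                assert v[a, b] == pytest.approx(v[-a % h, -b % w], abs=1e-10)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            autocorrelation_fft(np.array([[0.0, np.nan]]))


class TestAutocorrelationDirect:
    def test_checkerboard_matches_hand_sum(self):
        acf = autocorrelation_direct(CHECKER_2x2, max_lag=1)
        np.testing.assert_allclose(
            acf.values, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-14
        )

    def test_zero_field(self):
        acf = autocorrelation_direct(np.zeros((5, 5)), max_lag=3)
        np.testing.assert_array_equal(acf.values, 0.0)

    def test_max_lag_out_of_range(self):
        with pytest.raises(ValidationError):
            autocorrelation_direct(np.zeros((4, 4)), max_lag=4)

    @pytest.mark.parametrize("mode", [AcfMode.CIRCULAR, AcfMode.LINEAR_UNBIASED])
    def test_oracle_equivalence_30_random_fields(self, rng, mode):
        worst = 0.0
        for _ in range(30):
            c = rng.standard_normal((12, 12))
            c -= c.mean()
            direct = autocorrelation_direct(c, max_lag=11, mode=mode).values
            fft = autocorrelation_fft(c, mode=mode).values[:12, :12]
            worst = max(worst, np.abs(direct - fft).max())
        assert worst < 1e-10

    def test_oracle_equivalence_nonsquare_linear(self, rng):
        c = rng.standard_normal((7, 13))
        c -= c.mean()
        direct = autocorrelation_direct(c, max_lag=6, mode=AcfMode.LINEAR_UNBIASED)
        fft = autocorrelation_fft(c, mode=AcfMode.LINEAR_UNBIASED)
        np.testing.assert_allclose(
            direct.values, fft.values[:7, :7], atol=1e-10
        )


class TestImageContrast:
    def test_uniform_zero(self):
        for level in (0.0, 0.3, 1.0):
            res = image_contrast(LuminanceField(values=np.full((8, 8), level)))
            assert res.variance_contrast == pytest.approx(0.0, abs=1e-15)

    def test_balanced_binary_maximal(self):
        vals = np.kron(np.indices((8, 8)).sum(axis=0) % 2, np.ones((2, 2)))
        res = image_contrast(LuminanceField(values=vals.astype(float)))
        assert res.variance_contrast == pytest.approx(0.25, abs=1e-12)
        assert res.rms_contrast == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("amp, k", [(0.4, 4), (0.25, 1), (0.1, 17)])
    def test_grating_closed_form(self, amp, k):
        x = np.arange(128)
        vals = np.tile(0.5 + amp * np.sin(2 * np.pi * k * x / 128), (64, 1))
        res = image_contrast(LuminanceField(values=vals))
        assert res.variance_contrast == pytest.approx(amp**2 / 2, abs=1e-6)

    def test_single_pixel_error(self):
        with pytest.raises(ValidationError):
            image_contrast(LuminanceField(values=np.array([[0.5]])))

    def test_rms_is_sqrt_of_variance(self, random_field):
        res = image_contrast(random_field())
        assert res.rms_contrast == pytest.approx(
            np.sqrt(res.variance_contrast), abs=1e-12
        )

    def test_parseval_spectral_equals_direct_sum(self, random_field):
        field = random_field(17, 23)
        res = image_contrast(field)
        direct = np.mean((field.values - field.values.mean()) ** 2)
        assert res.variance_contrast == pytest.approx(direct, abs=1e-12)


class TestInvariances:
    def test_shift_flip_rotation_offset(self, random_field, rng):
        field = random_field(12, 18)
        base = image_contrast(field).variance_contrast
        v = field.values
        transformed = [
            np.roll(v, (3, 5), axis=(0, 1)),
            v[::-1, :],
            v[:, ::-1],
            np.rot90(v),
        ]
        headroom = min(1.0 - v.max(), 0.9)
        transformed.append(v + headroom / 2)
        for t in transformed:
            assert image_contrast(
                LuminanceField(values=t)
            ).variance_contrast == pytest.approx(base, abs=1e-12)

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 12), st.integers(2, 12)),
            elements=st.floats(0.0, 1.0, width=64),
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_rms_bounded_by_half(self, vals):
        res = image_contrast(LuminanceField(values=vals))
        assert 0.0 <= res.rms_contrast <= 0.5 + 1e-12

    def test_equality_only_for_balanced_binary(self):
        vals = np.array([[0.0, 1.0, 1.0], [0.0, 1.0, 0.0]])  # balanced binary
        assert image_contrast(
            LuminanceField(values=vals)
        ).rms_contrast == pytest.approx(0.5, abs=1e-12)
        vals_unbalanced = np.array([[0.0, 1.0, 1.0], [1.0, 1.0, 0.0]])
        assert image_contrast(LuminanceField(values=vals_unbalanced)).rms_contrast < 0.5


class TestEstimatorConsistency:
    def test_iid_noise_mean_within_3se(self):
        sigma = 0.1
        estimates = [
            image_contrast(
                generate_gaussian_field(64, 64, sigma, 0.0, seed)
            ).variance_contrast
            for seed in range(100)
        ]
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - sigma**2) < 3 * se


class TestRadialProfile:
    def test_bin0_equals_variance_contrast(self, random_field):
        field = random_field()
        acf = autocorrelation_fft(mean_center(field))
        prof = radial_acf_profile(acf, n_bins=6)
        assert prof[0, 0] == 0.0
        assert prof[0, 1] == pytest.approx(
            image_contrast(field).variance_contrast, abs=1e-12
        )

    def test_zero_acf_zero_profile(self):
        acf = autocorrelation_fft(np.zeros((10, 10)))
        prof = radial_acf_profile(acf, n_bins=4)
        np.testing.assert_allclose(prof[~np.isnan(prof[:, 1]), 1], 0.0)

    def test_gaussian_field_profile_decays_over_correlation_length(self):
        ell = 8.0
        field = generate_gaussian_field(256, 256, 0.1, ell, seed=5)
        acf = autocorrelation_fft(mean_center(field))
        prof = radial_acf_profile(acf, n_bins=64)
        # the imposed ACF is Gaussian with scale ell*sqrt(2); look within 3 ell
        within = prof[prof[:, 0] <= 3 * ell]
        diffs = np.diff(within[:, 1])
        assert np.all(diffs <= 1e-4)  # monotone non-increasing up to sampling noise
        assert within[-1, 1] < 0.5 * within[0, 1]  # appreciable decay by 3 ell

    def test_n_bins_validation(self, random_field):
        acf = autocorrelation_fft(mean_center(random_field()))
        with pytest.raises(ValidationError):
            radial_acf_profile(acf, n_bins=1)
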