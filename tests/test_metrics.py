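import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhmkit import (
    HeightMap,
    benchmark_scores,
    evaluation_report,
    gaussian_baseline,
    ideal_microsphere_reference,
    make_microsphere_phantom,
    psnr,
    report_average,
    ssim,
)


class TestGaussianBaseline:
    def test_zero_sigma_is_identity(self, rng):
        img = HeightMap(rng.normal(size=(32, 32)))
        assert np.allclose(gaussian_baseline(img, 0.0).values, img.values, atol=1e-9)

    def test_constant_image_unchanged(self):
        img = HeightMap(np.full((32, 32), 4.2))
        assert np.allclose(gaussian_baseline(img, 2.0).values, 4.2, atol=1e-12)

    def test_impulse_response_is_normalized_separable_gaussian(self):
        impulse = np.zeros((41, 41))
        impulse[20, 20] = 1.0
        kernel2d = gaussian_baseline(HeightMap(impulse), 2.0).values
        assert kernel2d.sum() == pytest.approx(1.0, rel=1e-9)
        # separable: the 2D response equals the outer product of its 1D profiles
        row = kernel2d[20] / kernel2d[20].sum()
        col = kernel2d[:, 20] / kernel2d[:, 20].sum()
        assert np.allclose(kernel2d, np.outer(col, row), atol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_baseline(HeightMap(np.zeros((8, 8))), -1.0)


class TestIdealReference:
    def test_peak_and_width_equal_diameter(self):
        ref = ideal_microsphere_reference(10.0, (256, 256), 0.1)
        # grid center falls between pixels; the sampled peak sits within half
        # a pixel of the apex
        assert ref.values.max() == pytest.approx(10.0, abs=0.01)
        mid = ref.values[128]
        assert np.count_nonzero(mid > 0) * 0.1 == pytest.approx(10.0, abs=0.2)

    def test_rotation_invariance(self):
        ref = ideal_microsphere_reference(8.0, (128, 128), 0.1)
        assert np.allclose(ref.values, np.rot90(ref.values), atol=1e-9)

    def test_matches_phantom_construction(self):
        ref = ideal_microsphere_reference(10.0, (128, 128), 0.2)
        center = ((127 / 2) * 0.2, (127 / 2) * 0.2)
        ph = make_microsphere_phantom((128, 128), 0.2, 10.0, [center])
        assert np.array_equal(ref.values, ph.height)

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ideal_microsphere_reference(100.0, (64, 64), 0.1)


class TestPSNR:
    def test_identical_images_are_infinite(self, rng):
        img = rng.normal(size=(16, 16))
        assert psnr(img, img, data_range=1.0) == np.inf

    def test_closed_form_value(self):
        ref = np.zeros((10, 10))
        img = np.ones((10, 10))  # MSE = 1
        assert psnr(img, ref, data_range=10.0) == pytest.approx(20.0, rel=1e-12)

    def test_matches_direct_formula_on_random_pairs(self, rng):
        for _ in range(5):
            a, b = rng.normal(size=(2, 20, 20))
            expected = 10 * np.log10((b.max() - b.min()) ** 2 / np.mean((a - b) ** 2))
            assert psnr(a, b) == pytest.approx(expected, rel=1e-10)

    @given(st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=30)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 16, 16))
        assert psnr(scale * a, scale * b, data_range=scale * 4.0) == pytest.approx(
            psnr(a, b, data_range=4.0), rel=1e-9
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            psnr(np.zeros((4, 4)), np.zeros((4, 5)))


def _reference_ssim(img, ref, data_range, sigma=1.5, truncate=3.5, k1=0.01, k2=0.03):
    """Brute-force sliding-window SSIM with an explicit Gaussian window."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g, g)
    w /= w.sum()
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    h, wd = img.shape
    vals = []
    for i in range(radius, h - radius):
        for j in range(radius, wd - radius):
            a = img[i - radius : i + radius + 1, j - radius : j + radius + 1]
            b = ref[i - radius : i + radius + 1, j - radius : j + radius + 1]
            mu_a = (w * a).sum()
            mu_b = (w * b).sum()
            var_a = (w * a * a).sum() - mu_a**2
            var_b = (w * b * b).sum() - mu_b**2
            cov = (w * a * b).sum() - mu_a * mu_b
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return float(np.mean(vals))


class TestSSIM:
    def test_identical_images_score_one(self, rng):
        img = rng.normal(size=(24, 24))
        assert ssim(img, img, data_range=4.0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_penalizes_luminance(self):
        ref = np.full((24, 24), 1.0)
        img = ref + 5.0
        assert ssim(img, ref, data_range=10.0) < 1.0

    def test_matches_brute_force_windowed_oracle(self, rng):
        img = rng.normal(0, 1, (24, 24))
        ref = img + rng.normal(0, 0.5, (24, 24))
        ours = ssim(img, ref, data_range=4.0)
        brute = _reference_ssim(img, ref, data_range=4.0)
        assert ours == pytest.approx(brute, abs=1e-8)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)), data_range=1.0)

    def test_scale_invariance_with_data_range(self, rng):
        a = rng.normal(size=(24, 24))
        b = a + rng.normal(0, 0.3, (24, 24))
        assert ssim(2 * a, 2 * b, data_range=8.0) == pytest.approx(
            ssim(a, b, data_range=4.0), rel=1e-9
        )


class TestEvaluationReport:
    def test_single_row_average_equals_row(self, rng):
        ref = rng.normal(size=(24, 24))
        img = ref + rng.normal(0, 0.2, (24, 24))
        table = evaluation_report({"m": img}, ref, data_range=4.0)
        assert table.loc["Average", "ssim_m"] == table.loc[1, "ssim_m"]
        assert table.loc["Average", "psnr_m"] == table.loc[1, "psnr_m"]

    def test_average_row_is_column_mean(self, rng):
        ref = [rng.normal(size=(24, 24)) for _ in range(4)]
        maps = [r + rng.normal(0, 0.3, (24, 24)) for r in ref]
        table = evaluation_report({"m": maps}, ref, data_range=4.0)
        per_image = table.drop(index="Average")
        assert table.loc["Average", "psnr_m"] == pytest.approx(per_image["psnr_m"].mean())

    def test_empty_methods_rejected(self, rng):
        with pytest.raises(ValueError, match="method"):
            evaluation_report({}, rng.normal(size=(24, 24)))

    def test_length_mismatch_rejected(self, rng):
        ref = [rng.normal(size=(24, 24))] * 2
        with pytest.raises(ValueError, match="expected"):
            evaluation_report({"m": [ref[0]]}, ref)


class TestBenchmarkTable:
    def test_has_twenty_rows_and_six_score_columns(self):
        df = benchmark_scores()
        assert df.shape == (20, 6)
        assert set(df.columns) == {
            "ssim_unfiltered", "ssim_gaussian", "ssim_proposed",
            "psnr_unfiltered", "psnr_gaussian", "psnr_proposed",
        }

    def test_report_average_recovers_published_summary_row(self):
        avg = report_average(benchmark_scores())
        assert avg["ssim_unfiltered"] == pytest.approx(0.7600, abs=5e-5)
        assert avg["ssim_gaussian"] == pytest.approx(0.7730, abs=5e-5)
        assert avg["ssim_proposed"] == pytest.approx(0.7839, abs=5e-5)
        assert avg["psnr_unfiltered"] == pytest.approx(8.744, abs=5e-4)
        assert avg["psnr_gaussian"] == pytest.approx(9.011, abs=5e-4)
        assert avg["psnr_proposed"] == pytest.approx(9.181, abs=5e-4)
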