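"""Fidelity metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage, stats

import miranet as mn
from miranet.image import ValidationError

RNG = np.random.default_rng(23)


def _pair(h=16, w=16):
    a = mn.ImageSlice(RNG.random((h, w)))
    b = mn.ImageSlice(RNG.random((h, w)))
    return a, b


def ssim_window_oracle(x, y, data_range=1.0):
    """Direct windowed SSIM: gaussian 11x11 (sigma 1.5) over valid positions."""
    r = 5
    i = np.arange(-r, r + 1)
    k1 = np.exp(-(i ** 2) / (2 * 1.5 ** 2))
    k1 /= k1.sum()
    kern = np.outer(k1, k1)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = x.shape
    vals = []
    for ci in range(r, h - r):
        for cj in range(r, w - r):
            wx = x[ci - r:ci + r + 1, cj - r:cj + r + 1]
            wy = y[ci - r:ci + r + 1, cj - r:cj + r + 1]
            ux, uy = (kern * wx).sum(), (kern * wy).sum()
            vx = (kern * (wx - ux) ** 2).sum()
            vy = (kern * (wy - uy) ** 2).sum()
            vxy = (kern * (wx - ux) * (wy - uy)).sum()
            vals.append(((2 * ux * uy + c1) * (2 * vxy + c2))
                        / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


class TestRmsePsnr:
    def test_identical_images(self):
        a, _ = _pair()
        assert mn.rmse(a, a) == 0.0
        assert mn.psnr(a, a) == float("inf")

    def test_constant_difference_closed_forms(self):
        a = mn.ImageSlice(np.full((8, 8), 0.2))
        b = mn.ImageSlice(np.full((8, 8), 0.7))
        assert abs(mn.rmse(a, b) - 0.5) < 1e-12
        c = mn.ImageSlice(np.full((8, 8), 0.3))
        assert abs(mn.psnr(a, c, data_range=1.0) - 20.0) < 1e-9

    def test_rmse_matches_loop_oracle(self):
        for _ in range(50):
            a, b = _pair(6, 7)
            acc = 0.0
            for i in range(6):
                for j in range(7):
                    acc += (a.pixels[i, j] - b.pixels[i, j]) ** 2
            assert abs(mn.rmse(a, b) - np.sqrt(acc / 42)) < 1e-9

    def test_psnr_rmse_consistency(self):
        for _ in range(50):
            a, b = _pair()
            r = mn.rmse(a, b)
            assert abs(mn.psnr(a, b) - 20 * np.log10(1.0 / r)) < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mn.rmse(mn.ImageSlice(np.zeros((8, 8))), mn.ImageSlice(np.zeros((8, 9))))


class TestSsim:
    def test_identical_images_score_one(self):
        a, _ = _pair()
        assert mn.ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        a, b = _pair()
        assert mn.ssim(a, b) == pytest.approx(mn.ssim(b, a), abs=1e-9)

    def test_constant_images_closed_form(self):
        mu_x, mu_y = 0.3, 0.6
        a = mn.ImageSlice(np.full((16, 16), mu_x))
        b = mn.ImageSlice(np.full((16, 16), mu_y))
        c1 = 0.01 ** 2
        expected = (2 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
        assert mn.ssim(a, b) == pytest.approx(expected, abs=1e-7)

    def test_matches_windowed_oracle(self):
        for _ in range(50):
            a, b = _pair(16, 16)
            assert mn.ssim(a, b) == pytest.approx(
                ssim_window_oracle(a.pixels, b.pixels), abs=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            mn.ssim(mn.ImageSlice(np.zeros((8, 8))), mn.ImageSlice(np.zeros((8, 8))))


class TestPairedTTest:
    def test_zero_variance_contract(self):
        t, p = mn.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        a = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        b = a - np.array([1, 2, 3, 4, 5.0])
        t, p = mn.paired_t_test(a, b)
        assert t == pytest.approx(4.2426, abs=1e-4)
        assert p == pytest.approx(0.0132, abs=2e-4)

    def test_antisymmetry(self):
        a = RNG.random(10)
        b = RNG.random(10)
        t1, p1 = mn.paired_t_test(a, b)
        t2, p2 = mn.paired_t_test(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_reference_implementation(self):
        for _ in range(50):
            n = int(RNG.integers(3, 30))
            a = RNG.normal(size=n)
            b = a + RNG.normal(size=n) * 0.5
            t, p = mn.paired_t_test(a, b)
            ref = stats.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-6)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mn.paired_t_test([1.0], [2.0])
        with pytest.raises(ValidationError):
            mn.paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 3, 0.0167), (0.05, 1, 0.05), (0.03, 3, 0.01),
    ])
    def test_thresholds(self, alpha, m, expected):
        assert mn.bonferroni_threshold(alpha, m) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mn.bonferroni_threshold(0.0, 3)
        with pytest.raises(ValidationError):
            mn.bonferroni_threshold(0.05, 0)


@pytest.fixture(scope="module")
def samples():
    cohort = mn.generate_cohort(mn.PhantomSpec(modality_tag="pet_like"), 5, seed=41)
    return [mn.degrade(im, mn.DegradationSpec(kind="count_thinning", seed=i))
            for i, im in enumerate(cohort)]


class TestEvaluateModel:
    def test_perfect_stub(self, samples):
        lookup = {id(s.low_quality): s.high_quality for s in samples}
        records, _ = mn.evaluate_model(lambda img: lookup[id(img)], samples)
        assert all(r.rmse == 0 for r in records)
        assert all(r.ssim == pytest.approx(1.0, abs=1e-9) for r in records)

    def test_identity_stub_equals_input_baseline(self, samples):
        records, _ = mn.evaluate_model(lambda img: img, samples)
        for r, s in zip(records, samples):
            assert r.psnr == pytest.approx(mn.psnr(s.low_quality, s.high_quality), abs=1e-9)

    def test_record_count_and_aggregates(self, samples):
        records, agg = mn.evaluate_model(lambda img: img, samples)
        assert len(records) == len(samples)
        assert ("psnr", "mean") in agg.columns
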