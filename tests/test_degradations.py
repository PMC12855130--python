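"""Degradation simulators: identities, noise statistics and dispatch."""

import math

import numpy as np
import pytest

import miranet as mn
from miranet.degradations import fbp_reference, kspace_mask
from miranet.image import ValidationError


@pytest.fixture(scope="module")
def phantoms():
    return {tag: mn.generate_phantom(mn.PhantomSpec(modality_tag=tag, seed=31))
            for tag in ("mri_like", "ct_like", "pet_like")}


class TestKspace:
    @pytest.mark.parametrize("h,acc", [(64, 4), (64, 1), (128, 4), (96, 3), (100, 7)])
    def test_retained_line_count(self, h, acc):
        mask = kspace_mask(h, acc, center_fraction=0.08, seed=0)
        assert int(mask.sum()) == math.ceil(h / acc)

    def test_full_sampling_is_identity(self, phantoms):
        img = phantoms["mri_like"]
        out = mn.undersample_kspace(img, acceleration=1, seed=0)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-10)

    def test_zero_image_stays_zero(self):
        z = mn.ImageSlice(np.zeros((64, 64)), "mri_like")
        out = mn.undersample_kspace(z, acceleration=4, seed=1)
        assert np.all(out.pixels == 0)

    def test_undersampling_degrades(self, phantoms):
        img = phantoms["mri_like"]
        out = mn.undersample_kspace(img, acceleration=4, seed=2)
        assert mn.psnr(out, img) < 60

    def test_acceleration_above_height_rejected(self, phantoms):
        with pytest.raises(ValidationError):
            mn.undersample_kspace(phantoms["mri_like"], acceleration=100)


class TestLowDoseCT:
    def test_huge_budget_approaches_noiseless_fbp(self, phantoms):
        img = phantoms["ct_like"]
        out = mn.simulate_low_dose_ct(img, dose_fraction=1.0, photon_budget=1e12, seed=3)
        ref = fbp_reference(img)
        assert np.sqrt(np.mean((out.pixels - ref.pixels) ** 2)) < 1e-4

    def test_noise_monotone_in_dose(self, phantoms):
        """Monte-Carlo deviation from the noiseless FBP strictly decreases
        as dose_fraction increases over {0.1, 0.25, 0.5, 1.0}."""
        img = phantoms["ct_like"]
        ref = fbp_reference(img).pixels
        mses = []
        for dose in (0.1, 0.25, 0.5, 1.0):
            reps = [np.mean((mn.simulate_low_dose_ct(img, dose_fraction=dose,
                                                     seed=1000 + r).pixels - ref) ** 2)
                    for r in range(30)]
            mses.append(np.mean(reps))
        assert all(a > b for a, b in zip(mses, mses[1:]))

    def test_zero_image_reconstructs_near_zero(self):
        z = mn.ImageSlice(np.zeros((64, 64)), "ct_like")
        out = mn.simulate_low_dose_ct(z, photon_budget=1e8, seed=4)
        assert np.abs(out.pixels).max() < 0.02

    @pytest.mark.parametrize("kwargs", [
        dict(dose_fraction=0.0), dict(dose_fraction=1.5),
        dict(photon_budget=0.0), dict(n_angles=4),
    ])
    def test_invalid_parameters_rejected(self, phantoms, kwargs):
        with pytest.raises(ValidationError):
            mn.simulate_low_dose_ct(phantoms["ct_like"], **kwargs)


class TestCountThinning:
    def test_factor_one_without_noise_is_identity(self, phantoms):
        img = phantoms["pet_like"]
        out = mn.thin_counts(img, reduction_factor=1, seed=0, poisson_noise=False)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-9)

    def test_expectation_preserved_after_rescale(self):
        """100 thinning reps on a constant image: grand mean within 2 SE."""
        c = 0.4
        img = mn.ImageSlice(np.full((32, 32), c), "pet_like")
        reps = np.array([mn.thin_counts(img, reduction_factor=12, count_scale=100.0,
                                        seed=r).pixels for r in range(100)])
        # per-pixel variance of thinned-and-rescaled counts: (r*c/scale)^2 * scale/r
        var = (12 * c / 100.0) ** 2 * (100.0 / 12)
        se = np.sqrt(var / reps.size)
        assert abs(reps.mean() - c) < 2 * se

    def test_zero_image_stays_zero(self):
        z = mn.ImageSlice(np.zeros((32, 32)), "pet_like")
        out = mn.thin_counts(z, reduction_factor=12, seed=5)
        assert np.all(out.pixels == 0)

    def test_thinning_degrades(self, phantoms):
        img = phantoms["pet_like"]
        out = mn.thin_counts(img, reduction_factor=12, seed=6)
        assert mn.psnr(out, img) < 60

    def test_invalid_factor_rejected(self, phantoms):
        with pytest.raises(ValidationError):
            mn.thin_counts(phantoms["pet_like"], reduction_factor=0)


class TestDegradeDispatch:
    @pytest.mark.parametrize("kind,tag", [
        ("kspace_undersample", "mri_like"),
        ("low_dose_ct", "ct_like"),
        ("count_thinning", "pet_like"),
    ])
    def test_routes_and_labels(self, phantoms, kind, tag):
        spec = mn.DegradationSpec(kind=kind, seed=11)
        pair = mn.degrade(phantoms[tag], spec)
        assert pair.degradation_label == kind
        assert np.array_equal(pair.high_quality.pixels, phantoms[tag].pixels)
        if kind == "kspace_undersample":
            direct = mn.undersample_kspace(phantoms[tag], spec.acceleration,
                                           spec.center_fraction, spec.seed)
            np.testing.assert_array_equal(pair.low_quality.pixels, direct.pixels)

    def test_deterministic(self, phantoms):
        spec = mn.DegradationSpec(kind="count_thinning", seed=12)
        a = mn.degrade(phantoms["pet_like"], spec)
        b = mn.degrade(phantoms["pet_like"], spec)
        assert np.array_equal(a.low_quality.pixels, b.low_quality.pixels)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            mn.DegradationSpec(kind="motion_blur")


def test_default_specs_inject_real_noise(phantoms):
    """Mean PSNR of degraded vs clean over a 50-image cohort stays below 60 dB."""
    for kind, tag in (("kspace_undersample", "mri_like"),
                      ("low_dose_ct", "ct_like"),
                      ("count_thinning", "pet_like")):
        cohort = mn.generate_cohort(mn.PhantomSpec(modality_tag=tag), 50, seed=77)
        vals = [mn.psnr(mn.degrade(im, mn.DegradationSpec(kind=kind, seed=i)).low_quality, im)
                for i, im in enumerate(cohort)]
        assert np.mean(vals) < 60.0
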