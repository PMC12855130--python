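"""Modulated U-Net: shapes, identity-at-initialization, modulation algebra."""

import numpy as np
import pytest

import miranet as mn
from miranet import nn
from miranet.image import ValidationError
from miranet.model import FeatureMap

RNG = np.random.default_rng(11)


def _img(h=16, w=16):
    return mn.ImageSlice(RNG.random((h, w)))


class TestShallow:
    def test_shape(self, tiny_model):
        fm = mn.extract_shallow(_img(16, 16), tiny_model)
        assert fm.values.shape == (8, 16, 16)

    def test_zero_in_zero_out(self, tiny_model):
        fm = mn.extract_shallow(mn.ImageSlice(np.zeros((16, 16))), tiny_model)
        assert np.all(fm.values == 0)

    def test_deterministic(self, tiny_model):
        img = _img()
        a = mn.extract_shallow(img, tiny_model)
        b = mn.extract_shallow(img, tiny_model)
        np.testing.assert_array_equal(a.values, b.values)


class TestGenerateModulation:
    def test_identity_at_initialization(self, tiny_model):
        instr = RNG.normal(size=256)
        for block_id in tiny_model.modulated_block_ids:
            mod = mn.generate_modulation(instr, block_id, tiny_model)
            np.testing.assert_array_equal(mod.gamma, np.ones_like(mod.gamma))
            np.testing.assert_array_equal(mod.beta, np.zeros_like(mod.beta))

    def test_lengths_match_block_channels(self, tiny_model):
        mod = mn.generate_modulation(np.zeros(256), "bottleneck", tiny_model)
        c = tiny_model.config.level_channels[-1]
        assert mod.gamma.shape == (c,) and mod.beta.shape == (c,)

    def test_deterministic(self, tiny_model):
        instr = RNG.normal(size=256)
        a = mn.generate_modulation(instr, "enc0", tiny_model)
        b = mn.generate_modulation(instr, "enc0", tiny_model)
        np.testing.assert_array_equal(a.gamma, b.gamma)

    def test_unknown_block_rejected(self, tiny_model):
        with pytest.raises(ValidationError):
            mn.generate_modulation(np.zeros(256), "enc99", tiny_model)


class TestModulate:
    def test_identity_parameters(self):
        fm = FeatureMap(values=RNG.normal(size=(4, 5, 5)))
        mod = mn.ModulationParams(gamma=np.ones(4), beta=np.zeros(4), block_id="b")
        np.testing.assert_array_equal(mn.modulate(fm, mod).values, fm.values)

    def test_zero_features_give_beta(self):
        mod = mn.ModulationParams(gamma=RNG.normal(size=3), beta=RNG.normal(size=3),
                                  block_id="b")
        out = mn.modulate(FeatureMap(values=np.zeros((3, 4, 4))), mod)
        np.testing.assert_allclose(out.values, np.broadcast_to(
            mod.beta[:, None, None], (3, 4, 4)))

    def test_matches_elementwise_loop(self):
        fm = FeatureMap(values=RNG.normal(size=(2, 2, 2)))
        mod = mn.ModulationParams(gamma=RNG.normal(size=2), beta=RNG.normal(size=2),
                                  block_id="b")
        out = mn.modulate(fm, mod).values
        for c in range(2):
            for i in range(2):
                for j in range(2):
                    expected = mod.gamma[c] * fm.values[c, i, j] + mod.beta[c]
                    assert abs(out[c, i, j] - expected) < 1e-7

    def test_channel_mismatch_rejected(self):
        mod = mn.ModulationParams(gamma=np.ones(5), beta=np.zeros(5), block_id="b")
        with pytest.raises(ValidationError):
            mn.modulate(FeatureMap(values=np.zeros((3, 4, 4))), mod)


class TestRestore:
    def test_shape_preserved_for_awkward_sizes(self, tiny_model):
        img = _img(23, 18)
        out = tiny_model.restore(img)
        assert out.shape == (23, 18)

    def test_deterministic(self, tiny_model):
        img = _img()
        np.testing.assert_array_equal(tiny_model.restore(img).pixels,
                                      tiny_model.restore(img).pixels)

    def test_output_within_intensity_range(self, tiny_model):
        out = tiny_model.restore(_img())
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_non_finite_input_rejected(self, tiny_model):
        bad = mn.ImageSlice(np.ones((16, 16)))
        object.__setattr__(bad, "pixels", np.full((16, 16), np.nan))
        with pytest.raises(ValidationError):
            tiny_model.restore(bad)


def test_fresh_model_equals_unmodulated_backbone():
    """Zero-initialized modulation heads make guidance a strict no-op at init."""
    model = mn.MiraNet(mn.ModelConfig(depth=3, base_channels=8, n_atoms=4,
                                      mlp_hidden=16), seed=2)
    for k in range(10):
        x = nn.Tensor(np.random.default_rng(k).random((1, 32, 32, 1), np.float32))
        with_mod, _, _ = model.forward(x, use_modulation=True)
        without, _, _ = model.forward(x, use_modulation=False)
        assert np.abs(with_mod.numpy() - without.numpy()).max() < 1e-5


def test_single_sample_overfit_improves_psnr():
    """200 optimization steps on one pair beat the degraded-input PSNR."""
    img = mn.generate_phantom(mn.PhantomSpec(modality_tag="pet_like", height=32,
                                             width=32, seed=13))
    pair = mn.degrade(img, mn.DegradationSpec(kind="count_thinning", seed=14))
    model = mn.MiraNet(mn.ModelConfig(depth=2, base_channels=8, n_atoms=4,
                                      mlp_hidden=16), seed=4)
    opt = nn.Adam(model.parameters(), lr=1e-3)
    x = nn.Tensor(pair.low_quality.pixels[None, :, :, None].astype(np.float32))
    y = pair.high_quality.pixels[None, :, :, None].astype(np.float32)
    for _ in range(200):
        out, _, _ = model.forward(x)
        loss = nn.l1_loss(out, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert mn.psnr(model.restore(pair.low_quality), pair.high_quality) > \
        mn.psnr(pair.low_quality, pair.high_quality)
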