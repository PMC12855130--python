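"""Instruction-modulated U-Net restoration backbone.

The network is a standard hierarchical encoder-decoder: a 3x3 convolution
extracts shallow features, encoder blocks (two padded 3x3 convolutions with
ReLUs) alternate with 2x average-pool downsampling, and decoder blocks mirror
them with bilinear upsampling and skip concatenation.  What makes it
instruction-guided is that every convolutional block carries a dedicated
two-layer perceptron mapping the 256-d instruction vector to a per-channel
scale ``gamma`` and bias ``beta``; the block output is recalibrated as

    f_mod = gamma * f_orig + beta        (broadcast over spatial positions)

The final MLP layer is zero-initialized and gamma is parameterized as
``1 + dgamma``, so a freshly initialized model is exactly the unmodulated
backbone — guidance is learned, never imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .arc import INSTRUCTION_DIM, AdaptiveRestorationCore, InstructionState
from .image import ImageSlice, ValidationError


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters of backbone + ARC + modulation MLPs."""

    depth: int = 4
    base_channels: int = 32
    channel_growth: int = 2
    instruction_dim: int = INSTRUCTION_DIM
    n_atoms: int = 8
    mlp_hidden: int = 64
    use_global_residual: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.base_channels < 8:
            raise ValidationError("base_channels must be >= 8")
        if self.instruction_dim != INSTRUCTION_DIM:
            raise ValidationError(f"instruction_dim is fixed at {INSTRUCTION_DIM}")

    @property
    def level_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * self.channel_growth ** i
                     for i in range(self.depth))


@dataclass(frozen=True)
class ModulationParams:
    """Per-channel affine parameters produced for one block."""

    gamma: np.ndarray
    beta: np.ndarray
    block_id: str

    def __post_init__(self) -> None:
        if np.asarray(self.gamma).shape != np.asarray(self.beta).shape:
            raise ValidationError("gamma and beta must have equal length")


@dataclass(frozen=True)
class FeatureMap:
    """A (channels, height, width) activation tensor with its block tag."""

    values: np.ndarray
    block_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValidationError("feature map values must be (C, H, W)")
        if not np.all(np.isfinite(v)):
            raise ValidationError("feature map contains non-finite values")
        object.__setattr__(self, "values", v)


class ModulationMLP(nn.Module):
    """Two-layer perceptron: instruction -> (gamma, beta) for one block."""

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator):
        self.fc1 = nn.Linear(INSTRUCTION_DIM, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, 2 * channels, rng=rng, zero_init=True)
        self.channels = channels

    def __call__(self, instruction: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = self.fc2(nn.relu(self.fc1(instruction)))
        dgamma = nn.narrow(h, 1, 0, self.channels)
        beta = nn.narrow(h, 1, self.channels, self.channels)
        gamma = nn.add(dgamma, nn.Tensor(np.float32(1.0)))
        return gamma, beta


class ConvBlock(nn.Module):
    """Two padded 3x3 convolutions with ReLUs, then channel-wise modulation."""

    def __init__(self, c_in: int, c_out: int, hidden: int, rng: np.random.Generator):
        self.conv_a = nn.Conv2d(c_in, c_out, rng=rng)
        self.conv_b = nn.Conv2d(c_out, c_out, rng=rng)
        self.mod = ModulationMLP(c_out, hidden, rng)

    def __call__(self, x: nn.Tensor, instruction: nn.Tensor | None) -> nn.Tensor:
        h = nn.relu(self.conv_b(nn.relu(self.conv_a(x))))
        if instruction is None:
            return h
        gamma, beta = self.mod(instruction)
        b, c = gamma.shape  # broadcast over NHWC spatial axes
        gamma = nn.reshape(gamma, (b, 1, 1, c))
        beta = nn.reshape(beta, (b, 1, 1, c))
        return nn.add(nn.mul(gamma, h), beta)


class MiraNet(nn.Module):
    """ARC-guided restoration network (backbone + ARC + modulation MLPs)."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(7,)))
        self.config = config
        ch = config.level_channels
        self.arc = AdaptiveRestorationCore(config.n_atoms, rng=rng)
        self.shallow = nn.Conv2d(1, ch[0], rng=rng)
        self.enc_blocks = [ConvBlock(ch[i], ch[i], config.mlp_hidden, rng)
                           for i in range(config.depth - 1)]
        self.down_convs = [nn.Conv2d(ch[i], ch[i + 1], rng=rng)
                           for i in range(config.depth - 1)]
        self.bottleneck = ConvBlock(ch[-1], ch[-1], config.mlp_hidden, rng)
        self.up_convs = [nn.Conv2d(ch[i + 1], ch[i], rng=rng)
                         for i in reversed(range(config.depth - 1))]
        self.dec_blocks = [ConvBlock(2 * ch[i], ch[i], config.mlp_hidden, rng)
                           for i in reversed(range(config.depth - 1))]
        self.out_conv = nn.Conv2d(ch[0], 1, rng=rng)

    # ------------------------------------------------------------------
    @property
    def modulated_block_ids(self) -> list[str]:
        d = self.config.depth
        return ([f"enc{i}" for i in range(d - 1)] + ["bottleneck"]
                + [f"dec{i}" for i in reversed(range(d - 1))])

    def _block(self, block_id: str) -> ConvBlock:
        d = self.config.depth
        if block_id == "bottleneck":
            return self.bottleneck
        kind, idx = block_id[:3], block_id[3:]
        if idx.isdigit():
            i = int(idx)
            if kind == "enc" and i < d - 1:
                return self.enc_blocks[i]
            if kind == "dec" and i < d - 1:
                return self.dec_blocks[d - 2 - i]
        raise ValidationError(f"unknown block_id {block_id!r}")

    # ------------------------------------------------------------------
    def forward(self, x: nn.Tensor, use_modulation: bool = True,
                alpha_override: np.ndarray | None = None
                ) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        """Run the full network on an (N, H, W, 1) channels-last batch.

        Returns ``(output, alpha, instruction)``; the output is *not* clamped
        (clamping belongs to inference, see :meth:`restore`).  With
        ``alpha_override`` the ARC attention is replaced by a fixed simplex
        vector — used to probe instruction sensitivity.
        """
        if alpha_override is not None:
            alpha = nn.Tensor(np.broadcast_to(
                np.asarray(alpha_override, dtype=np.float32),
                (x.shape[0], self.config.n_atoms)).copy())
            instruction = self.arc.compose(alpha)
        else:
            alpha, instruction = self.arc.forward(x)
        instr = instruction if use_modulation else None

        h = self.shallow(x)
        skips = []
        for blk, down in zip(self.enc_blocks, self.down_convs):
            h = blk(h, instr)
            skips.append(h)
            h = down(nn.avg_pool2(h))
        h = self.bottleneck(h, instr)
        for up, blk, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            h = up(nn.upsample_bilinear2(h))
            h = blk(nn.concat([h, skip], axis=3), instr)
        out = self.out_conv(h)
        if self.config.use_global_residual:
            out = nn.add(out, x)
        return out, alpha, instruction

    def restore(self, image: ImageSlice, use_modulation: bool = True,
                alpha_override: np.ndarray | None = None) -> ImageSlice:
        """Restore one slice: pad to the grid, forward, crop, clamp to range."""
        if not np.all(np.isfinite(image.pixels)):
            raise ValidationError("input contains non-finite values")
        h, w = image.shape
        m = 2 ** (self.config.depth - 1)
        ph, pw = (-h) % m, (-w) % m
        px = image.pixels
        if ph or pw:
            px = np.pad(px, ((0, ph), (0, pw)), mode="reflect")
        out, _, _ = self.forward(nn.Tensor(px[None, :, :, None].astype(np.float32)),
                                 use_modulation=use_modulation,
                                 alpha_override=alpha_override)
        rec = out.numpy()[0, :h, :w, 0].astype(np.float64)
        lo, hi = image.intensity_range
        return image.with_pixels(np.clip(rec, lo, hi))

    def instruction_state(self, image: ImageSlice) -> InstructionState:
        from .arc import arc_forward

        return arc_forward(image, self.arc)


# -- functional surface -------------------------------------------------------

def extract_shallow(image: ImageSlice, model: MiraNet) -> FeatureMap:
    """Shallow 3x3 feature extraction; spatial dimensions preserved."""
    if image.pixels.ndim != 2:
        raise ValidationError("expected a single-channel 2-D slice")
    x = nn.Tensor(image.pixels[None, :, :, None].astype(np.float32))
    values = model.shallow(x).numpy()[0].transpose(2, 0, 1)
    return FeatureMap(values=np.ascontiguousarray(values), block_id="shallow")


def generate_modulation(instruction: np.ndarray, block_id: str,
                        model: MiraNet) -> ModulationParams:
    """Evaluate one block's MLP on an instruction vector."""
    instruction = np.asarray(instruction, dtype=np.float32)
    if instruction.shape != (INSTRUCTION_DIM,):
        raise ValidationError(f"instruction must have length {INSTRUCTION_DIM}")
    block = model._block(block_id)
    gamma, beta = block.mod(nn.Tensor(instruction[None]))
    return ModulationParams(gamma=gamma.numpy()[0].astype(np.float64),
                            beta=beta.numpy()[0].astype(np.float64),
                            block_id=block_id)


def modulate(features: FeatureMap, mod: ModulationParams) -> FeatureMap:
    """Channel-wise affine recalibration ``gamma * f + beta``."""
    gamma = np.asarray(mod.gamma, dtype=np.float64)
    beta = np.asarray(mod.beta, dtype=np.float64)
    if features.values.shape[0] != gamma.size:
        raise ValidationError(
            f"feature channels ({features.values.shape[0]}) != gamma length ({gamma.size})")
    out = gamma[:, None, None] * features.values + beta[:, None, None]
    return FeatureMap(values=out, block_id=features.block_id)
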