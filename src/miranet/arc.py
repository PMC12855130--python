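"""Adaptive Restoration Core (ARC).

A compact three-stage strided convolutional encoder inspects the degraded
input and emits N channels; global average pooling followed by a softmax turns
them into attention weights ``alpha`` on the N-simplex.  These weights form a
convex combination of the columns of a learnable 256 x N instruction
dictionary D — each column an atom encoding a primitive restoration strategy —
yielding the instruction vector ``i_ir`` in R^256 that conditions every block
of the restoration backbone:

    i_ir = sum_i alpha_i * D_i,   alpha = softmax(GAP(E(x_lq)))

No degradation labels are used anywhere: the attention is learned end-to-end
from the restoration loss alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .image import ImageSlice, ValidationError

#: Fixed dimensionality of the instruction space (dictionary row count).
INSTRUCTION_DIM = 256

#: Channel widths of the two hidden encoder stages (the third emits n_atoms).
ENCODER_CHANNELS = (16, 32)


@dataclass(frozen=True)
class InstructionState:
    """Attention weights on the simplex plus the composed instruction vector."""

    attention: np.ndarray
    instruction: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.attention, dtype=np.float64)
        if a.ndim != 1 or a.size < 2:
            raise ValidationError("attention must be a vector of length >= 2")
        if np.any(a < -1e-9) or abs(a.sum() - 1.0) > 1e-6:
            raise ValidationError("attention must lie on the probability simplex")
        if np.asarray(self.instruction).shape != (INSTRUCTION_DIM,):
            raise ValidationError(f"instruction must have length {INSTRUCTION_DIM}")
        object.__setattr__(self, "attention", a)
        object.__setattr__(self, "instruction",
                           np.asarray(self.instruction, dtype=np.float64))


class AdaptiveRestorationCore(nn.Module):
    """Degradation encoder E, GAP + softmax attention, instruction dictionary."""

    def __init__(self, n_atoms: int = 8, rng: np.random.Generator | None = None):
        if n_atoms < 2:
            raise ValidationError("n_atoms must be >= 2")
        rng = rng or np.random.default_rng(0)
        c1, c2 = ENCODER_CHANNELS
        self.conv1 = nn.Conv2d(1, c1, stride=2, rng=rng)
        self.conv2 = nn.Conv2d(c1, c2, stride=2, rng=rng)
        self.conv3 = nn.Conv2d(c2, n_atoms, stride=2, rng=rng)
        # atoms drawn at scale 1/sqrt(256); trained with the restoration loss
        self.dictionary = nn.Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(INSTRUCTION_DIM), (INSTRUCTION_DIM, n_atoms)),
            requires_grad=True)
        self.n_atoms = n_atoms

    # -- graph-building pieces (used inside training) -----------------------
    def encode(self, x: nn.Tensor) -> nn.Tensor:
        # the final stage stays linear: its pooled output feeds a softmax, and
        # sign-unconstrained logits let atoms be actively suppressed
        h = nn.relu(self.conv1(x))
        h = nn.relu(self.conv2(h))
        return self.conv3(h)

    def attend(self, featmap: nn.Tensor) -> nn.Tensor:
        # featmap is NHWC: pool over the spatial axes
        return nn.softmax(nn.mean(featmap, axes=(1, 2)), axis=-1)

    def compose(self, alpha: nn.Tensor) -> nn.Tensor:
        # (batch, N) @ (N, 256) -> (batch, 256)
        return nn.matmul(alpha, _transpose(self.dictionary))

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        alpha = self.attend(self.encode(x))
        return alpha, self.compose(alpha)


def _transpose(t: nn.Tensor) -> nn.Tensor:
    def bw(g):
        t.accumulate(g.T)

    out = nn.Tensor(t.data.T)
    out.requires_grad = True
    out._parents = (t,)
    out._backward = bw
    return out


def _pad_to_multiple(pixels: np.ndarray, multiple: int) -> np.ndarray:
    h, w = pixels.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        pixels = np.pad(pixels, ((0, ph), (0, pw)), mode="reflect")
    return pixels


# -- functional surface -------------------------------------------------------

def encode_degradation(image: ImageSlice, arc: AdaptiveRestorationCore) -> np.ndarray:
    """Run the compact encoder; returns an (N, H/8, W/8) feature map.

    Inputs whose sides are not divisible by 8 are reflect-padded first.
    """
    px = _pad_to_multiple(image.pixels, 8)
    x = nn.Tensor(px[None, :, :, None])
    return np.ascontiguousarray(arc.encode(x).numpy()[0].transpose(2, 0, 1))


def pool_and_attend(featmap: np.ndarray) -> np.ndarray:
    """Softmax of per-channel spatial means: a point on the N-simplex."""
    fm = np.asarray(featmap, dtype=np.float64)
    if fm.ndim != 3:
        raise ValidationError("feature map must be (channels, H, W)")
    logits = fm.mean(axis=(1, 2))
    z = np.exp(logits - logits.max())
    return z / z.sum()


def compose_instruction(alpha: np.ndarray, dictionary: np.ndarray) -> np.ndarray:
    """Convex combination of dictionary columns: ``sum_i alpha_i D_i``."""
    alpha = np.asarray(alpha, dtype=np.float64)
    dictionary = np.asarray(dictionary, dtype=np.float64)
    if dictionary.ndim != 2 or alpha.ndim != 1 or dictionary.shape[1] != alpha.size:
        raise ValidationError(
            f"dictionary columns ({dictionary.shape}) must match alpha length ({alpha.size})")
    return dictionary @ alpha


def arc_forward(image: ImageSlice, arc: AdaptiveRestorationCore) -> InstructionState:
    """Full ARC pass: encoder -> GAP+softmax -> dictionary combination."""
    featmap = encode_degradation(image, arc)
    alpha = pool_and_attend(featmap)
    instruction = compose_instruction(alpha, arc.dictionary.data)
    return InstructionState(attention=alpha, instruction=instruction)
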