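"""Synthetic high-quality phantom images and cohort handling.

The generator produces reproducible 2-D phantoms with modality-distinct
structure so that the three restoration tasks present genuinely different
image statistics to the network:

* ``mri_like`` — many overlapping soft-edged ellipses inside a head-like
  outline, mimicking smooth tissue contrast of T2-weighted brain slices;
* ``ct_like`` — piecewise-constant elliptical regions inside a body outline,
  mimicking the flat organ plateaus and sharp boundaries of CT;
* ``pet_like`` — a smooth low-intensity background with a few sparse bright
  Gaussian foci, mimicking tracer-avid lesions (heavy right tail).

All randomness derives from explicit integer seeds; every operation is a pure
function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import MODALITY_TAGS, ImageSlice, ValidationError, normalize

# Frozen per-modality shape-parameter ranges (relative to image size):
# (n extra structures beyond n_structures is never drawn; these are the
# uniform ranges for ellipse semi-axes and intensities).
_MODALITY_RANGES = {
    # semi-axis range (fraction of size), intensity range of structures
    "mri_like": {"axis": (0.05, 0.25), "intensity": (0.15, 0.9)},
    "ct_like": {"axis": (0.08, 0.30), "intensity": (0.2, 1.0)},
    "pet_like": {"axis": (0.02, 0.06), "intensity": (0.6, 1.0)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic phantom."""

    modality_tag: str = "mri_like"
    height: int = 64
    width: int = 64
    n_structures: int = 10
    intensity_range: tuple[float, float] = (0.0, 1.0)
    smoothness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality_tag not in MODALITY_TAGS:
            raise ValidationError(f"unknown modality_tag {self.modality_tag!r}")
        if self.height < 16 or self.width < 16:
            raise ValidationError("height and width must be >= 16")
        if self.n_structures < 1:
            raise ValidationError("n_structures must be >= 1")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValidationError("intensity_range lower must be < upper")


@dataclass(frozen=True)
class SplitAllocation:
    """Exact train/validation/test counts for a cohort."""

    train: int
    validation: int
    test: int

    def __post_init__(self) -> None:
        if min(self.train, self.validation, self.test) < 0:
            raise ValidationError("allocation counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.train + self.validation + self.test


def _item_seed(seed: int, index: int) -> np.random.SeedSequence:
    # SeedSequence spawn keys give a collision-free mixing of (seed, index).
    return np.random.SeedSequence(entropy=seed, spawn_key=(index,))


def _ellipse_mask(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                  ay: float, ax: float, theta: float) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    y, x = yy - cy, xx - cx
    u = (y * ct + x * st) / ay
    v = (-y * st + x * ct) / ax
    return u * u + v * v <= 1.0


def generate_phantom(spec: PhantomSpec) -> ImageSlice:
    """Deterministically render one phantom from ``spec``.

    The same spec (including its seed) always yields a bit-identical image;
    pixel values are min-max normalized into ``spec.intensity_range``.
    """
    # modality enters the stream key so equal seeds across tags stay decorrelated
    tag_key = MODALITY_TAGS.index(spec.modality_tag)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed,
                                                       spawn_key=(tag_key,)))
    h, w = spec.height, spec.width
    size = min(h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    ranges = _MODALITY_RANGES[spec.modality_tag]
    img = np.zeros((h, w))

    # body/head outline common to mri/ct: a large ellipse of base intensity
    if spec.modality_tag in ("mri_like", "ct_like"):
        outline = _ellipse_mask(yy, xx, h / 2, w / 2, 0.45 * h, 0.42 * w,
                                rng.uniform(-0.2, 0.2))
        img[outline] = 0.25 if spec.modality_tag == "ct_like" else 0.15
    else:
        outline = np.ones((h, w), dtype=bool)
        # smooth random background field for PET
        field_ = rng.standard_normal((h, w))
        field_ = ndimage.gaussian_filter(field_, sigma=0.15 * size)
        img += 0.12 * normalize(field_) + 0.03

    a_lo, a_hi = ranges["axis"]
    i_lo, i_hi = ranges["intensity"]
    for _ in range(spec.n_structures):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        ay = rng.uniform(a_lo, a_hi) * size
        ax = rng.uniform(a_lo, a_hi) * size
        theta = rng.uniform(0, np.pi)
        val = rng.uniform(i_lo, i_hi)
        mask = _ellipse_mask(yy, xx, cy, cx, ay, ax, theta) & outline
        if spec.modality_tag == "ct_like":
            img[mask] = val          # piecewise constant: later organs overwrite
        elif spec.modality_tag == "mri_like":
            img[mask] += 0.5 * val   # soft additive tissue compartments
        else:
            # sparse bright focus: gaussian bump
            bump = val * np.exp(-(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2))
            img += bump

    sigma = {"mri_like": spec.smoothness, "ct_like": 0.3 * spec.smoothness,
             "pet_like": 0.75 * spec.smoothness}[spec.modality_tag]
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=sigma)
    img = normalize(img, spec.intensity_range)
    return ImageSlice(pixels=img, modality_tag=spec.modality_tag,
                      intensity_range=spec.intensity_range)


def generate_cohort(spec: PhantomSpec, n: int, seed: int) -> list[ImageSlice]:
    """Generate ``n`` phantoms with per-item seeds mixed from ``(seed, index)``."""
    if n < 1:
        raise ValidationError("cohort size n must be >= 1")
    out = []
    for i in range(n):
        item_seed = int(_item_seed(seed, i).generate_state(1)[0] % (2**31))
        out.append(generate_phantom(
            PhantomSpec(modality_tag=spec.modality_tag, height=spec.height,
                        width=spec.width, n_structures=spec.n_structures,
                        intensity_range=spec.intensity_range,
                        smoothness=spec.smoothness, seed=item_seed)))
    return out


def split_cohort(items: Sequence, allocation: SplitAllocation, seed: int):
    """Partition ``items`` into (train, validation, test) by a seeded shuffle.

    The allocation counts must sum to ``len(items)``; the partitions are
    disjoint, cover all items, and have exactly the allocated sizes.
    """
    if allocation.total != len(items):
        raise ValidationError(
            f"allocation sums to {allocation.total} but cohort has {len(items)} items")
    order = np.random.default_rng(seed).permutation(len(items))
    picked = [items[i] for i in order]
    a, b = allocation.train, allocation.train + allocation.validation
    return picked[:a], picked[a:b], picked[b:]
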