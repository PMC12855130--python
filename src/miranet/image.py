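"""2-D grayscale image container shared across the package.

An :class:`ImageSlice` carries one single-channel slice (row-major, origin at
the top-left) together with a modality tag and the closed intensity interval
its values are expressed in.  It is the unit that flows through the phantom
generator, the degradation simulators, the restoration network and the
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Modality tags understood by the phantom generator and simulators.
MODALITY_TAGS = ("mri_like", "ct_like", "pet_like")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ImageSlice:
    """One 2-D grayscale image slice.

    Parameters
    ----------
    pixels
        ``(height, width)`` float array; all values must be finite.
    modality_tag
        Free-form modality label; the built-in generator uses one of
        ``{"mri_like", "ct_like", "pet_like"}``.
    intensity_range
        Closed ``(lower, upper)`` interval the pixel values live in.
    """

    pixels: np.ndarray
    modality_tag: str = "mri_like"
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("pixels contain non-finite values")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValidationError(f"intensity_range lower must be < upper, got {self.intensity_range}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "intensity_range", (float(lo), float(hi)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def clipped(self) -> "ImageSlice":
        """Return a copy with pixels clipped to ``intensity_range``."""
        lo, hi = self.intensity_range
        return replace(self, pixels=np.clip(self.pixels, lo, hi))

    def with_pixels(self, pixels: np.ndarray) -> "ImageSlice":
        """Return a copy carrying ``pixels`` and the same metadata."""
        return replace(self, pixels=pixels)


def normalize(pixels: np.ndarray, intensity_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Affinely map an array onto ``intensity_range`` (min-max scaling).

    A constant array maps to the lower bound.
    """
    px = np.asarray(pixels, dtype=np.float64)
    lo, hi = intensity_range
    span = px.max() - px.min()
    if span == 0:
        return np.full_like(px, lo)
    return lo + (px - px.min()) * (hi - lo) / span
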