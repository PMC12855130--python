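"""Paired-degradation simulators for the three acquisition protocols.

Each simulator maps a high-quality slice to a low-quality one with the noise
and artifact statistics of its modality:

* **k-space undersampling** (accelerated MRI): the 2-D Fourier transform is
  masked row-wise (phase-encode lines).  A central band of
  ``center_fraction * height`` lines is always retained; further lines are
  drawn uniformly at random until ``ceil(height / acceleration)`` lines are
  kept.  The inverse-transform magnitude is returned.
* **low-dose CT**: the slice (interpreted as an attenuation map) is
  forward-projected over equally spaced angles, line integrals are converted
  to expected transmitted photons ``I = dose_fraction * photon_budget *
  exp(-mu * sinogram)``, Poisson counts are drawn, log-converted back, and the
  slice is reconstructed by filtered back-projection.  Noise therefore enters
  in the projection domain and reconstructs into the spatially correlated
  streaky texture characteristic of low-dose CT.
* **count thinning** (low-dose PET): pixel intensities are scaled to expected
  photon counts, Poisson counts drawn, and each recorded count is kept
  independently with probability ``1/reduction_factor`` — the statistical
  model of list-mode event subsampling.  The thinned counts are rescaled so
  the expectation matches the input.

Degraded outputs are clipped back to the image's intensity range so a single
network can ingest all modalities on a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .image import ImageSlice, ValidationError

DEGRADATION_KINDS = ("kspace_undersample", "low_dose_ct", "count_thinning")

#: Attenuation per pixel length at unit intensity; frozen so that line
#: integrals through a typical normalized phantom give ~20-80% transmission.
CT_ATTENUATION = 0.05


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of one degradation protocol.

    Only the fields relevant to ``kind`` are consulted; the rest are ignored.
    """

    kind: str
    # k-space undersampling
    acceleration: int = 4
    center_fraction: float = 0.08
    # low-dose CT
    dose_fraction: float = 0.25
    photon_budget: float = 1e4
    n_angles: int = 96
    # count thinning
    reduction_factor: int = 12
    count_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEGRADATION_KINDS:
            raise ValidationError(f"unknown degradation kind {self.kind!r}")
        if self.kind == "kspace_undersample":
            if self.acceleration < 1:
                raise ValidationError("acceleration must be >= 1")
            if not 0 <= self.center_fraction < 1:
                raise ValidationError("center_fraction must be in [0, 1)")
        elif self.kind == "low_dose_ct":
            if not 0 < self.dose_fraction <= 1:
                raise ValidationError("dose_fraction must be in (0, 1]")
            if self.photon_budget <= 0:
                raise ValidationError("photon_budget must be positive")
            if self.n_angles < 8:
                raise ValidationError("n_angles must be >= 8")
        elif self.kind == "count_thinning":
            if self.reduction_factor < 1:
                raise ValidationError("reduction_factor must be >= 1")
            if self.count_scale <= 0:
                raise ValidationError("count_scale must be positive")


@dataclass(frozen=True)
class PairedSample:
    """A (degraded, reference) training/evaluation pair."""

    low_quality: ImageSlice
    high_quality: ImageSlice
    degradation_label: str
    spec_used: DegradationSpec

    def __post_init__(self) -> None:
        if self.low_quality.shape != self.high_quality.shape:
            raise ValidationError("paired images must share shape")
        if self.low_quality.intensity_range != self.high_quality.intensity_range:
            raise ValidationError("paired images must share intensity_range")


def kspace_mask(height: int, acceleration: int, center_fraction: float,
                seed: int) -> np.ndarray:
    """Boolean mask over fft-shifted phase-encode lines.

    Exactly ``ceil(height / acceleration)`` lines are retained: the central
    ``round(center_fraction * height)`` band plus uniformly drawn others.
    """
    n_keep = math.ceil(height / acceleration)
    n_center = min(int(round(center_fraction * height)), n_keep)
    mask = np.zeros(height, dtype=bool)
    c = height // 2
    lo = c - n_center // 2
    mask[lo:lo + n_center] = True
    remaining = np.flatnonzero(~mask)
    extra = n_keep - int(mask.sum())
    if extra > 0:
        rng = np.random.default_rng(seed)
        mask[rng.choice(remaining, size=extra, replace=False)] = True
    return mask


def undersample_kspace(image: ImageSlice, acceleration: int = 4,
                       center_fraction: float = 0.08, seed: int = 0) -> ImageSlice:
    """Retain ``ceil(H/acceleration)`` Fourier rows and invert to magnitude."""
    if acceleration < 1:
        raise ValidationError("acceleration must be >= 1")
    h = image.shape[0]
    if acceleration > h:
        raise ValidationError(f"acceleration {acceleration} exceeds image height {h}")
    mask = kspace_mask(h, acceleration, center_fraction, seed)
    k = np.fft.fftshift(np.fft.fft2(image.pixels), axes=0)
    k = k * mask[:, None]
    rec = np.abs(np.fft.ifft2(np.fft.ifftshift(k, axes=0)))
    lo, hi = image.intensity_range
    return image.with_pixels(np.clip(rec, lo, hi))


def _ct_pipeline(image: ImageSlice, dose_fraction: float, photon_budget: float,
                 n_angles: int, seed: int, noiseless: bool) -> np.ndarray:
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sino = radon(image.pixels, theta=theta, circle=False)
    expected = dose_fraction * photon_budget * np.exp(-CT_ATTENUATION * sino)
    if noiseless:
        counts = expected
    else:
        counts = np.random.default_rng(seed).poisson(expected).astype(np.float64)
        counts = np.maximum(counts, 1.0)  # photon starvation guard for the log
    noisy_sino = -np.log(counts / (dose_fraction * photon_budget)) / CT_ATTENUATION
    rec = iradon(noisy_sino, theta=theta, circle=False, filter_name="ramp",
                 output_size=image.shape[0])
    return rec


def simulate_low_dose_ct(image: ImageSlice, dose_fraction: float = 0.25,
                         photon_budget: float = 1e4, n_angles: int = 96,
                         seed: int = 0, noiseless: bool = False) -> ImageSlice:
    """Poisson projection noise at a reduced photon budget, FBP reconstruction."""
    if not 0 < dose_fraction <= 1:
        raise ValidationError("dose_fraction must be in (0, 1]")
    if photon_budget <= 0:
        raise ValidationError("photon_budget must be positive")
    if n_angles < 8:
        raise ValidationError("n_angles must be >= 8")
    rec = _ct_pipeline(image, dose_fraction, photon_budget, n_angles, seed, noiseless)
    lo, hi = image.intensity_range
    return image.with_pixels(np.clip(rec, lo, hi))


def fbp_reference(image: ImageSlice, n_angles: int = 96) -> ImageSlice:
    """Noise-free radon/FBP round trip (the infinite-dose limit)."""
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sino = radon(image.pixels, theta=theta, circle=False)
    rec = iradon(sino, theta=theta, circle=False, filter_name="ramp",
                 output_size=image.shape[0])
    lo, hi = image.intensity_range
    return image.with_pixels(np.clip(rec, lo, hi))


def thin_counts(image: ImageSlice, reduction_factor: int = 12,
                count_scale: float = 100.0, seed: int = 0,
                poisson_noise: bool = True) -> ImageSlice:
    """Binomial thinning of Poisson counts, rescaled to preserve expectation.

    With ``poisson_noise=False`` the expected (continuous) counts are used in
    place of Poisson draws, so ``reduction_factor=1`` is the exact identity.
    """
    if reduction_factor < 1:
        raise ValidationError("reduction_factor must be >= 1")
    if count_scale <= 0:
        raise ValidationError("count_scale must be positive")
    px = image.pixels
    peak = px.max()
    if peak <= 0:
        return image.with_pixels(np.zeros_like(px))
    lam = px / peak * count_scale
    rng = np.random.default_rng(seed)
    if poisson_noise:
        counts = rng.poisson(np.maximum(lam, 0.0))
        kept = rng.binomial(counts, 1.0 / reduction_factor)
    else:
        kept = lam / reduction_factor
    out = kept * (reduction_factor / count_scale) * peak
    lo, hi = image.intensity_range
    return image.with_pixels(np.clip(out, lo, hi))


def degrade(image: ImageSlice, spec: DegradationSpec) -> PairedSample:
    """Dispatch to the simulator selected by ``spec.kind``."""
    if spec.kind == "kspace_undersample":
        low = undersample_kspace(image, spec.acceleration, spec.center_fraction, spec.seed)
    elif spec.kind == "low_dose_ct":
        low = simulate_low_dose_ct(image, spec.dose_fraction, spec.photon_budget,
                                   spec.n_angles, spec.seed)
    elif spec.kind == "count_thinning":
        low = thin_counts(image, spec.reduction_factor, spec.count_scale, spec.seed)
    else:  # pragma: no cover - guarded by DegradationSpec
        raise ValidationError(f"unknown degradation kind {spec.kind!r}")
    return PairedSample(low_quality=low, high_quality=image,
                        degradation_label=spec.kind, spec_used=spec)
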