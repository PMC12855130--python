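"""Image-fidelity metrics and paired-comparison statistics.

PSNR, SSIM and RMSE are the field's standard restoration metrics; paired
two-sided t-tests on per-case metric values, interpreted against a
Bonferroni-adjusted threshold, are the standard way of comparing restoration
models on a common test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .degradations import PairedSample
from .image import ImageSlice, ValidationError


@dataclass(frozen=True)
class MetricRecord:
    case_id: str
    task: str
    psnr: float
    ssim: float
    rmse: float

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.ssim > 1 + 1e-12:
            raise ValidationError("rmse must be >= 0 and ssim <= 1")


def _check_pair(a: ImageSlice, b: ImageSlice) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")


def rmse(a: ImageSlice, b: ImageSlice) -> float:
    """Root mean squared pixel difference."""
    _check_pair(a, b)
    return float(np.sqrt(np.mean((a.pixels - b.pixels) ** 2)))


def psnr(a: ImageSlice, b: ImageSlice, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    _check_pair(a, b)
    if data_range <= 0:
        raise ValidationError("data_range must be positive")
    err = rmse(a, b)
    if err == 0:
        return float("inf")
    return 20.0 * np.log10(data_range) - 20.0 * np.log10(err)


def ssim(a: ImageSlice, b: ImageSlice, data_range: float = 1.0) -> float:
    """Mean structural similarity (Gaussian 11x11 window, sigma 1.5,
    C1=(0.01 R)^2, C2=(0.03 R)^2)."""
    _check_pair(a, b)
    if min(a.shape) < 11:
        raise ValidationError("images must be at least 11x11 for SSIM")
    return float(structural_similarity(
        a.pixels, b.pixels, data_range=data_range, gaussian_weights=True,
        sigma=1.5, win_size=11, use_sample_covariance=False))


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-sided paired t-test; returns ``(t, p)``.

    All-zero differences return ``(0, 1)`` by contract so deterministic
    pipelines producing identical outputs do not crash the harness.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("inputs must be equal-length 1-D sequences of length >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bonferroni_threshold(family_alpha: float, m: int) -> float:
    """Per-comparison significance threshold ``alpha / m`` (4 decimals)."""
    if not 0 < family_alpha < 1:
        raise ValidationError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return round(family_alpha / m, 4)


def evaluate_model(model, test_set: Sequence[PairedSample],
                   data_range: float = 1.0
                   ) -> tuple[list[MetricRecord], pd.DataFrame]:
    """Per-case metrics plus per-task mean/sd aggregates.

    ``model`` is anything with a ``restore(ImageSlice) -> ImageSlice`` method,
    or a bare callable with that signature (useful for baselines and stubs).
    """
    if len(test_set) == 0:
        raise ValidationError("test set must be non-empty")
    restorer: Callable[[ImageSlice], ImageSlice]
    restorer = model.restore if hasattr(model, "restore") else model
    records = []
    for i, s in enumerate(test_set):
        out = restorer(s.low_quality)
        records.append(MetricRecord(
            case_id=f"case{i:04d}", task=s.degradation_label,
            psnr=psnr(out, s.high_quality, data_range),
            ssim=ssim(out, s.high_quality, data_range),
            rmse=rmse(out, s.high_quality)))
    df = pd.DataFrame([{"task": r.task, "psnr": r.psnr, "ssim": r.ssim,
                        "rmse": r.rmse} for r in records])
    aggregates = df.groupby("task").agg(["mean", "std"])
    return records, aggregates
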