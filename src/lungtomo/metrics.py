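"""Image-quality metrics: MSE, RMSE, ISNR, PSNR, SSIM, line profiles.

Definitions (reference image a, candidate b, P pixels):

* ``MSE   = (1/P) * sum (a - b)^2``
* ``EMSE  = sqrt(MSE)`` (root-mean-square error)
* ``ISNR  = 10 log10(MSE_in / MSE_out)`` dB — improvement of one
  reconstruction (MSE_out) over a baseline reconstruction (MSE_in),
  both measured against the same reference;
* ``PSNR  = 10 log10(peak^2 / MSE)`` dB, peak defaulting to the declared
  dynamic range of the reference (a candidate-independent choice; pass
  ``peak=candidate.values.max()`` for the literal maximum-pixel reading);
* ``SSIM``: mean structural similarity over sliding windows,
  ``(2 mu_a mu_b + c1)(2 cov_ab + c2) /
  ((mu_a^2 + mu_b^2 + c1)(sigma_a^2 + sigma_b^2 + c2))`` with
  ``c1 = (k1 * range)^2`` and ``c2 = (k2 * range)^2``; defaults are a 7x7
  uniform window, k1 = 0.01, k2 = 0.03.

Identical images make PSNR/ISNR unbounded; the functions raise
:class:`PerfectReconstructionError` instead of silently returning infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .phantom import ImageGrid

__all__ = ["MetricsReport", "PerfectReconstructionError", "mse", "emse",
           "isnr", "psnr", "ssim", "line_profile", "total_variation",
           "compare"]


class PerfectReconstructionError(ZeroDivisionError):
    """Raised when a log-ratio metric is undefined because MSE = 0."""


def _check_pair(reference: ImageGrid, candidate: ImageGrid) -> None:
    if reference.values.shape != candidate.values.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.values.shape} vs "
            f"candidate {candidate.values.shape}")


def mse(reference: ImageGrid, candidate: ImageGrid) -> float:
    """Mean squared pixel difference."""
    _check_pair(reference, candidate)
    return float(np.mean((reference.values - candidate.values) ** 2))


def emse(reference: ImageGrid, candidate: ImageGrid) -> float:
    """Root-mean-square error, sqrt(MSE)."""
    return float(np.sqrt(mse(reference, candidate)))


def isnr(mse_in: float, mse_out: float) -> float:
    """Improvement in SNR (dB) of a reconstruction over a baseline."""
    if mse_in <= 0 or mse_out <= 0:
        raise PerfectReconstructionError(
            "ISNR is undefined for zero MSE (perfect reconstruction)")
    return float(10.0 * np.log10(mse_in / mse_out))


def psnr(reference: ImageGrid, candidate: ImageGrid,
         peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB."""
    m = mse(reference, candidate)
    if m == 0:
        raise PerfectReconstructionError(
            "PSNR is unbounded for identical images")
    if peak is None:
        lo, hi = reference.value_range
        peak = hi - lo
    if peak <= 0:
        raise ValueError("peak must be positive")
    return float(10.0 * np.log10(peak**2 / m))


def ssim(reference: ImageGrid, candidate: ImageGrid, window: int = 7,
         k1: float = 0.01, k2: float = 0.03,
         data_range: float | None = None) -> float:
    """Mean structural similarity with a uniform sliding window."""
    _check_pair(reference, candidate)
    if window > reference.grid_size:
        raise ValueError(
            f"window {window} exceeds image size {reference.grid_size}")
    if data_range is None:
        lo, hi = reference.value_range
        data_range = hi - lo
    return float(structural_similarity(
        reference.values, candidate.values, win_size=window,
        data_range=data_range, K1=k1, K2=k2, gaussian_weights=False))


def line_profile(image: ImageGrid, index: int, axis: str = "row") -> np.ndarray:
    """Pixel value sequence along one row or column."""
    n = image.grid_size
    if not (0 <= index < n):
        raise IndexError(f"{axis} index {index} out of range for size {n}")
    if axis == "row":
        return image.values[index, :].copy()
    if axis == "column":
        return image.values[:, index].copy()
    raise ValueError("axis must be 'row' or 'column'")


def total_variation(profile: np.ndarray) -> float:
    """Sum of absolute successive differences of a 1D profile."""
    profile = np.asarray(profile, dtype=float).ravel()
    return float(np.sum(np.abs(np.diff(profile))))


@dataclass
class MetricsReport:
    """All quality metrics for one (reference, candidate) pair."""

    mse: float
    emse: float
    psnr: float
    ssim: float
    isnr: float | None = None
    ssim_params: dict = field(default_factory=dict)

    def to_row(self, label: str = "") -> dict:
        row = {"candidate": label, "mse": self.mse, "emse": self.emse,
               "psnr": self.psnr, "ssim": self.ssim}
        if self.isnr is not None:
            row["isnr"] = self.isnr
        return row


def compare(reference: ImageGrid, candidate: ImageGrid,
            baseline: ImageGrid | None = None, peak: float | None = None,
            window: int = 7, k1: float = 0.01, k2: float = 0.03) -> MetricsReport:
    """Full metric panel; ISNR is included when a baseline image is given.

    A perfect reconstruction (zero MSE) is reported with infinite PSNR
    rather than raising, so batch comparisons never abort.
    """
    m = mse(reference, candidate)
    try:
        p = psnr(reference, candidate, peak)
    except PerfectReconstructionError:
        p = float("inf")
    lo, hi = reference.value_range
    s = ssim(reference, candidate, window=window, k1=k1, k2=k2)
    report = MetricsReport(
        mse=m, emse=float(np.sqrt(m)), psnr=p, ssim=s,
        ssim_params={"window": window, "k1": k1, "k2": k2,
                     "data_range": hi - lo})
    if baseline is not None:
        m_in = mse(reference, baseline)
        try:
            report.isnr = isnr(m_in, m)
        except PerfectReconstructionError:
            report.isnr = float("inf")
    return report
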