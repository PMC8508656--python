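"""Richardson-Lucy deconvolution with an image-derived SNR stopping rule.

Deconvolution in the source workflow used a commercial maximum-likelihood
restoration configured by an iteration cap (40) and a signal-to-noise ratio
estimated from the image histogram.  This module provides the open classic
equivalent: the Richardson-Lucy multiplicative MLE iteration for a Gaussian
PSF, stopped either at ``max_iterations`` or when the relative L1 change of
the estimate falls below ``stop_tol``.  By convention ``stop_tol = 1 / snr**2``
with the SNR estimated as ``3 * sqrt(max / min_positive)`` from the image
histogram; both knobs are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .simulate import fwhm_to_sigma


@dataclass
class DeconvConfig:
    """Settings for one restoration run.

    ``psf_fwhm_nm`` and ``pixel_size_nm`` define the Gaussian PSF in pixel
    units; ``snr`` (if None) is estimated from the image; ``stop_tol``
    (if None) is derived as ``1 / snr**2``.
    """

    psf_fwhm_nm: float
    pixel_size_nm: float
    max_iterations: int = 40
    snr: Optional[float] = None
    stop_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.psf_fwhm_nm < 0:
            raise ValueError("psf_fwhm_nm must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


def estimate_snr(image: np.ndarray) -> float:
    """SNR = 3 * sqrt(max / min+) from the image histogram.

    ``min+`` is the smallest strictly positive pixel value: the literal
    histogram minimum of a background-subtracted image is routinely 0, which
    would make the ratio undefined.
    """
    img = np.asarray(image, dtype=float)
    positive = img[img > 0]
    if positive.size == 0:
        raise ValueError("cannot estimate SNR of an image with no positive pixels")
    return float(3.0 * np.sqrt(img.max() / positive.min()))


def richardson_lucy(image: np.ndarray, config: DeconvConfig) -> np.ndarray:
    """Restore a single plane by Richardson-Lucy iteration.

    The estimate stays nonnegative by construction and, with the mirrored
    boundary used here, conserves total flux to well under 1%.  A zero-width
    (delta) PSF returns the input unchanged at any iteration count.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("richardson_lucy expects a single 2D plane")
    if np.any(img < 0):
        raise ValueError("image must be nonnegative")

    sigma_px = fwhm_to_sigma(config.psf_fwhm_nm) / config.pixel_size_nm
    if sigma_px == 0:
        return img.copy()
    if not np.isfinite(sigma_px):
        raise ValueError("PSF is not normalizable")

    snr = config.snr if config.snr is not None else estimate_snr(img)
    stop_tol = config.stop_tol if config.stop_tol is not None else 1.0 / snr**2

    def blur(x: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(x, sigma_px, mode="mirror")

    eps = np.finfo(float).tiny
    est = np.clip(img, eps, None)
    for _ in range(config.max_iterations):
        denom = blur(est)
        ratio = img / np.clip(denom, eps, None)
        new = est * blur(ratio)  # Gaussian PSF is symmetric: adjoint = forward
        change = np.abs(new - est).sum() / max(est.sum(), eps)
        est = new
        if change < stop_tol:
            break
    return est
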