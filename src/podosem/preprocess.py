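"""Gaussian pre-smoothing and ROI histogram utilities.

The smoothing step mirrors ImageJ's "Accurate Gaussian Blur": the plugin's
``radius`` parameter is the Gaussian σ in pixels, applied as a separable
convolution with a generous kernel support. Boundaries are handled by
reflection so that intensities near the ROI border are not darkened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CalibratedImage

__all__ = ["BlurParams", "gaussian_blur", "roi_histogram"]


@dataclass(frozen=True)
class BlurParams:
    """Gaussian smoothing parameters.

    ``radius`` is the Gaussian σ in pixels; ``truncation`` sets the kernel
    support in multiples of σ (≥ 3 keeps the truncation error below ~3e-3,
    the default 4 below ~1e-4).
    """

    radius: float = 2.0
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"blur radius must be positive, got {self.radius}")
        if self.truncation < 3:
            raise ValueError("kernel truncation must be at least 3 σ")


def gaussian_blur(image: CalibratedImage, params: BlurParams) -> CalibratedImage:
    """Separable Gaussian convolution with σ = ``params.radius`` (reflect boundary)."""
    data = np.asarray(image.pixels, dtype=np.float64)
    out = ndimage.gaussian_filter(data, sigma=params.radius, mode="reflect",
                                  truncate=params.truncation)
    return image.with_pixels(out)


def roi_histogram(image: CalibratedImage, mask: np.ndarray, n_bins: int = 256,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of intensities under ``mask``.

    Returns ``(edges, counts)`` with ``len(edges) == n_bins + 1``. For 8-bit
    sources the 256 default bins are unit-width bins centered on the integer
    levels (edges -0.5 .. 255.5); for other sources the bins span the data
    range found under the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    if not mask.any():
        raise ValueError("empty ROI mask")
    values = np.asarray(image.pixels, dtype=np.float64)[mask]
    if image.bit_depth in (8, 16) and n_bins == 2**image.bit_depth:
        top = float(2**image.bit_depth - 1)
        edges = np.arange(n_bins + 1, dtype=float) - 0.5
        if image.bit_depth == 16:
            edges = np.linspace(-0.5, top + 0.5, n_bins + 1)
    else:
        lo, hi = float(values.min()), float(values.max())
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts
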