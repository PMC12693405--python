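"""Threshold-based slit-diaphragm fraction (automatic Yen threshold).

The pipeline: Gaussian blur (σ = 2 px by default) → intensity histogram of
the ROI pixels → Yen's maximum-correlation threshold → classify the dark
side of the threshold as slit diaphragm → report the SD area as a
percentage of the ROI.

Slit diaphragms are recessed grooves between foot processes and image dark
in secondary-electron SEM, so the default polarity selects intensities at
or below the threshold; a ``polarity`` flag flips this for inverted data.
"""

from __future__ import annotations

import numpy as np

from .io import CalibratedImage, PolygonRoi, rasterize_roi
from .measures import SdMeasurement
from .preprocess import BlurParams, gaussian_blur, roi_histogram

__all__ = ["yen_criterion", "yen_threshold", "sd_fraction_by_threshold"]


def yen_criterion(counts: np.ndarray) -> np.ndarray:
    """Yen's maximum-correlation criterion evaluated at every cut point.

    For a threshold after bin ``t`` (foreground = bins ``0..t``), the
    criterion is

        TC(t) = -ln[ G1(t) * G2(t) / (P(t)^2 * (1 - P(t))^2) ]

    where ``P`` is the cumulative probability and ``G1``/``G2`` are the
    cumulative sums of squared bin probabilities below/above the cut.
    Cut points that leave either side empty are assigned -inf.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    p = counts / total
    P = np.cumsum(p)
    G1 = np.cumsum(p * p)
    G2 = G1[-1] - G1
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(G1 * G2) + 2.0 * np.log(P * (1.0 - P))
    crit[~np.isfinite(crit)] = -np.inf
    return crit


def yen_threshold(counts: np.ndarray, edges: np.ndarray | None = None) -> float:
    """Automatic threshold maximizing Yen's criterion.

    The optimal cut index ``t`` (foreground = bins ``0..t``) is the argmax
    of the criterion, ties breaking toward the lowest index. The returned
    level is the boundary *between* bins ``t`` and ``t+1`` — ``t + 0.5``
    in bin units, or the shared bin edge when ``edges`` is given — so that
    "intensity ≤ level" selects exactly the foreground bins. A histogram
    with fewer than two populated bins is degenerate.
    """
    counts = np.asarray(counts)
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: fewer than two populated bins")
    crit = yen_criterion(counts)
    t = int(np.argmax(crit))  # argmax takes the first maximum -> lowest index
    if edges is None:
        return t + 0.5
    edges = np.asarray(edges, dtype=float)
    return float(edges[t + 1])


def sd_fraction_by_threshold(image: CalibratedImage, roi: PolygonRoi,
                             blur: BlurParams | None = None,
                             n_bins: int = 256,
                             polarity: str = "dark",
                             provenance: dict | None = None) -> SdMeasurement:
    """Slit-diaphragm fraction of a ROI by automatic Yen thresholding.

    ``polarity="dark"`` classifies pixels at or below the threshold as SD
    (grooves); ``"bright"`` selects the other side.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    blur = blur or BlurParams(radius=2.0)
    smoothed = gaussian_blur(image, blur)
    mask = rasterize_roi(roi, image.shape)
    edges, counts = roi_histogram(smoothed, mask, n_bins=n_bins)
    level = yen_threshold(counts, edges)
    values = np.asarray(smoothed.pixels, dtype=float)
    sd = (values <= level) if polarity == "dark" else (values > level)
    sd &= mask
    roi_area = int(mask.sum())
    sd_area = int(sd.sum())
    params = {"method": "threshold", "blur_radius": blur.radius,
              "n_bins": n_bins, "polarity": polarity}
    return SdMeasurement(sd_fraction=100.0 * sd_area / roi_area,
                         roi_area=roi_area, sd_area=sd_area,
                         method="threshold", threshold_level=level,
                         parameters=params, provenance=provenance or {})
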