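"""Measurement result records shared by the three quantification methods."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SdMeasurement", "ProfileMeasurement", "parameters_hash"]


def parameters_hash(params: dict) -> str:
    """Stable short hash of a parameter mapping, for provenance columns."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SdMeasurement:
    """One slit-diaphragm fraction measurement over a polygon ROI.

    ``sd_fraction`` is the percentage of ROI pixels classified as slit
    diaphragm; it always equals ``100 * sd_area / roi_area``.
    """

    sd_fraction: float
    roi_area: int
    sd_area: int
    method: str  # "threshold" | "ridge"
    threshold_level: float | None = None
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roi_area <= 0:
            raise ValueError("roi_area must be positive")
        expected = 100.0 * self.sd_area / self.roi_area
        if not np.isclose(self.sd_fraction, expected, atol=1e-9):
            raise ValueError("sd_fraction inconsistent with sd_area / roi_area")
        if not 0.0 <= self.sd_fraction <= 100.0:
            raise ValueError("sd_fraction must lie in [0, 100]")

    def as_row(self) -> dict:
        row = {**self.provenance,
               "method": self.method,
               "value": self.sd_fraction,
               "units": "percent",
               "roi_area_px": self.roi_area,
               "sd_area_px": self.sd_area,
               "parameters_hash": parameters_hash(self.parameters)}
        if self.threshold_level is not None:
            row["threshold_level"] = self.threshold_level
        return row


@dataclass
class ProfileMeasurement:
    """Foot-process width from one intensity profile.

    ``fpw`` is the mean spacing (µm) between adjacent detected peaks along
    the profile; undefined (None) when fewer than two peaks are found.
    """

    arc_length_um: np.ndarray
    intensity: np.ndarray
    peak_positions_um: np.ndarray
    fpw: float | None
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_positions_um = np.asarray(self.peak_positions_um, dtype=float)
        if np.any(np.diff(self.peak_positions_um) <= 0):
            raise ValueError("peak positions must be strictly increasing")
        if self.fpw is not None and self.fpw <= 0:
            raise ValueError("fpw must be positive when defined")
        if self.fpw is not None and self.n_peaks < 2:
            raise ValueError("fpw requires at least two peaks")

    @property
    def n_peaks(self) -> int:
        return int(len(self.peak_positions_um))

    def as_row(self) -> dict:
        return {**self.provenance,
                "method": "profile",
                "value": self.fpw if self.fpw is not None else np.nan,
                "units": "um",
                "n_peaks": self.n_peaks,
                "parameters_hash": parameters_hash(self.parameters)}
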