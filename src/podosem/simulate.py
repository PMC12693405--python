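"""Synthetic SEM-like foot-process / slit-diaphragm image generator.

Real secondary-electron micrographs of the podocyte surface show bright,
quasi-parallel foot-process ridges separated by narrow dark slit grooves.
The generator emulates that geometry with a periodic groove pattern:

* a stripe coordinate (optionally rotated and sinusoidally warped) defines
  the distance to the nearest slit centerline;
* the groove cross-profile is a smoothed trapezoid (plateau with erf
  shoulders) so edge and ridge operators see realistic gradients rather
  than ideal steps;
* the exact groove mask is captured *before* noise, giving pixel-exact
  ground truth for the slit-diaphragm fraction and foot-process width;
* additive Gaussian noise, an optional illumination ramp, and 8-bit
  quantization are applied last.

Whole cohorts with mouse-level and image-level variation are produced by
hierarchical Gaussian sampling of the true slit fraction, mirroring a
two-group diabetic-vs-control study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf
from scipy.stats import truncnorm

from .io import (CalibratedImage, PolygonRoi, Polyline, StudyRecord,
                 rasterize_roi, save_image, write_imagej_roi)

__all__ = [
    "PatternSpec", "GroundTruth", "GroupSpec", "CohortSpec", "SimImage",
    "make_pattern", "simulate_cohort", "write_cohort",
]


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of one synthetic foot-process pattern.

    Defaults approximate a murine podocyte surface at high magnification:
    ~0.55 µm foot-process spacing with ~30% of the surface in slit grooves,
    imaged at 0.01 µm/pixel.
    """

    size: tuple[int, int] = (256, 256)       # (height, width) px
    scale: float = 0.01                       # µm per pixel
    fp_period: float = 0.55                   # µm, FP center-to-center spacing
    slit_width: float = 0.165                 # µm, groove full width
    slit_depth: float = 0.6                   # intensity contrast, 0-1
    curvature: float = 0.0                    # warp amplitude, fraction of period
    warp_wavelength: float = 2.0              # µm, along-ridge warp period
    orientation: float = 0.0                  # degrees, stripe normal vs x-axis
    phase: float = 0.0                        # µm, slit-center offset
    shoulder: float = 0.02                    # µm, groove edge softness
    crest_amp: float = 0.10                   # FP crest brightening, 0-1
    noise_sd: float = 0.05                    # fraction of dynamic range
    illumination_gradient: float = 0.0        # fraction across the field
    background: float = 0.85                  # FP plateau intensity, 0-1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.slit_width < self.fp_period:
            raise ValueError("need 0 < slit_width < fp_period")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0 < self.slit_depth <= 1:
            raise ValueError("slit_depth must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Exact pattern truth captured before noise was applied."""

    slit_mask: np.ndarray        # bool, True on groove pixels
    true_sd_fraction: float      # percent, over the reference region
    true_fpw: float              # µm, = fp_period


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the simulated study."""

    name: str
    n_mice: int
    mean_fraction: float         # percent, group mean of per-mouse truth
    between_sd: float            # percent, mouse-to-mouse SD
    within_sd: float             # percent, image-to-image SD within a mouse

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ValueError("each group needs at least 2 mice")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """A two-(or more-)group simulated study.

    Defaults mirror a diabetic-nephropathy SEM study design: 17 control
    mice around 32% slit fraction versus 15 diabetic mice around 29.8%,
    3-5 glomerular images per mouse.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("non-DN", 17, 32.00, 2.08, 1.0),
        GroupSpec("STZ-DN", 15, 29.82, 1.98, 1.0),
    )
    images_per_mouse: tuple[int, int] = (3, 5)
    base: PatternSpec = field(default_factory=PatternSpec)
    fraction_bounds: tuple[float, float] = (5.0, 60.0)
    seed: int = 0


@dataclass
class SimImage:
    """One simulated micrograph with its annotations and truth.

    ``target_sd_fraction`` is the hierarchically sampled fraction the
    pattern was built from (the continuous target); ``truth`` carries the
    pixel-exact realized fraction of the rendered groove mask.
    """

    image: CalibratedImage
    roi: PolygonRoi
    profile_lines: list[Polyline]
    truth: GroundTruth
    record: StudyRecord
    target_sd_fraction: float = float("nan")


# ---------------------------------------------------------------------------


def make_pattern(spec: PatternSpec, roi_mask: np.ndarray | None = None,
                 ) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic pattern and its exact ground truth.

    ``true_sd_fraction`` is the groove-pixel percentage over ``roi_mask``
    (whole image when None); for an unwarped, axis-aligned pattern whose
    reference region spans an integer number of periods it equals
    ``100 * slit_width / fp_period`` exactly.
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(spec.orientation)
    u = (np.cos(theta) * xx + np.sin(theta) * yy) * spec.scale
    v = (-np.sin(theta) * xx + np.cos(theta) * yy) * spec.scale
    if spec.curvature:
        u = u + spec.curvature * spec.fp_period * np.sin(
            2.0 * np.pi * v / spec.warp_wavelength)
    period = spec.fp_period
    d = np.abs((u - spec.phase + period / 2.0) % period - period / 2.0)

    half = spec.slit_width / 2.0
    slit_mask = d <= half
    s = max(spec.shoulder, 1e-6)
    groove = 0.5 * (erf((half - d) / (s * np.sqrt(2)))
                    + erf((half + d) / (s * np.sqrt(2))))
    intensity = spec.background - spec.slit_depth * groove
    if spec.crest_amp:
        # convex foot-process tops image brighter at their crest (midway
        # between slits), giving profiles a well-defined maximum per FP
        crest = 0.5 * (1.0 - np.cos(2.0 * np.pi * (u - spec.phase) / period))
        intensity = intensity + spec.crest_amp * crest * (1.0 - groove)
    if spec.illumination_gradient:
        intensity = intensity + spec.illumination_gradient * (xx / max(w - 1, 1) - 0.5)
    if spec.noise_sd:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=(h, w))
    pixels = np.clip(np.round(intensity * 255.0), 0, 255).astype(np.uint8)

    ref = np.ones((h, w), dtype=bool) if roi_mask is None else np.asarray(roi_mask, bool)
    frac = 100.0 * (slit_mask & ref).sum() / ref.sum()
    image = CalibratedImage(pixels=pixels, scale=spec.scale, bit_depth=8,
                            source_id=f"sim_seed{spec.seed}")
    return image, GroundTruth(slit_mask=slit_mask, true_sd_fraction=float(frac),
                              true_fpw=spec.fp_period)


def _inset_roi(shape: tuple[int, int], margin: int = 8, label: str = "roi") -> PolygonRoi:
    h, w = shape
    m = margin
    return PolygonRoi(vertices=[(m, m), (w - 1 - m, m),
                                (w - 1 - m, h - 1 - m), (m, h - 1 - m)],
                      label=label)


def _profile_lines(spec: PatternSpec, n_lines: int = 3) -> list[Polyline]:
    """Polylines crossing the stripes perpendicular to the foot processes."""
    h, w = spec.size
    theta = np.deg2rad(spec.orientation)
    direction = np.array([np.cos(theta), np.sin(theta)])
    offset_dir = np.array([-np.sin(theta), np.cos(theta)])
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    half_len = 0.42 * min(h, w)
    spread = 0.15 * min(h, w)
    lines = []
    offsets = np.linspace(-spread, spread, n_lines) if n_lines > 1 else [0.0]
    for i, off in enumerate(offsets):
        c = center + off * offset_dir
        p0 = c - half_len * direction
        p1 = c + half_len * direction
        lines.append(Polyline(vertices=[tuple(p0), tuple(p1)], label=f"profile_{i}"))
    return lines


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int | None = None):
    if sd == 0:
        val = np.full(size, float(np.clip(mean, lo, hi))) if size else float(np.clip(mean, lo, hi))
        return val
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(spec: CohortSpec) -> list[SimImage]:
    """Simulate a full two-group study with hierarchical truth sampling.

    Per mouse: true fraction ~ Normal(group mean, between-mouse SD); per
    image: ~ Normal(mouse value, within-mouse SD); both truncated to
    ``fraction_bounds``. Slit widths are back-solved from the sampled
    fractions; orientation and groove phase vary randomly per image.
    Mouse-level covariates (fasting glucose in mg/dL, urinary ACR in µg/mg)
    are drawn negatively correlated with the mouse's true slit fraction.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.fraction_bounds
    out: list[SimImage] = []
    for g_idx, group in enumerate(spec.groups):
        mouse_fracs = np.atleast_1d(_truncated_normal(
            rng, group.mean_fraction, group.between_sd, lo, hi, group.n_mice))
        for m_idx, mouse_frac in enumerate(mouse_fracs):
            mouse_id = f"{group.name}_m{m_idx:02d}"
            glucose_base = 450.0 if "DN" in group.name and "non" not in group.name else 150.0
            acr_base = 300.0 if glucose_base > 200 else 30.0
            covs = {
                "fasting_glucose": float(glucose_base
                                         - 20.0 * (mouse_frac - group.mean_fraction)
                                         + rng.normal(0.0, 30.0)),
                "acr": float(acr_base * np.exp(-0.10 * (mouse_frac - group.mean_fraction)
                                               + rng.normal(0.0, 0.25))),
            }
            n_img = int(rng.integers(spec.images_per_mouse[0],
                                     spec.images_per_mouse[1] + 1))
            for i_idx in range(n_img):
                frac = float(_truncated_normal(rng, float(mouse_frac),
                                               group.within_sd, lo, hi))
                pat = replace(
                    spec.base,
                    slit_width=frac / 100.0 * spec.base.fp_period,
                    orientation=float(rng.uniform(0.0, 45.0)),
                    phase=float(rng.uniform(0.0, spec.base.fp_period)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                roi = _inset_roi(pat.size, label=f"{mouse_id}_g{i_idx}")
                roi_mask = rasterize_roi(roi, pat.size)
                image, truth = make_pattern(pat, roi_mask=roi_mask)
                image.source_id = f"{mouse_id}_img{i_idx:02d}"
                record = StudyRecord(image_id=image.source_id,
                                     glomerulus_id=f"{mouse_id}_glom{i_idx:02d}",
                                     mouse_id=mouse_id, group=group.name,
                                     covariates=covs)
                out.append(SimImage(image=image, roi=roi,
                                    profile_lines=_profile_lines(pat),
                                    truth=truth, record=record,
                                    target_sd_fraction=frac))
    return out


def study_table(dataset: list[SimImage]) -> pd.DataFrame:
    rows = []
    for sim in dataset:
        r = sim.record
        rows.append({"image_id": r.image_id, "glomerulus_id": r.glomerulus_id,
                     "mouse_id": r.mouse_id, "group": r.group,
                     "true_sd_fraction": sim.truth.true_sd_fraction,
                     "target_sd_fraction": sim.target_sd_fraction,
                     "true_fpw": sim.truth.true_fpw, **r.covariates})
    return pd.DataFrame(rows)


def write_cohort(dataset: list[SimImage], outdir: str | Path) -> Path:
    """Write a simulated cohort to disk: TIFFs, ROI files, profile lines,
    ``study_table.csv`` and ``ground_truth.csv``."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "rois").mkdir(exist_ok=True)
    for sim in dataset:
        stem = sim.record.image_id
        save_image(sim.image, outdir / "images" / f"{stem}.tif")
        write_imagej_roi(sim.roi, outdir / "rois" / f"{stem}.roi")
        lines_txt = "\n".join(
            "line:" + " ".join(f"{x:.3f},{y:.3f}" for x, y in pl.vertices)
            for pl in sim.profile_lines)
        (outdir / "rois" / f"{stem}_lines.txt").write_text(lines_txt + "\n")
    table = study_table(dataset)
    table.drop(columns=["true_sd_fraction", "target_sd_fraction", "true_fpw"]
               ).to_csv(outdir / "study_table.csv", index=False)
    table[["image_id", "true_sd_fraction", "target_sd_fraction", "true_fpw"]
          ].to_csv(outdir / "ground_truth.csv", index=False)
    return outdir
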