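"""Study-level orchestration: measure → aggregate → statistics.

A run is driven by a manifest table (one row per image: paths, mouse and
group bookkeeping) plus a parameter config. All outputs are plain CSV/JSON
with a run manifest recording every parameter, so a rerun with identical
inputs reproduces the numbers bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagstats import (aggregate_per_mouse, bland_altman, empirical_roc,
                        group_summary, hedges_g, pearson_corr, two_sample_test,
                        wilson_ci, youden_optimal)
from .io import (CalibratedImage, PolygonRoi, Polyline, load_image,
                 read_rois, write_measurements)
from .measures import parameters_hash
from .preprocess import BlurParams
from .profile import fpw_from_profiles, measure_profile
from .ridge import RidgeParams, sd_fraction_by_ridge
from .threshold import sd_fraction_by_threshold

__all__ = ["RunConfig", "REFERENCE_DEFAULTS", "measure_image", "run_study",
           "compare_methods", "stats_report"]

# Baseline parameter profile: the reference protocol's published ImageJ
# settings for each method.
REFERENCE_DEFAULTS: dict = {
    "threshold": {"blur_radius": 2.00, "polarity": "dark", "n_bins": 256},
    "ridge": {"blur_radius": 4.00, "sigma": 5.70, "line_width": 15.0,
              "lower_threshold": 0.00, "upper_threshold": 0.17,
              "min_line_length": 5.00, "max_line_length": 0.00,
              "mode": "line-envelope", "polarity": "dark"},
    "profile": {"step_px": 1.0, "min_prominence": 0.2,
                "min_separation_um": 0.1, "polarity": "peaks"},
}


@dataclass
class RunConfig:
    """Configuration of one study run.

    ``manifest`` rows need: image_path, roi_path (polygon ROI for SD
    methods and/or a lines file for the profile method), image_id,
    glomerulus_id, mouse_id, group; optional covariate columns.
    """

    manifest: pd.DataFrame
    scale: float
    method: str = "ridge"
    params: dict = field(default_factory=dict)
    out_dir: str | Path = "podosem_out"
    positive_group: str | None = None  # defaults to the second group label

    def method_params(self) -> dict:
        merged = dict(REFERENCE_DEFAULTS[self.method])
        merged.update(self.params)
        return merged


def _provenance(row: pd.Series) -> dict:
    return {k: row[k] for k in ("mouse_id", "glomerulus_id", "image_id")
            if k in row}


def measure_image(image: CalibratedImage, roi, method: str, params: dict,
                  provenance: dict | None = None) -> dict:
    """Run one method on one (image, annotation) pair; returns a result row."""
    provenance = provenance or {}
    if method == "threshold":
        m = sd_fraction_by_threshold(
            image, roi, blur=BlurParams(radius=params["blur_radius"]),
            n_bins=params.get("n_bins", 256),
            polarity=params.get("polarity", "dark"), provenance=provenance)
        return m.as_row()
    if method == "ridge":
        rp = RidgeParams(sigma=params["sigma"], line_width=params["line_width"],
                         lower_threshold=params["lower_threshold"],
                         upper_threshold=params["upper_threshold"],
                         min_line_length=params["min_line_length"],
                         max_line_length=params["max_line_length"])
        m = sd_fraction_by_ridge(
            image, roi, blur=BlurParams(radius=params["blur_radius"]),
            params=rp, mode=params.get("mode", "line-envelope"),
            polarity=params.get("polarity", "dark"), provenance=provenance)
        return m.as_row()
    if method == "profile":
        lines = roi if isinstance(roi, list) else [roi]
        lines = [l for l in lines if isinstance(l, Polyline)]
        if not lines:
            raise ValueError("profile method needs polyline annotations")
        profs = [measure_profile(image, l, step=params.get("step_px", 1.0),
                                 min_prominence=params.get("min_prominence", 0.2),
                                 min_separation_um=params.get("min_separation_um", 0.1),
                                 polarity=params.get("polarity", "peaks"),
                                 provenance=provenance)
                 for l in lines]
        fpw = fpw_from_profiles(profs)
        return {**provenance, "method": "profile", "value": fpw, "units": "um",
                "n_profiles": len(profs),
                "parameters_hash": parameters_hash(params)}
    raise ValueError(f"unknown method: {method!r}")


def _load_annotation(path: str, method: str):
    rois = read_rois(path)
    if method == "profile":
        lines = [r for r in rois if isinstance(r, Polyline)]
        if not lines:
            raise ValueError(f"{path}: no polyline annotations for the profile method")
        return lines
    polys = [r for r in rois if isinstance(r, PolygonRoi)]
    if not polys:
        raise ValueError(f"{path}: no polygon ROI found")
    return polys[0]


def run_study(config: RunConfig) -> dict:
    """Measure every manifest image, aggregate per mouse, compute statistics.

    Writes per_image.csv, per_mouse.csv, stats.json and run_manifest.json
    under ``config.out_dir`` and returns the stats report dict. Any stage
    failure is re-raised with image provenance attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.method_params()
    rows = []
    for _, row in config.manifest.iterrows():
        try:
            image = load_image(row["image_path"], scale=config.scale)
            ann = _load_annotation(row["roi_path"], config.method)
            rows.append(measure_image(image, ann, config.method, params,
                                      provenance=_provenance(row)))
        except Exception as exc:
            raise RuntimeError(
                f"measurement failed for image_id={row.get('image_id')!r} "
                f"(mouse={row.get('mouse_id')!r}): {exc}") from exc
    per_image = pd.DataFrame(rows)
    write_measurements(per_image, out / "per_image.csv")

    study_cols = [c for c in config.manifest.columns
                  if c not in ("image_path", "roi_path")]
    study = config.manifest[study_cols]
    per_mouse = aggregate_per_mouse(per_image, study)
    write_measurements(per_mouse, out / "per_mouse.csv")

    report = stats_report(per_mouse, study, config.positive_group,
                          direction="lower" if config.method != "profile" else "higher")
    (out / "stats.json").write_text(json.dumps(report, indent=2, default=float))
    manifest = {"version": __version__, "method": config.method,
                "scale_um_per_px": config.scale, "parameters": params,
                "parameters_hash": parameters_hash(params),
                "n_images": len(per_image), "n_mice": len(per_mouse)}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def stats_report(per_mouse: pd.DataFrame, study: pd.DataFrame | None = None,
                 positive_group: str | None = None,
                 direction: str = "lower") -> dict:
    """Group summaries, t-test, Hedges' g, ROC/Youden with Wilson CIs, and
    covariate correlations for a per-mouse table with ``group`` labels."""
    if "group" not in per_mouse.columns:
        raise ValueError("per-mouse table lacks group labels")
    groups = list(dict.fromkeys(per_mouse["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g0, g1 = groups
    if positive_group is None:
        positive_group = g1
    v0 = per_mouse.loc[per_mouse["group"] == g0, "value"].to_numpy()
    v1 = per_mouse.loc[per_mouse["group"] == g1, "value"].to_numpy()
    report: dict = {"groups": {}}
    for name, vals in ((g0, v0), (g1, v1)):
        if len(vals) >= 2:
            s = group_summary(vals, name)
            report["groups"][name] = {"n": s.n, "mean": s.mean, "sd": s.sd,
                                      "ci95": list(s.ci95)}
        else:
            report["groups"][name] = {"n": int(len(vals)),
                                      "mean": float(np.mean(vals)),
                                      "sd": None, "ci95": None}
    if len(v0) >= 2 and len(v1) >= 2:
        t, df, p = two_sample_test(v0, v1)
        report["t_test"] = {"t": t, "df": df, "p": p}
        if v0.std(ddof=1) > 0 or v1.std(ddof=1) > 0:
            es = hedges_g(len(v0), v0.mean(), v0.std(ddof=1),
                          len(v1), v1.mean(), v1.std(ddof=1))
            report["hedges_g"] = {"g": es.g, "ci95": list(es.ci95),
                                  "pooled_sd": es.pooled_sd,
                                  "correction": es.correction}
        labels = (per_mouse["group"] == positive_group).astype(int).to_numpy()
        scores = per_mouse["value"].to_numpy()
        roc = empirical_roc(scores, labels, direction=direction)
        thr, j, sens, spec = youden_optimal(roc, scores=scores)
        n_pos = int(labels.sum())
        n_neg = int(len(labels) - n_pos)
        sens_ci = wilson_ci(int(round(sens * n_pos)), n_pos)
        spec_ci = wilson_ci(int(round(spec * n_neg)), n_neg)
        report["roc"] = {"auc": roc.auc, "youden_j": j,
                         "optimal_threshold": thr,
                         "sensitivity": sens, "sensitivity_ci95": list(sens_ci),
                         "specificity": spec, "specificity_ci95": list(spec_ci),
                         "positive_group": positive_group,
                         "direction": direction}
    else:
        report["warning"] = "fewer than 2 mice in a group; tests skipped"
    if study is not None:
        numeric = [c for c in study.columns
                   if c not in ("image_id", "glomerulus_id", "mouse_id", "group")
                   and pd.api.types.is_numeric_dtype(study[c])]
        if numeric:
            mouse_cov = study.groupby("mouse_id", as_index=False)[numeric].mean()
            merged = per_mouse.merge(mouse_cov, on="mouse_id")
            report["correlations"] = {}
            for cov in numeric:
                sub = merged.dropna(subset=[cov, "value"])
                if len(sub) >= 3 and sub[cov].std() > 0:
                    c = pearson_corr(sub["value"], sub[cov])
                    report["correlations"][cov] = {"r": c.r, "p": c.p, "n": c.n}
    return report


def compare_methods(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run all three methods on the same manifest and report their ROCs.

    Returns a per-mouse table with one column per method plus a dict of the
    three stats reports. The manifest needs a ``lines_path`` column for the
    profile method.
    """
    per_mouse_tables = {}
    reports = {}
    for method in ("threshold", "ridge", "profile"):
        cfg = RunConfig(manifest=config.manifest, scale=config.scale,
                        method=method, params={},
                        out_dir=Path(config.out_dir) / method,
                        positive_group=config.positive_group)
        if method == "profile":
            if "lines_path" not in config.manifest.columns:
                continue
            cfg.manifest = config.manifest.assign(
                roi_path=config.manifest["lines_path"])
        reports[method] = run_study(cfg)
        per_mouse_tables[method] = pd.read_csv(Path(cfg.out_dir) / "per_mouse.csv")
    base = None
    for method, table in per_mouse_tables.items():
        table = table.rename(columns={"value": method})
        base = table if base is None else base.merge(table, on=["mouse_id", "group"])
    side_by_side = base
    write_measurements(side_by_side, Path(config.out_dir) / "methods_per_mouse.csv")
    return side_by_side, reports
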