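"""Batch orchestration: per-lesion feature extraction and cohort runs.

``extract_features`` evaluates the eleven features on one LesionROI in a
fixed order and never crashes on a single bad feature: a failed feature is
recorded as a missing value with a flag, so one pathological lesion cannot
sink a batch.  ``run_batch`` maps a manifest CSV over that extractor and
writes a numeric-parseable feature table (empty cell + flags column for
failures) plus an error report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcification, cohort_stats, contour_geometry, glgcm_texture
from . import margin_features as mf
from . import roi_io
from .config import RunConfig
from .exceptions import EchofeatError, ValidationError

log = logging.getLogger("echofeat")


@dataclass
class FeatureVector:
    """The eleven named features for one lesion, plus quality flags."""

    lesion_id: str = ""
    circularity: float = np.nan
    hwr: float = np.nan
    spicules: float = np.nan
    coarseness_px: float = np.nan
    indistinctness_e6: float = np.nan
    lobulation: float = np.nan
    energy: float = np.nan
    entropy: float = np.nan
    grey_mean: float = np.nan
    calcifications: float = np.nan
    als_deg: float = np.nan
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {"lesion_id": self.lesion_id}
        row.update({c: getattr(self, c) for c in cohort_stats.FEATURE_COLUMNS})
        row["flags"] = ";".join(self.flags)
        return row


def extract_features(roi: roi_io.LesionROI,
                     config: RunConfig | None = None,
                     lesion_id: str = "") -> FeatureVector:
    """Compute all eleven features for one lesion ROI.

    Deterministic for fixed input and config.  A feature whose computation
    raises records a flag ``<name>:<reason>`` and leaves NaN in the table.
    """
    cfg = config or RunConfig()
    fv = FeatureVector(lesion_id=lesion_id)
    t0 = time.perf_counter()

    seq = None
    try:
        seq = roi_io.to_radial_sequence(roi.boundary, roi.centroid)
    except EchofeatError as exc:
        fv.flags.append(f"radial:{exc}")

    def attempt(name: str, fn) -> None:
        try:
            setattr(fv, name, fn())
        except EchofeatError as exc:
            fv.flags.append(f"{name}:{exc}")

    attempt("circularity", lambda: contour_geometry.circularity(roi))
    attempt("hwr", lambda: contour_geometry.height_width_ratio(roi))
    if seq is not None:
        spic_seq = (mf.resample_radial(seq, cfg.spicules.n_resample)
                    if cfg.spicules.n_resample > 0 else seq)
        attempt("spicules", lambda: mf.margin_spicules(spic_seq))
        attempt("coarseness_px", lambda: mf.margin_coarseness(seq))
        attempt("lobulation", lambda: float(mf.margin_lobulation(
            seq, median_frame=cfg.lobulation.median_frame,
            degree=cfg.lobulation.poly_degree)))
    attempt("indistinctness_e6", lambda: mf.margin_indistinctness(
        roi, band_width=cfg.margin.band_width) / 1e6)

    try:
        g = glgcm_texture.build_glgcm(
            roi, L_s=cfg.texture.L_s, L_g=cfg.texture.L_g,
            quantization=cfg.texture.quantization)
        fv.energy = glgcm_texture.glgcm_energy(g)
        fv.entropy = glgcm_texture.glgcm_entropy(g)
        fv.grey_mean = glgcm_texture.glgcm_grey_mean(g, gm_scale=cfg.texture.gm_scale)
    except EchofeatError as exc:
        fv.flags.append(f"texture:{exc}")

    params = calcification.CalcificationParams(
        threshold_alpha=cfg.calc.alpha, struct_radius=cfg.calc.struct_radius,
        min_blob_px=cfg.calc.min_blob_px, connectivity=cfg.calc.connectivity,
        morph_order=cfg.calc.morph_order)
    attempt("calcifications", lambda: float(
        calcification.count_calcifications(roi, params)))

    try:
        fit = contour_geometry.fit_ellipse(roi.boundary)
        fv.als_deg = float(np.degrees(contour_geometry.fold_angle(fit.theta_raw)))
        if fit.low_confidence:
            fv.flags.append("als_low_confidence")
    except EchofeatError as exc:
        fv.flags.append(f"als_deg:{exc}")

    if fv.spicules == mf.SPICULES_OVERFLOW:
        fv.flags.append("spicules_overflow")
    log.info("extracted %s in %.1f ms (flags: %s)", lesion_id or "<roi>",
             1e3 * (time.perf_counter() - t0), fv.flags or "none")
    return fv


def extract_table(lesions, config: RunConfig | None = None) -> pd.DataFrame:
    """Feature table for in-memory lesions ``(id, group, image, contour, truth)``."""
    rows = []
    for lesion_id, group, img, contour, _ in lesions:
        roi = roi_io.build_roi(img, contour)
        row = extract_features(roi, config, lesion_id=lesion_id).as_row()
        row["group"] = group
        rows.append(row)
    return pd.DataFrame(rows)


def run_batch(manifest_path: str | Path,
              config: RunConfig | None = None,
              out_dir: str | Path | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for every lesion in a manifest CSV.

    Returns ``(features, errors)``; lesions whose files are missing or
    invalid produce an error record, not an abort.  With ``out_dir`` the
    two tables are written as ``features.csv`` and ``errors.csv``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"lesion_id", "image_path", "contour_path", "group"}
    if not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest needs columns {sorted(required)}, got {list(manifest.columns)}")

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else manifest_path.parent / q

    feature_rows, error_rows = [], []
    for _, rec in manifest.iterrows():
        lesion_id = str(rec["lesion_id"])
        try:
            img = roi_io.load_image(resolve(rec["image_path"]))
            contour = roi_io.load_contour(resolve(rec["contour_path"]))
            roi = roi_io.build_roi(img, contour)
        except (OSError, EchofeatError) as exc:
            log.warning("lesion %s failed: %s", lesion_id, exc)
            error_rows.append({"lesion_id": lesion_id, "error": str(exc)})
            continue
        row = extract_features(roi, config, lesion_id=lesion_id).as_row()
        row["group"] = rec["group"]
        feature_rows.append(row)

    features = pd.DataFrame(feature_rows)
    errors = pd.DataFrame(error_rows, columns=["lesion_id", "error"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        errors.to_csv(out / "errors.csv", index=False)
    return features, errors
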