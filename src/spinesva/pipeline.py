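"""End-to-end prediction pipeline and tabular file formats.

Annotation tables are UTF-8 CSV with a required header and 0-based pixel
coordinates in the original image frame::

    image_path,c7_x,c7_y,s1_x,s1_y,mm_per_pixel_x,mm_per_pixel_y,facing

Prediction runs process each image through resize/pad, a forward pass, one
function fit per heatmap channel, inversion of the coordinate transform
back to the original resolution, and signed SVA computation.  Failures
(unreadable image, degenerate heatmap) are recorded per image with a
reason, never silently dropped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .heatmaps import HeatmapSpec, LandmarkPoint
from .localize import DegenerateMapError, fit_localize
from .metrics import (
    DetectionCurve,
    ErrorSummary,
    bland_altman,
    compute_sva,
    detection_curve,
    icc_two_way_random_absolute,
    mae_sva,
)
from .preprocess import ImageRecord, PreprocessSpec, invert_coordinates, load_image, resize_pad

__all__ = [
    "AnnotationRow",
    "PredictionRow",
    "evaluate_run",
    "read_annotations",
    "run_predict",
    "write_annotations",
    "write_predictions",
]

ANNOTATION_COLUMNS = [
    "image_path",
    "c7_x",
    "c7_y",
    "s1_x",
    "s1_y",
    "mm_per_pixel_x",
    "mm_per_pixel_y",
    "facing",
]


@dataclass(frozen=True)
class AnnotationRow:
    image_path: str
    c7_x: float
    c7_y: float
    s1_x: float
    s1_y: float
    mm_per_pixel_x: float
    mm_per_pixel_y: float
    facing: str

    def c7(self) -> LandmarkPoint:
        return LandmarkPoint(self.c7_x, self.c7_y)

    def s1(self) -> LandmarkPoint:
        return LandmarkPoint(self.s1_x, self.s1_y)


@dataclass
class PredictionRow:
    image_path: str
    c7_x: float = math.nan
    c7_y: float = math.nan
    s1_x: float = math.nan
    s1_y: float = math.nan
    sva_mm: float = math.nan
    c7_method: str = ""
    s1_method: str = ""
    error: str = ""

    @property
    def failed(self) -> bool:
        return bool(self.error)


def read_annotations(path: str | Path) -> list[AnnotationRow]:
    """Read and validate an annotation CSV; errors name the row and field."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    rows: list[AnnotationRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        rownum = i + 2  # 1-based, after the header
        for f in ANNOTATION_COLUMNS[1:-1]:
            v = rec[f]
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise ValueError(f"{path} row {rownum}: field {f!r} is not numeric: {v!r}")
            if not math.isfinite(v):
                raise ValueError(f"{path} row {rownum}: field {f!r} is not finite: {v!r}")
            rec[f] = v
        for f in ("mm_per_pixel_x", "mm_per_pixel_y"):
            if rec[f] <= 0:
                raise ValueError(f"{path} row {rownum}: field {f!r} must be positive")
        if rec["facing"] not in ("left", "right"):
            raise ValueError(
                f"{path} row {rownum}: field 'facing' must be left/right, got {rec['facing']!r}"
            )
        rows.append(AnnotationRow(**{c: rec[c] for c in ANNOTATION_COLUMNS}))
    return rows


def write_annotations(rows: Sequence[AnnotationRow], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.image_path, r.c7_x, r.c7_y, r.s1_x, r.s1_y,
                 r.mm_per_pixel_x, r.mm_per_pixel_y, r.facing]
            )
    return path


def write_predictions(rows: Sequence[PredictionRow], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_path", "c7_x", "c7_y", "s1_x", "s1_y", "sva_mm",
             "c7_method", "s1_method", "error"]
        )
        for r in rows:
            writer.writerow(
                [r.image_path, r.c7_x, r.c7_y, r.s1_x, r.s1_y, r.sva_mm,
                 r.c7_method, r.s1_method, r.error]
            )
    return path


def _record_from_annotation(row: AnnotationRow, image_root: Path) -> ImageRecord:
    pixels = load_image(image_root / row.image_path)
    return ImageRecord(
        pixels=pixels,
        mm_per_pixel_x=row.mm_per_pixel_x,
        mm_per_pixel_y=row.mm_per_pixel_y,
        facing=row.facing,
        image_path=row.image_path,
    )


def run_predict(
    model: Callable[[np.ndarray], np.ndarray],
    records: Sequence[ImageRecord],
    heatmap_spec: HeatmapSpec = HeatmapSpec(),
    preprocess_spec: PreprocessSpec = PreprocessSpec(),
) -> list[PredictionRow]:
    """Predict landmark locations and SVA for each record.

    ``model`` maps an N x H x W x 1 canvas batch to N x H x W x K heatmaps
    (a built network or any callable with that contract, e.g. an oracle in
    tests).  Per image: resize/pad, forward pass, per-channel function fit,
    inverse coordinate transform, signed SVA.  Images are processed
    independently; a failure yields a row with a reason.
    """
    rows: list[PredictionRow] = []
    for i, record in enumerate(records):
        name = record.image_path or f"image_{i}"
        try:
            canvas, _, transform = resize_pad(record, preprocess_spec)
            pred = model(canvas[None, ..., None].astype(np.float32))
            heatmaps = np.asarray(pred)[0]
            points = []
            methods = []
            for k in range(heatmaps.shape[-1]):
                loc = fit_localize(
                    heatmaps[..., k], heatmap_spec.family, sigma_init=heatmap_spec.sigma
                )
                points.append(invert_coordinates(loc.point, transform))
                methods.append(loc.method)
            c7, s1 = points[0], points[1]
            sva = compute_sva(c7, s1, record)
            rows.append(
                PredictionRow(
                    image_path=name,
                    c7_x=c7.x, c7_y=c7.y, s1_x=s1.x, s1_y=s1.y,
                    sva_mm=sva.value,
                    c7_method=methods[0], s1_method=methods[1],
                )
            )
        except (DegenerateMapError, ValueError, OSError) as exc:
            rows.append(PredictionRow(image_path=name, error=f"{type(exc).__name__}: {exc}"))
    return rows


def predict_from_annotations(
    model: Callable[[np.ndarray], np.ndarray],
    annotations: Sequence[AnnotationRow],
    image_root: str | Path,
    heatmap_spec: HeatmapSpec = HeatmapSpec(),
    preprocess_spec: PreprocessSpec = PreprocessSpec(),
) -> list[PredictionRow]:
    """Load each annotated image (failures become failure rows) and predict."""
    image_root = Path(image_root)
    rows: list[PredictionRow] = []
    for ann in annotations:
        try:
            record = _record_from_annotation(ann, image_root)
        except (OSError, ValueError) as exc:
            rows.append(
                PredictionRow(image_path=ann.image_path, error=f"{type(exc).__name__}: {exc}")
            )
            continue
        rows.extend(run_predict(model, [record], heatmap_spec, preprocess_spec))
    return rows


@dataclass
class EvaluationReport:
    sva_summary: ErrorSummary
    detection_curves: dict[str, DetectionCurve]
    per_image: pd.DataFrame
    unmatched: list[str] = field(default_factory=list)
    icc: dict | None = None
    bland_altman: dict | None = None

    def write(self, out_dir: str | Path) -> Path:
        """Per-image errors as CSV, detection curves as CSV, summary as YAML."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(out_dir / "per_image_errors.csv", index=False)
        curves = []
        for label, curve in self.detection_curves.items():
            for t, r in zip(curve.thresholds, curve.rates):
                curves.append({"landmark": label, "threshold_mm": t, "rate": r})
        pd.DataFrame(curves).to_csv(out_dir / "detection_curves.csv", index=False)
        summary = {
            "n": self.sva_summary.n,
            "median_abs_error_mm": self.sva_summary.median_abs_error,
            "outlier_count": self.sva_summary.outlier_count,
            "outlier_fraction": self.sva_summary.outlier_fraction,
            "unmatched": self.unmatched,
        }
        if self.icc is not None:
            summary["icc"] = self.icc
        if self.bland_altman is not None:
            summary["bland_altman"] = self.bland_altman
        (out_dir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
        return out_dir


def evaluate_run(
    predictions: Sequence[PredictionRow],
    annotations: Sequence[AnnotationRow],
    thresholds_mm: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0),
) -> EvaluationReport:
    """Join predictions with annotations on image_path and compute all metrics.

    Unmatched or failed images are listed in the report and excluded from
    the statistics.  When both sets agree on n >= 3 images, the SVA ICC and
    Bland-Altman summaries (prediction vs. annotation) are included.
    """
    ann_by_path = {a.image_path: a for a in annotations}
    unmatched = []
    rows = []
    from .metrics import landmark_distances_mm  # local import to avoid cycle noise

    matched_records = []
    true_c7, pred_c7, true_s1, pred_s1 = [], [], [], []
    true_sva, pred_sva = [], []
    for p in predictions:
        a = ann_by_path.get(p.image_path)
        if a is None or p.failed:
            unmatched.append(p.image_path if a is None else f"{p.image_path} ({p.error})")
            continue
        record = ImageRecord(
            pixels=np.zeros((2, 2), dtype=np.float32),  # geometry-only carrier
            mm_per_pixel_x=a.mm_per_pixel_x,
            mm_per_pixel_y=a.mm_per_pixel_y,
            facing=a.facing,
        )
        t_sva = compute_sva(a.c7(), a.s1(), record).value
        true_sva.append(t_sva)
        pred_sva.append(p.sva_mm)
        matched_records.append(record)
        true_c7.append(a.c7())
        pred_c7.append(LandmarkPoint(p.c7_x, p.c7_y))
        true_s1.append(a.s1())
        pred_s1.append(LandmarkPoint(p.s1_x, p.s1_y))
        rows.append(
            {
                "image_path": p.image_path,
                "sva_true_mm": t_sva,
                "sva_pred_mm": p.sva_mm,
                "abs_error_mm": abs(t_sva - p.sva_mm),
            }
        )
    if not rows:
        raise ValueError("no prediction/annotation pairs could be matched")
    per_image = pd.DataFrame(rows)
    summary = mae_sva(true_sva, pred_sva)
    c7_dist = landmark_distances_mm(true_c7, pred_c7, matched_records)
    s1_dist = landmark_distances_mm(true_s1, pred_s1, matched_records)
    per_image["c7_error_mm"] = c7_dist
    per_image["s1_error_mm"] = s1_dist
    curves = {
        "c7": detection_curve(true_c7, pred_c7, matched_records, thresholds_mm, "c7"),
        "s1": detection_curve(true_s1, pred_s1, matched_records, thresholds_mm, "s1"),
    }
    icc = None
    ba = None
    if len(true_sva) >= 3:
        icc_res = icc_two_way_random_absolute(np.column_stack([true_sva, pred_sva]))
        icc = {
            "estimate": icc_res.estimate,
            "ci_low": icc_res.ci_low,
            "ci_high": icc_res.ci_high,
        }
        ba_res = bland_altman(pred_sva, true_sva)
        ba = {
            "mean_diff_mm": ba_res.mean_diff,
            "sd_diff_mm": ba_res.sd_diff,
            "loa_low_mm": ba_res.loa_low,
            "loa_high_mm": ba_res.loa_high,
            "median_abs_diff_mm": ba_res.median_abs_diff,
        }
    return EvaluationReport(
        sva_summary=summary,
        detection_curves=curves,
        per_image=per_image,
        unmatched=unmatched,
        icc=icc,
        bland_altman=ba,
    )
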