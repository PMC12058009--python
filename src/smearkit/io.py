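"""Reading and writing annotations, detections, and metric reports.

Two on-disk dialects are supported:

* ``yolo_txt`` — darknet-style: one ``.txt`` per image whose lines are
  ``class_index cx cy w h`` with all coordinates normalized to [0, 1]
  relative to the image; detections carry a sixth confidence field.
  Class indices follow the taxonomy's canonical ordering.  An image
  dimensions registry is required to recover pixel boxes.
* ``json`` — a single self-describing file with explicit field names and
  an embedded image-dimension registry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .evaluation import MetricsRow, round_half_up
from .interobserver import AgreementRow
from .records import Annotation, AnnotationSet, BoundingBox, Detection
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy

DIALECTS = ("yolo_txt", "json")


def _norm_box_to_pixels(cx: float, cy: float, w: float, h: float,
                        width: int, height: int) -> BoundingBox:
    return BoundingBox(
        (cx - w / 2.0) * width,
        (cy - h / 2.0) * height,
        (cx + w / 2.0) * width,
        (cy + h / 2.0) * height,
    )


def _pixels_to_norm(box: BoundingBox, width: int, height: int) -> tuple[float, float, float, float]:
    cx, cy = box.center
    return (cx / width, cy / height, box.width / width, box.height / height)


def _parse_yolo_file(
    path: Path,
    image_id: str,
    dims: tuple[int, int],
    taxonomy: Taxonomy,
    with_confidence: bool,
) -> list:
    width, height = dims
    n_fields = 6 if with_confidence else 5
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != n_fields:
            raise ValueError(f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}")
        try:
            idx = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable line {line!r}") from exc
        try:
            cls = taxonomy.class_at(idx).name
        except IndexError as exc:
            raise ValueError(f"{path}:{lineno}: unknown class index {idx}") from exc
        cx, cy, w, h = vals[:4]
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{lineno}: normalized value {v} outside [0, 1]")
        box = _norm_box_to_pixels(cx, cy, w, h, width, height)
        if with_confidence:
            out.append(Detection(image_id, cls, box, confidence=vals[4]))
        else:
            out.append(Annotation(image_id, cls, box))
    return out


def _yolo_paths(path: Union[str, Path]) -> list[Path]:
    p = Path(path)
    if p.is_dir():
        return sorted(p.glob("*.txt"))
    if p.is_file():
        return [p]
    raise FileNotFoundError(p)


def load_annotations(
    path: Union[str, Path],
    dialect: str,
    image_dims: dict[str, tuple[int, int]] | None = None,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    annotator_id: str = "",
) -> AnnotationSet:
    """Load ground-truth annotations from either dialect.

    For ``yolo_txt``, ``path`` is a directory of per-image ``.txt`` files
    (image id = file stem) and ``image_dims`` is required.  For ``json``
    the registry is read from the file itself.
    """
    if dialect == "yolo_txt":
        if image_dims is None:
            raise ValueError("yolo_txt dialect requires an image dimensions registry")
        records: list[Annotation] = []
        dims_used: dict[str, tuple[int, int]] = {}
        for p in _yolo_paths(path):
            image_id = p.stem
            if image_id not in image_dims:
                raise KeyError(f"image {image_id!r} missing from dimensions registry")
            dims_used[image_id] = image_dims[image_id]
            for rec in _parse_yolo_file(p, image_id, image_dims[image_id], taxonomy, False):
                records.append(dataclasses.replace(rec, annotator_id=annotator_id))
        return AnnotationSet(records=records, image_dims=dims_used)
    if dialect == "json":
        payload = json.loads(Path(path).read_text())
        dims = {k: (int(v[0]), int(v[1])) for k, v in payload["images"].items()}
        if image_dims:
            dims.update(image_dims)
        records = [
            Annotation(
                image_id=r["image_id"],
                cell_class=taxonomy.resolve(r["cell_class"]),
                box=BoundingBox(r["x_min"], r["y_min"], r["x_max"], r["y_max"]),
                annotator_id=r.get("annotator_id", annotator_id),
            )
            for r in payload["records"]
        ]
        return AnnotationSet(records=records, image_dims=dims)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def save_annotations(
    annotations: AnnotationSet,
    path: Union[str, Path],
    dialect: str,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> None:
    """Write annotations in either dialect (yolo_txt: one file per image)."""
    p = Path(path)
    if dialect == "yolo_txt":
        p.mkdir(parents=True, exist_ok=True)
        by_image: dict[str, list[Annotation]] = {i: [] for i in annotations.image_dims}
        for r in annotations:
            by_image[r.image_id].append(r)
        for image_id, recs in by_image.items():
            w, h = annotations.image_dims[image_id]
            lines = []
            for r in recs:
                cx, cy, bw, bh = _pixels_to_norm(r.box, w, h)
                lines.append(f"{taxonomy.index_of(r.cell_class)} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
            (p / f"{image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    if dialect == "json":
        payload = {
            "images": {k: list(v) for k, v in annotations.image_dims.items()},
            "records": [
                {
                    "image_id": r.image_id,
                    "cell_class": r.cell_class,
                    "x_min": r.box.x_min, "y_min": r.box.y_min,
                    "x_max": r.box.x_max, "y_max": r.box.y_max,
                    "annotator_id": r.annotator_id,
                }
                for r in annotations
            ],
        }
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(payload, indent=1))
        return
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def load_detections(
    path: Union[str, Path],
    dialect: str,
    image_dims: dict[str, tuple[int, int]] | None = None,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> list[Detection]:
    """Load detector outputs (labeled boxes with confidences)."""
    if dialect == "yolo_txt":
        if image_dims is None:
            raise ValueError("yolo_txt dialect requires an image dimensions registry")
        out: list[Detection] = []
        for p in _yolo_paths(path):
            image_id = p.stem
            if image_id not in image_dims:
                raise KeyError(f"image {image_id!r} missing from dimensions registry")
            out.extend(_parse_yolo_file(p, image_id, image_dims[image_id], taxonomy, True))
        return out
    if dialect == "json":
        payload = json.loads(Path(path).read_text())
        return [
            Detection(
                image_id=r["image_id"],
                cell_class=taxonomy.resolve(r["cell_class"]),
                box=BoundingBox(r["x_min"], r["y_min"], r["x_max"], r["y_max"]),
                confidence=float(r["confidence"]),
            )
            for r in payload["records"]
        ]
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def save_detections(
    detections: Sequence[Detection],
    image_dims: dict[str, tuple[int, int]],
    path: Union[str, Path],
    dialect: str,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> None:
    p = Path(path)
    if dialect == "yolo_txt":
        p.mkdir(parents=True, exist_ok=True)
        by_image: dict[str, list[Detection]] = {i: [] for i in image_dims}
        for d in detections:
            by_image.setdefault(d.image_id, []).append(d)
        for image_id, dets in by_image.items():
            if image_id not in image_dims:
                raise KeyError(f"image {image_id!r} missing from dimensions registry")
            w, h = image_dims[image_id]
            lines = []
            for d in dets:
                cx, cy, bw, bh = _pixels_to_norm(d.box, w, h)
                lines.append(
                    f"{taxonomy.index_of(d.cell_class)} {cx:.6f} {cy:.6f} "
                    f"{bw:.6f} {bh:.6f} {d.confidence:.6f}"
                )
            (p / f"{image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    if dialect == "json":
        payload = {
            "images": {k: list(v) for k, v in image_dims.items()},
            "records": [
                {
                    "image_id": d.image_id,
                    "cell_class": d.cell_class,
                    "x_min": d.box.x_min, "y_min": d.box.y_min,
                    "x_max": d.box.x_max, "y_max": d.box.y_max,
                    "confidence": d.confidence,
                }
                for d in detections
            ],
        }
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(payload, indent=1))
        return
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


_METRIC_COLS = ("sensitivity", "specificity", "kappa", "precision", "f1")


def report_frame(rows: Sequence[Union[MetricsRow, AgreementRow]]) -> pd.DataFrame:
    """Rows as a DataFrame at full precision (one schema per call)."""
    kinds = {type(r) for r in rows}
    if len(kinds) > 1:
        raise TypeError(f"mixed report schemas: {sorted(k.__name__ for k in kinds)}")
    schema = kinds.pop() if kinds else MetricsRow
    cols = [f.name for f in dataclasses.fields(schema)]
    return pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=cols)


def save_report(
    rows: Sequence[Union[MetricsRow, AgreementRow]],
    path: Union[str, Path],
    format: str = "csv",
) -> None:
    """Write a metrics or agreement report.

    CSV output rounds rate-valued cells to 2 decimals (half-up), the
    convention of printed tables; JSON keeps full precision.  Missing
    metrics are written as empty cells / nulls, never as 0.
    """
    frame = report_frame(rows)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        disp = frame.copy()
        for col in disp.columns:
            if col in _METRIC_COLS or col == "coefficient":
                disp[col] = [
                    "" if v is None or pd.isna(v) else f"{round_half_up(v):.2f}"
                    for v in disp[col]
                ]
        disp.to_csv(p, index=False)
        return
    if format == "json":
        p.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
        return
    raise ValueError(f"unknown report format {format!r}; expected csv or json")
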