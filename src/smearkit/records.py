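"""Core record types: bounding boxes, annotations, detections, annotation sets.

Coordinates are continuous pixels with the origin at the top-left corner
and a half-open convention ``[x_min, x_max) × [y_min, y_max)``, matching
raster indexing; two boxes that merely share an edge have IOU exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in continuous pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clipped(self, width: float, height: float) -> "BoundingBox":
        """Clip to image bounds; raises if nothing remains."""
        return BoundingBox(
            max(self.x_min, 0.0),
            max(self.y_min, 0.0),
            min(self.x_max, float(width)),
            min(self.y_max, float(height)),
        )


@dataclass(frozen=True)
class Annotation:
    """A ground-truth labeled box placed by an annotator."""

    image_id: str
    cell_class: str
    box: BoundingBox
    annotator_id: str = ""


@dataclass(frozen=True)
class Detection:
    """A detector output: labeled box plus a confidence score in [0, 1]."""

    image_id: str
    cell_class: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class AnnotationSet:
    """Annotations together with the pixel dimensions of their images.

    The dimensions registry maps ``image_id -> (width, height)``.  Boxes
    extending past image bounds are clipped on construction with a warning
    (objects at the field edge are partially captured; no published rule
    governs them, so the visible part is kept).
    """

    records: list[Annotation] = field(default_factory=list)
    image_dims: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clipped: list[Annotation] = []
        n_clipped = 0
        for rec in self.records:
            if rec.image_id not in self.image_dims:
                raise KeyError(f"image {rec.image_id!r} missing from dimensions registry")
            w, h = self.image_dims[rec.image_id]
            b = rec.box
            if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
                rec = replace(rec, box=b.clipped(w, h))
                n_clipped += 1
            clipped.append(rec)
        if n_clipped:
            warnings.warn(f"clipped {n_clipped} box(es) extending past image bounds", stacklevel=2)
        self.records = clipped

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.records)

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.image_dims)

    def for_image(self, image_id: str) -> list[Annotation]:
        return [r for r in self.records if r.image_id == image_id]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.cell_class] = counts.get(r.cell_class, 0) + 1
        return counts

    def subset(self, image_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(image_ids)
        missing = keep - set(self.image_dims)
        if missing:
            raise KeyError(f"unknown image ids: {sorted(missing)}")
        return AnnotationSet(
            records=[r for r in self.records if r.image_id in keep],
            image_dims={i: d for i, d in self.image_dims.items() if i in keep},
        )
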