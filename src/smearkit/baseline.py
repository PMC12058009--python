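"""A classical segment-and-classify detector for synthetic scenes.

This is a deliberately simple, deterministic harness — background
thresholding, connected components, and nearest-centroid classification
on four features (mean RGB, area, equivalent diameter, eccentricity) —
so the full pipeline (generate -> detect -> match -> metrics) can run
end-to-end without any trained neural network.  It is a test harness,
not a competitive detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .records import Annotation, BoundingBox, Detection


@dataclass(frozen=True)
class FeatureVector:
    """Per-object appearance features used by the centroid classifier."""

    mean_rgb: tuple[float, float, float]
    area: float
    equivalent_diameter: float
    eccentricity: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([*self.mean_rgb, self.area, self.equivalent_diameter, self.eccentricity])


def _background_color(image: np.ndarray) -> np.ndarray:
    border = np.concatenate(
        [image[0], image[-1], image[:, 0], image[:, -1]], axis=0
    ).astype(float)
    return np.median(border, axis=0)


def foreground_mask(image: np.ndarray) -> np.ndarray:
    """Histogram-thresholded (Otsu) distance from the background color."""
    dist = np.linalg.norm(image.astype(float) - _background_color(image), axis=-1)
    if np.ptp(dist) == 0.0:
        return np.zeros(image.shape[:2], dtype=bool)
    return dist > threshold_otsu(dist)


def _regions(image: np.ndarray, min_area: int):
    labeled = cc_label(foreground_mask(image))
    return [p for p in regionprops(labeled) if p.area >= min_area]


def segment(image: np.ndarray, min_area: int = 30) -> list[BoundingBox]:
    """Tight per-component boxes of foreground blobs; [] for blank images."""
    boxes = []
    for p in _regions(image, min_area):
        r0, c0, r1, c1 = p.bbox
        boxes.append(BoundingBox(float(c0), float(r0), float(c1), float(r1)))
    return boxes


def _region_feature(image: np.ndarray, prop) -> FeatureVector:
    r0, c0, r1, c1 = prop.bbox
    patch = image[r0:r1, c0:c1].astype(float)
    mean_rgb = patch[prop.image].mean(axis=0)
    return FeatureVector(
        mean_rgb=tuple(float(v) for v in mean_rgb),
        area=float(prop.area),
        equivalent_diameter=float(prop.equivalent_diameter_area),
        eccentricity=float(prop.eccentricity),
    )


def extract_features(image: np.ndarray, min_area: int = 30) -> list[tuple[BoundingBox, FeatureVector]]:
    out = []
    for p in _regions(image, min_area):
        r0, c0, r1, c1 = p.bbox
        out.append(
            (BoundingBox(float(c0), float(r0), float(c1), float(r1)), _region_feature(image, p))
        )
    return out


def box_feature(image: np.ndarray, box: BoundingBox) -> Optional[FeatureVector]:
    """Feature of the foreground inside one (ground-truth) box, or None if empty."""
    x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
    x1, y1 = int(np.ceil(box.x_max)), int(np.ceil(box.y_max))
    crop = image[max(y0, 0): y1, max(x0, 0): x1]
    if crop.size == 0:
        return None
    mask = foreground_mask_local(crop, _background_color(image))
    if mask.sum() < 4:
        return None
    labeled = cc_label(mask)
    props = sorted(regionprops(labeled), key=lambda p: -p.area)
    return _region_feature(crop, props[0])


def foreground_mask_local(crop: np.ndarray, background: np.ndarray) -> np.ndarray:
    dist = np.linalg.norm(crop.astype(float) - background, axis=-1)
    if np.ptp(dist) == 0.0:
        return dist > max(dist.max(), 1.0)  # all-background or all-foreground guess
    return dist > 0.5 * dist.max()


class CentroidModel:
    """Nearest-centroid classifier in standardized feature space.

    Confidence is a softmax over negative standardized distances, hence
    always in (0, 1].  Exact distance ties break to the
    lexicographically first class (classes are stored sorted).
    """

    def __init__(self) -> None:
        self.classes_: Optional[list[str]] = None
        self.centroids_: Optional[np.ndarray] = None
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None

    def fit(self, features: Sequence[FeatureVector], labels: Sequence[str]) -> "CentroidModel":
        if len(features) == 0 or len(features) != len(labels):
            raise ValueError("need equally many features and labels, at least one")
        X = np.stack([f.as_array() for f in features])
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = (X - self.mean_) / self.scale_
        self.classes_ = sorted(set(labels))
        self.centroids_ = np.stack(
            [Z[np.array([l == c for l in labels])].mean(axis=0) for c in self.classes_]
        )
        return self

    def predict(self, feature: FeatureVector) -> tuple[str, float]:
        if self.classes_ is None:
            raise RuntimeError("CentroidModel.predict called before fit")
        z = (feature.as_array() - self.mean_) / self.scale_
        d = np.linalg.norm(self.centroids_ - z, axis=1)
        w = np.exp(-(d - d.min()))
        conf = float(w[np.argmin(d)] / w.sum())
        return self.classes_[int(np.argmin(d))], conf

    def to_json(self, path: Union[str, Path]) -> None:
        if self.classes_ is None:
            raise RuntimeError("cannot serialize an unfitted model")
        Path(path).write_text(json.dumps({
            "classes": self.classes_,
            "centroids": self.centroids_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
        }))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CentroidModel":
        payload = json.loads(Path(path).read_text())
        m = cls()
        m.classes_ = list(payload["classes"])
        m.centroids_ = np.asarray(payload["centroids"], dtype=float)
        m.mean_ = np.asarray(payload["mean"], dtype=float)
        m.scale_ = np.asarray(payload["scale"], dtype=float)
        return m


def fit_from_truth(
    images: dict[str, np.ndarray], annotations: Sequence[Annotation]
) -> CentroidModel:
    """Fit centroids on the foreground features of ground-truth boxes."""
    feats: list[FeatureVector] = []
    labels: list[str] = []
    for rec in annotations:
        fv = box_feature(images[rec.image_id], rec.box)
        if fv is not None:
            feats.append(fv)
            labels.append(rec.cell_class)
    return CentroidModel().fit(feats, labels)


def detect(
    image: np.ndarray, image_id: str, model: CentroidModel, min_area: int = 30
) -> list[Detection]:
    """Segment an image and classify each blob: the end-to-end baseline."""
    out = []
    for box, fv in extract_features(image, min_area):
        cls, conf = model.predict(fv)
        out.append(Detection(image_id, cls, box, conf))
    return out
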