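"""Synthetic smear scenes and a virtual detector with programmable errors.

No public image corpus accompanies the reference study, so every stage
of the pipeline is exercised on synthetic material that reproduces the
study's *structure*: roughly 80 cells per image, class frequencies as
unbalanced as the reference census, class-dependent cell size and color,
and a detector whose per-class true-positive rate, confusion matrix,
box jitter, and confidence distribution are dials rather than unknowns.

Cells are drawn as flat-colored, axis-aligned ellipses.  The evaluation
and augmentation machinery is geometry- and count-driven, so realistic
cell texture would add nothing the tests could see; the returned
annotations are the exact bounding boxes of the drawn ellipses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .records import Annotation, AnnotationSet, BoundingBox, Detection
from .tables import REFERENCE_CENSUS, table_fixtures  # noqa: F401  (re-export)
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy


@dataclass(frozen=True)
class ClassAppearance:
    """Size and color model for one synthetic cell class."""

    diameter_mean: float
    diameter_sd: float
    color_mean: tuple[float, float, float]
    color_sd: float = 6.0


_GROUP_BASE = {
    # (diameter mean px, sd, base RGB) at ~0.25 um/px effective sampling
    "WBC": (34.0, 3.5, (120.0, 80.0, 160.0)),   # large, basophilic purple
    "RBC": (20.0, 2.0, (205.0, 120.0, 110.0)),  # eosin pink-red discs
    "PLT": (9.0, 1.5, (150.0, 110.0, 170.0)),   # small purple fragments
    "ARTIFACT": (16.0, 4.0, (120.0, 120.0, 120.0)),  # neutral debris
}


def default_appearances(taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> dict[str, ClassAppearance]:
    """Per-class appearance defaults: group look plus a deterministic
    per-class shift so the 29 classes are not pixel-identical.

    Real per-class size/color statistics are not published; these values
    are stand-ins chosen to look smear-like, nothing more.
    """
    out: dict[str, ClassAppearance] = {}
    for k, cls in enumerate(taxonomy):
        dmean, dsd, (r, g, b) = _GROUP_BASE[cls.group]
        shift = 14.0 * np.sin(2.0 * np.pi * k / len(taxonomy) + np.array([0.0, 2.1, 4.2]))
        color = tuple(float(np.clip(v + s, 20, 235)) for v, s in zip((r, g, b), shift))
        out[cls.name] = ClassAppearance(
            diameter_mean=dmean * (1.0 + 0.04 * ((k % 5) - 2)),
            diameter_sd=dsd,
            color_mean=color,  # type: ignore[arg-type]
        )
    return out


def census_frequencies(taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> dict[str, float]:
    """Class frequencies proportional to the reference census annotation counts."""
    counts = {c.name: REFERENCE_CENSUS[c.name].annotations for c in taxonomy}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class SceneConfig:
    """Layout and rendering parameters for one synthetic smear field."""

    width: int = 1280
    height: int = 960
    cells_per_image: int = 80
    class_frequencies: Optional[dict[str, float]] = None  # default: census proportions
    appearances: Optional[dict[str, ClassAppearance]] = None
    background: tuple[int, int, int] = (231, 228, 224)
    overlap_limit: float = 0.05
    max_retries: int = 50
    seed: int = 0
    taxonomy: Taxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)

    def resolved_frequencies(self) -> tuple[list[str], np.ndarray]:
        freqs = self.class_frequencies or census_frequencies(self.taxonomy)
        names = sorted(freqs, key=self.taxonomy.index_of)
        p = np.array([freqs[n] for n in names], dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"class frequencies sum to {p.sum():.6f}, not 1")
        return names, p


def _place_cells(
    cfg: SceneConfig, image_id: str, rng: np.random.Generator
) -> tuple[list[Annotation], list[tuple[float, float, float, float]], list[np.ndarray]]:
    names, p = cfg.resolved_frequencies()
    appearances = cfg.appearances or default_appearances(cfg.taxonomy)
    records: list[Annotation] = []
    ellipses: list[tuple[float, float, float, float]] = []  # cy, cx, ry, rx
    colors: list[np.ndarray] = []
    # Accepted box coordinates as growing arrays for vectorized IOU checks.
    coords = np.empty((cfg.cells_per_image, 4))
    n_placed = 0
    skipped = 0
    for _ in range(cfg.cells_per_image):
        cls = names[rng.choice(len(names), p=p)]
        app = appearances[cls]
        placed = False
        for _attempt in range(cfg.max_retries):
            d = max(rng.normal(app.diameter_mean, app.diameter_sd), 4.0)
            rx = d / 2.0
            ry = rx * rng.uniform(0.75, 1.0)
            if 2 * rx >= cfg.width or 2 * ry >= cfg.height:
                continue
            cx = rng.uniform(rx, cfg.width - rx)
            cy = rng.uniform(ry, cfg.height - ry)
            x0, y0, x1, y1 = cx - rx, cy - ry, cx + rx, cy + ry
            prev = coords[:n_placed]
            if n_placed:
                ix = np.minimum(prev[:, 2], x1) - np.maximum(prev[:, 0], x0)
                iy = np.minimum(prev[:, 3], y1) - np.maximum(prev[:, 1], y0)
                inter = np.where((ix > 0) & (iy > 0), ix * iy, 0.0)
                areas = (prev[:, 2] - prev[:, 0]) * (prev[:, 3] - prev[:, 1])
                ious = inter / (areas + (x1 - x0) * (y1 - y0) - inter)
                if ious.max() > cfg.overlap_limit:
                    continue
            color = np.clip(rng.normal(app.color_mean, app.color_sd), 0, 255)
            coords[n_placed] = (x0, y0, x1, y1)
            n_placed += 1
            records.append(Annotation(image_id, cls, BoundingBox(x0, y0, x1, y1)))
            ellipses.append((cy, cx, ry, rx))
            colors.append(color)
            placed = True
            break
        if not placed:
            skipped += 1
    if skipped:
        warnings.warn(
            f"{image_id}: placed {len(records)}/{cfg.cells_per_image} cells "
            f"(overlap limit {cfg.overlap_limit})",
            stacklevel=2,
        )
    return records, ellipses, colors


def generate_layout(
    cfg: SceneConfig, image_id: str = "scene0", rng: Optional[np.random.Generator] = None
) -> AnnotationSet:
    """Ground-truth annotations of one scene without rasterizing pixels.

    Uses the same sampling sequence as :func:`generate_scene`, so the
    same seed yields the same boxes with or without rendering.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    records, _, _ = _place_cells(cfg, image_id, rng)
    return AnnotationSet(records=records, image_dims={image_id: (cfg.width, cfg.height)})


def generate_scene(
    cfg: SceneConfig, image_id: str = "scene0", rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, AnnotationSet]:
    """Render one synthetic smear field and return it with its ground truth."""
    from skimage.draw import ellipse as _draw_ellipse

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    records, ellipses, colors = _place_cells(cfg, image_id, rng)
    image = np.empty((cfg.height, cfg.width, 3), dtype=np.uint8)
    image[...] = np.asarray(cfg.background, dtype=np.uint8)
    for (cy, cx, ry, rx), color in zip(ellipses, colors):
        rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=(cfg.height, cfg.width))
        image[rr, cc] = color.astype(np.uint8)
    aset = AnnotationSet(records=records, image_dims={image_id: (cfg.width, cfg.height)})
    return image, aset


def generate_dataset(
    cfg: SceneConfig,
    n_images: int,
    seed: Optional[int] = None,
    render: bool = True,
) -> tuple[AnnotationSet, dict[str, np.ndarray]]:
    """A stack of scenes sharing one config; ``render=False`` skips pixels."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[Annotation] = []
    dims: dict[str, tuple[int, int]] = {}
    images: dict[str, np.ndarray] = {}
    for k in range(n_images):
        image_id = f"scene{k:05d}"
        if render:
            img, aset = generate_scene(cfg, image_id, rng)
            images[image_id] = img
        else:
            aset = generate_layout(cfg, image_id, rng)
        records.extend(aset.records)
        dims[image_id] = (cfg.width, cfg.height)
    return AnnotationSet(records=records, image_dims=dims), images


@dataclass
class DetectorProfile:
    """Error model of a virtual detector applied to ground truth.

    Each truth box is found with probability ``tpr`` (scalar or
    per-class); found boxes get i.i.d. Gaussian corner jitter, a label
    drawn from the confusion row of their true class (identity when
    ``misclassification`` is None), and a confidence drawn uniformly
    from the correct- or incorrect-label band.  Spurious detections
    arrive as a Poisson count per image, uniformly placed, with sizes
    resampled from the truth boxes.
    """

    tpr: Union[float, dict[str, float]] = 1.0
    misclassification: Optional[dict[str, dict[str, float]]] = None
    jitter_sd: float = 0.0
    spurious_rate: float = 0.0
    confidence_correct: tuple[float, float] = (0.6, 1.0)
    confidence_incorrect: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        rates = self.tpr.values() if isinstance(self.tpr, dict) else [self.tpr]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("true-positive rates must lie in [0, 1]")
        if self.misclassification is not None:
            for cls, row in self.misclassification.items():
                s = sum(row.values())
                if not np.isclose(s, 1.0):
                    raise ValueError(f"confusion row for {cls!r} sums to {s}, not 1")
        if self.jitter_sd < 0 or self.spurious_rate < 0:
            raise ValueError("jitter_sd and spurious_rate must be >= 0")

    def rate_for(self, cell_class: str) -> float:
        if isinstance(self.tpr, dict):
            return self.tpr[cell_class]
        return self.tpr


def _jittered_box(
    box: BoundingBox, sd: float, dims: tuple[int, int], rng: np.random.Generator
) -> BoundingBox:
    if sd == 0.0:
        return box
    w, h = dims
    dx0, dy0, dx1, dy1 = rng.normal(0.0, sd, size=4)
    x0, x1 = box.x_min + dx0, box.x_max + dx1
    y0, y1 = box.y_min + dy0, box.y_max + dy1
    if x1 - x0 < 1.0:  # keep a valid, at-least-1px box
        cx = 0.5 * (x0 + x1)
        x0, x1 = cx - 0.5, cx + 0.5
    if y1 - y0 < 1.0:
        cy = 0.5 * (y0 + y1)
        y0, y1 = cy - 0.5, cy + 0.5
    x0 = float(np.clip(x0, 0.0, w - 1.0))
    y0 = float(np.clip(y0, 0.0, h - 1.0))
    x1 = float(np.clip(x1, x0 + 1.0, w))
    y1 = float(np.clip(y1, y0 + 1.0, h))
    return BoundingBox(x0, y0, x1, y1)


def simulate_detector(
    truth: AnnotationSet,
    profile: DetectorProfile = DetectorProfile(),
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    rng: Optional[np.random.Generator] = None,
) -> list[Detection]:
    """Produce detections from ground truth under the profile's error model."""
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    detections: list[Detection] = []
    lo_c, hi_c = profile.confidence_correct
    lo_i, hi_i = profile.confidence_incorrect
    truth_boxes = [r.box for r in truth.records]

    for rec in truth:
        if rng.random() >= profile.rate_for(rec.cell_class):
            continue
        dims = truth.image_dims[rec.image_id]
        box = _jittered_box(rec.box, profile.jitter_sd, dims, rng)
        label = rec.cell_class
        if profile.misclassification is not None and rec.cell_class in profile.misclassification:
            row = profile.misclassification[rec.cell_class]
            classes = sorted(row, key=taxonomy.index_of)
            probs = np.array([row[c] for c in classes])
            label = classes[rng.choice(len(classes), p=probs / probs.sum())]
        correct = label == rec.cell_class
        conf = rng.uniform(lo_c, hi_c) if correct else rng.uniform(lo_i, hi_i)
        detections.append(Detection(rec.image_id, taxonomy.resolve(label), box, float(conf)))

    if profile.spurious_rate > 0 and truth_boxes:
        for image_id, (w, h) in sorted(truth.image_dims.items()):
            for _ in range(rng.poisson(profile.spurious_rate)):
                proto = truth_boxes[rng.integers(len(truth_boxes))]
                bw = min(proto.width, w - 1.0)
                bh = min(proto.height, h - 1.0)
                x0 = rng.uniform(0.0, w - bw)
                y0 = rng.uniform(0.0, h - bh)
                cls = taxonomy.class_at(rng.integers(len(taxonomy))).name
                conf = float(rng.uniform(lo_i, hi_i))
                detections.append(
                    Detection(image_id, cls, BoundingBox(x0, y0, x0 + bw, y0 + bh), conf)
                )
    return detections
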