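"""Detection-vs-ground-truth evaluation for blood-cell object detection.

The procedure mirrors standard object-detection scoring with one
field-specific twist: true negatives.  A smear image has no meaningful
"background boxes", so TN for a class ``c`` is defined as the sum of true
positives over ``c``'s negative cluster — the confusable cell types that
were correctly recognized as something else.  Specificity is then the
fraction of that confusable population not mistaken for ``c``.

Matching rules (per image):

* detections below the confidence threshold are discarded;
* survivors are processed in descending-confidence order, each greedily
  claiming the still-unclaimed ground-truth box of highest IOU >= the
  IOU threshold (defaults 0.25 and 0.5 respectively);
* claimed pair with equal class -> TP for that class; with different
  class -> FP for the detected class (and the ground-truth object, never
  correctly found, counts as FN for its own class);
* a surviving detection with no qualifying ground truth -> FP;
* a ground-truth box never claimed -> FN.

Per-class metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
Cohen's kappa 2(TP·TN − FP·FN)/[(TP+FP)(FP+TN) + (TP+FN)(TN+FN)],
precision TP/(TP+FP), F1 2PR/(P+R).  A metric whose denominator is zero
is reported as missing (None), not as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .records import Annotation, AnnotationSet, BoundingBox, Detection
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds and rule switches for detection-to-truth matching.

    ``wrong_class_consumes_gt`` controls whether a wrong-class overlap
    (IOU above threshold, labels differ) removes the ground-truth box
    from further matching and books an FN for its class.  The default
    (True) is the reading under which TP + FN equals the class's
    ground-truth count, which corpus-level bookkeeping requires.
    """

    iou_threshold: float = 0.5
    confidence_threshold: float = 0.25
    wrong_class_consumes_gt: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in (0, 1]")
        if not 0.0 <= self.confidence_threshold < 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1)")


@dataclass
class MatchResult:
    """Outcome of matching one image's detections against its ground truth.

    ``det_labels[i]`` is "TP", "FP" or "discarded" for detection ``i``;
    ``gt_matched_by[j]`` is the matching detection index or None;
    ``fn_gt`` lists ground-truth indices counted as FN.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    det_labels: list[str] = field(default_factory=list)
    gt_matched_by: list[Optional[int]] = field(default_factory=list)
    fn_gt: list[int] = field(default_factory=list)


def match(
    detections: Sequence[Detection],
    ground_truth: Sequence[Annotation],
    cfg: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Greedily associate one image's detections with its ground truth."""
    image_ids = {d.image_id for d in detections} | {g.image_id for g in ground_truth}
    if len(image_ids) > 1:
        raise ValueError(f"match() is per-image; got mixed image ids {sorted(image_ids)}")

    result = MatchResult(
        det_labels=["discarded"] * len(detections),
        gt_matched_by=[None] * len(ground_truth),
    )
    # Consumed GT boxes: claimed by a TP or by a wrong-class overlap.
    consumed = np.zeros(len(ground_truth), dtype=bool)
    fn_flag = [False] * len(ground_truth)

    # GT geometry as arrays so each detection scores all boxes at once.
    if ground_truth:
        gx0 = np.array([g.box.x_min for g in ground_truth])
        gy0 = np.array([g.box.y_min for g in ground_truth])
        gx1 = np.array([g.box.x_max for g in ground_truth])
        gy1 = np.array([g.box.y_max for g in ground_truth])
        garea = (gx1 - gx0) * (gy1 - gy0)

    order = sorted(
        (i for i, d in enumerate(detections) if d.confidence >= cfg.confidence_threshold),
        key=lambda i: (-detections[i].confidence, i),
    )
    for i in order:
        det = detections[i]
        best_j = None
        if ground_truth:
            b = det.box
            ix = np.minimum(gx1, b.x_max) - np.maximum(gx0, b.x_min)
            iy = np.minimum(gy1, b.y_max) - np.maximum(gy0, b.y_min)
            inter = np.where((ix > 0) & (iy > 0), ix * iy, 0.0)
            ious = inter / (garea + b.area - inter)
            ious[consumed] = -1.0
            j = int(np.argmax(ious))  # ties: lowest GT index (argmax convention)
            if ious[j] >= cfg.iou_threshold:
                best_j = j
        if best_j is None:
            result.det_labels[i] = "FP"
            continue
        if det.cell_class == ground_truth[best_j].cell_class:
            result.det_labels[i] = "TP"
            result.pairs.append((i, best_j))
            result.gt_matched_by[best_j] = i
            consumed[best_j] = True
        else:
            result.det_labels[i] = "FP"
            if cfg.wrong_class_consumes_gt:
                result.pairs.append((i, best_j))
                result.gt_matched_by[best_j] = i
                consumed[best_j] = True
                fn_flag[best_j] = True

    for j in range(len(ground_truth)):
        if result.gt_matched_by[j] is None or fn_flag[j]:
            result.fn_gt.append(j)
    return result


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/TN/FN."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def derive_tn(
    tp_by_class: dict[str, int], taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> dict[str, int]:
    """TN(c) = sum of TP over c's negative cluster of confusable classes."""
    for name in tp_by_class:
        if name not in taxonomy:
            raise KeyError(f"class {name!r} not in taxonomy")
    out: dict[str, int] = {}
    for cls in taxonomy:
        out[cls.name] = sum(
            tp_by_class.get(taxonomy.resolve(n), 0) for n in cls.negative_cluster
        )
    return out


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FN); None when the class has no ground truth."""
    d = c.tp + c.fn
    return c.tp / d if d else None


def specificity(c: ConfusionCounts) -> Optional[float]:
    """TN / (TN + FP); None when the negative population is empty."""
    d = c.tn + c.fp
    return c.tn / d if d else None


def cohens_kappa(c: ConfusionCounts) -> Optional[float]:
    """Chance-corrected two-rater agreement on the 2x2 table {TP, FP, FN, TN}."""
    d = (c.tp + c.fp) * (c.fp + c.tn) + (c.tp + c.fn) * (c.tn + c.fn)
    return 2.0 * (c.tp * c.tn - c.fp * c.fn) / d if d else None


def precision(c: ConfusionCounts) -> Optional[float]:
    """TP / (TP + FP); None when the class was never predicted."""
    d = c.tp + c.fp
    return c.tp / d if d else None


def f1_score(c: ConfusionCounts) -> Optional[float]:
    """Harmonic mean of precision and sensitivity, 2TP / (2TP + FP + FN)."""
    p, r = precision(c), sensitivity(c)
    if p is None or r is None or p + r == 0.0:
        return None
    return 2.0 * p * r / (p + r)


@dataclass(frozen=True)
class MetricsRow:
    """One class's confusion counts and the five derived metrics."""

    cell_class: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    kappa: Optional[float]
    precision: Optional[float]
    f1: Optional[float]


def metrics_from_counts(
    counts: dict[str, ConfusionCounts], taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> list[MetricsRow]:
    """Compute the five metrics for every class present in ``counts``."""
    rows = []
    ordered = [c.name for c in taxonomy if c.name in counts]
    ordered += [n for n in counts if n not in ordered]
    for name in ordered:
        c = counts[name]
        rows.append(
            MetricsRow(
                cell_class=name,
                tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn,
                sensitivity=sensitivity(c),
                specificity=specificity(c),
                kappa=cohens_kappa(c),
                precision=precision(c),
                f1=f1_score(c),
            )
        )
    return rows


@dataclass
class EvaluationResult:
    rows: list[MetricsRow]
    counts: dict[str, ConfusionCounts]


def evaluate(
    detections: Sequence[Detection],
    ground_truth: AnnotationSet,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    cfg: MatchConfig = MatchConfig(),
) -> EvaluationResult:
    """Match per image, pool counts corpus-wide, derive TN, compute metrics.

    Pooling before metric computation (micro-averaging) makes each row a
    corpus-level total rather than an average of per-image rates.
    """
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}

    by_image: dict[str, list[Detection]] = {}
    for d in detections:
        by_image.setdefault(d.image_id, []).append(d)

    all_images = sorted(set(ground_truth.image_dims) | set(by_image))
    gt_by_image: dict[str, list[Annotation]] = {i: [] for i in all_images}
    for g in ground_truth:
        gt_by_image[g.image_id].append(g)

    for image_id in all_images:
        dets = by_image.get(image_id, [])
        gts = gt_by_image.get(image_id, [])
        res = match(dets, gts, cfg)
        for i, lab in enumerate(res.det_labels):
            if lab == "TP":
                tp[dets[i].cell_class] = tp.get(dets[i].cell_class, 0) + 1
            elif lab == "FP":
                fp[dets[i].cell_class] = fp.get(dets[i].cell_class, 0) + 1
        for j in res.fn_gt:
            fn[gts[j].cell_class] = fn.get(gts[j].cell_class, 0) + 1

    tn = derive_tn(tp, taxonomy)
    seen = set(tp) | set(fp) | set(fn)
    counts = {
        name: ConfusionCounts(
            tp=tp.get(name, 0), fp=fp.get(name, 0), tn=tn.get(name, 0), fn=fn.get(name, 0)
        )
        for name in seen
    }
    return EvaluationResult(rows=metrics_from_counts(counts, taxonomy), counts=counts)


def stratified_split(
    annotations: AnnotationSet,
    test_fraction: float = 0.2,
    min_test_per_class: int = 100,
    seed: int = 0,
) -> tuple[AnnotationSet, AnnotationSet]:
    """Image-level train/test split with a per-class test-set floor.

    Images (not individual annotations) are assigned to one side, so no
    cell object leaks across the split.  After a random assignment that
    puts ~``test_fraction`` of annotations in the test side, images are
    moved from train to test until every class reaches
    ``min(min_test_per_class, class total)`` test annotations.  Classes
    too rare to support the floor without distorting the split (total
    below ``min_test_per_class / test_fraction``) are reported in a
    warning and topped up from whatever is available.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    images = sorted(annotations.image_dims)
    rng.shuffle(images)

    per_image_counts: dict[str, dict[str, int]] = {i: {} for i in images}
    for r in annotations:
        per_image_counts[r.image_id][r.cell_class] = (
            per_image_counts[r.image_id].get(r.cell_class, 0) + 1
        )
    totals = annotations.class_counts()
    n_total = len(annotations)

    test: set[str] = set()
    n_test = 0
    for img in images:
        if n_test >= test_fraction * n_total:
            break
        test.add(img)
        n_test += sum(per_image_counts[img].values())

    infeasible = sorted(
        c for c, t in totals.items() if t < min_test_per_class / test_fraction
    )
    if infeasible and min_test_per_class > 0:
        warnings.warn(
            "test-set floor of "
            f"{min_test_per_class} is infeasible at fraction {test_fraction} for "
            f"classes {infeasible}; using all available",
            stacklevel=2,
        )

    def test_count(cls: str) -> int:
        return sum(per_image_counts[i].get(cls, 0) for i in test)

    for cls in sorted(totals):
        target = min(min_test_per_class, totals[cls])
        deficit = target - test_count(cls)
        if deficit <= 0:
            continue
        candidates = sorted(
            (i for i in images if i not in test and per_image_counts[i].get(cls, 0) > 0),
            key=lambda i: (-per_image_counts[i].get(cls, 0), i),
        )
        for img in candidates:
            if deficit <= 0:
                break
            test.add(img)
            deficit -= per_image_counts[img].get(cls, 0)

    train_ids = [i for i in annotations.image_dims if i not in test]
    return annotations.subset(train_ids), annotations.subset(sorted(test))
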