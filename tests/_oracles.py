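"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the package's own matching/metric code paths:
the assignment oracle enumerates all injective detection-to-truth
pairings by brute force, and the kappa oracle goes through
scikit-learn's two-rater implementation on expanded label vectors.
"""

from __future__ import annotations

import numpy as np

from smearkit.evaluation import MatchConfig, iou, match
from smearkit.records import Annotation, BoundingBox, Detection

CLASSES = ("Lymphocyte", "Neutrophil", "Platelets")


def oracle_counts(dets, gts, cfg: MatchConfig):
    """Per-class TP/FP/FN from the maximum-cardinality assignment
    (ties broken by maximal total IOU), enumerated exhaustively."""
    live = [i for i, d in enumerate(dets) if d.confidence >= cfg.confidence_threshold]
    pairs = {}
    for i in live:
        for j in range(len(gts)):
            v = iou(dets[i].box, gts[j].box)
            if v >= cfg.iou_threshold:
                pairs[(i, j)] = v
    cand = list(pairs)
    best_sel: list[tuple[int, int]] = []
    best_key = (-1, -1.0)

    def rec(idx, used_d, used_g, sel, tot):
        nonlocal best_sel, best_key
        if (len(sel), tot) > best_key:
            best_key, best_sel = (len(sel), tot), list(sel)
        for k in range(idx, len(cand)):
            i, j = cand[k]
            if i in used_d or j in used_g:
                continue
            rec(k + 1, used_d | {i}, used_g | {j}, sel + [(i, j)], tot + pairs[(i, j)])

    rec(0, set(), set(), [], 0.0)
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    matched_d = {i for i, _ in best_sel}
    matched_g = {j for _, j in best_sel}
    for i, j in best_sel:
        if dets[i].cell_class == gts[j].cell_class:
            tp[dets[i].cell_class] = tp.get(dets[i].cell_class, 0) + 1
        else:
            fp[dets[i].cell_class] = fp.get(dets[i].cell_class, 0) + 1
            fn[gts[j].cell_class] = fn.get(gts[j].cell_class, 0) + 1
    for i in live:
        if i not in matched_d:
            fp[dets[i].cell_class] = fp.get(dets[i].cell_class, 0) + 1
    for j in range(len(gts)):
        if j not in matched_g:
            fn[gts[j].cell_class] = fn.get(gts[j].cell_class, 0) + 1
    return tp, fp, fn


def greedy_counts(dets, gts, cfg: MatchConfig):
    """Per-class TP/FP/FN as booked by the package's greedy matcher."""
    res = match(dets, gts, cfg)
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    for i, lab in enumerate(res.det_labels):
        if lab == "TP":
            tp[dets[i].cell_class] = tp.get(dets[i].cell_class, 0) + 1
        elif lab == "FP":
            fp[dets[i].cell_class] = fp.get(dets[i].cell_class, 0) + 1
    for j in res.fn_gt:
        fn[gts[j].cell_class] = fn.get(gts[j].cell_class, 0) + 1
    return tp, fp, fn


def duplicate_free_instance(rng: np.random.Generator):
    """A random per-image instance where greedy matching is provably optimal:
    well-separated ground truth, detections that are jittered copies of a
    subset of it (with label noise and random confidences), no duplicates
    or spurious boxes."""
    n_gt = int(rng.integers(1, 7))
    boxes: list[BoundingBox] = []
    for _ in range(n_gt):
        for _try in range(60):
            d = rng.uniform(16, 30)
            x = rng.uniform(0, 120 - d)
            y = rng.uniform(0, 120 - d)
            b = BoundingBox(x, y, x + d, y + d * rng.uniform(0.8, 1.0))
            if all(iou(b, bb) <= 0.05 for bb in boxes):
                boxes.append(b)
                break
    gts = [Annotation("img", CLASSES[rng.integers(len(CLASSES))], b) for b in boxes]
    dets = []
    for g in gts:
        if rng.random() < 0.85:
            j = rng.normal(0, 1.5, 4)
            b = g.box
            bb = BoundingBox(
                b.x_min + j[0],
                b.y_min + j[1],
                max(b.x_max + j[2], b.x_min + j[0] + 2.0),
                max(b.y_max + j[3], b.y_min + j[1] + 2.0),
            )
            cls = g.cell_class if rng.random() > 0.15 else CLASSES[rng.integers(len(CLASSES))]
            dets.append(Detection("img", cls, bb, float(rng.uniform(0.1, 1.0))))
    return dets, gts


def kappa_sklearn(tp: int, fp: int, fn: int, tn: int):
    """Standard two-rater Cohen's kappa via scikit-learn on the expanded
    2x2 contingency table; None when sklearn reports it undefined (NaN)."""
    from sklearn.metrics import cohen_kappa_score

    y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    if not y_true:
        return None
    k = cohen_kappa_score(y_true, y_pred)
    return None if np.isnan(k) else float(k)
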