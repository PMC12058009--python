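"""Interobserver agreement between two annotators of the same images.

Expert labeling of digitized smears is itself variable — pixelization
and digital magnification blur the cues (nucleus segmentation, cytoplasm
color) that are clear under glass.  The subjective test quantifies this:
one annotator is fixed as the reference, and for every reference
annotation we ask whether the other annotator drew an overlapping box
(IOU >= 0.5, one-to-one) of the same class.

Per class, ``positive`` counts same-class matches, ``negative`` counts
reference annotations left unmatched or matched with a different label,
and the agreement coefficient is positive / (positive + negative).  A
different-class overlap is a negative, not a skip, so that
positive + negative always equals the reference count for the class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import AnnotationSet


@dataclass(frozen=True)
class AgreementRow:
    """Agreement for one class between the reference and one comparison annotator."""

    cell_class: str
    positive: int
    negative: int
    coefficient: Optional[float]


def coefficient(pos: int, neg: int) -> Optional[float]:
    """pos / (pos + neg); None when the class is absent from the reference."""
    total = pos + neg
    return pos / total if total else None


def compare_annotators(
    reference: AnnotationSet,
    other: AnnotationSet,
    iou_threshold: float = 0.5,
) -> list[AgreementRow]:
    """Per-class agreement of ``other`` with the reference annotator.

    Boxes are paired one-to-one per image, greedily by descending IOU
    (confidences play no role here).  Images present in only one of the
    two sets are compared against an empty labeling; fully disjoint
    image sets are an error.
    """
    from .evaluation import iou  # local import: io-level module cycle

    ref_ids, other_ids = set(reference.image_dims), set(other.image_dims)
    if not ref_ids & other_ids:
        raise ValueError("annotation sets cover disjoint image sets; nothing to compare")

    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    order: list[str] = []

    for image_id in sorted(ref_ids | other_ids):
        refs = reference.for_image(image_id) if image_id in ref_ids else []
        others = other.for_image(image_id) if image_id in other_ids else []
        candidates = []
        for i, r in enumerate(refs):
            for j, o in enumerate(others):
                v = iou(r.box, o.box)
                if v >= iou_threshold:
                    candidates.append((v, i, j))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        ref_taken = [False] * len(refs)
        other_taken = [False] * len(others)
        matched_class: dict[int, str] = {}
        for v, i, j in candidates:
            if ref_taken[i] or other_taken[j]:
                continue
            ref_taken[i] = True
            other_taken[j] = True
            matched_class[i] = others[j].cell_class
        for i, r in enumerate(refs):
            if r.cell_class not in pos:
                pos[r.cell_class] = neg[r.cell_class] = 0
                order.append(r.cell_class)
            if matched_class.get(i) == r.cell_class:
                pos[r.cell_class] += 1
            else:
                neg[r.cell_class] += 1

    return [
        AgreementRow(c, pos[c], neg[c], coefficient(pos[c], neg[c]))
        for c in sorted(order)
    ]
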