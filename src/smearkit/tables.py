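"""Reference tables from a pediatric PBS annotation study.

Three small tables, transcribed as plain data, describe the corpus whose
structure the synthetic generator emulates and against which the metric
engine is validated:

* ``REFERENCE_CENSUS`` — per-class annotation counts before and after
  crop augmentation (~500,000 annotations over ~12,000 images, heavily
  unbalanced: microcytic RBCs outnumber basophils by three orders of
  magnitude).  Every row satisfies ``augmented == 4 * annotations`` and
  ``total == 5 * annotations``.
* ``REFERENCE_CONFUSION`` — per-class TP/FP/TN/FN of the study's detector
  on its held-out test split, together with the five reported metrics
  (sensitivity, specificity, Cohen's kappa, precision, F1) at 2 decimals.
* ``REFERENCE_AGREEMENT`` — interobserver counts: per class and per
  annotator pair (primary annotator PA vs annotators A1 and A2), the
  number of reference annotations matched by a same-class box at
  IOU >= 0.5 (positive) or not (negative), plus the reported ratio.
"""

from __future__ import annotations

from typing import NamedTuple


class CensusRow(NamedTuple):
    augmented: int
    annotations: int
    total: int


class ConfusionRow(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


class MetricsReported(NamedTuple):
    sensitivity: float
    specificity: float
    kappa: float
    precision: float
    f1: float


class AgreementReported(NamedTuple):
    positive: int
    negative: int
    coefficient: float


# Per-class census: augmented, annotations, total (= 5 x annotations).
REFERENCE_CENSUS: dict[str, CensusRow] = {
    "Basophil": CensusRow(664, 166, 830),
    "Neutrophil": CensusRow(28348, 7087, 35435),
    "Lymphocyte": CensusRow(28648, 7162, 35810),
    "Monocyte": CensusRow(3104, 776, 3880),
    "Eosinophil": CensusRow(2088, 522, 2610),
    "Hypersegmented neutrophil": CensusRow(744, 186, 930),
    "Band neutrophil": CensusRow(1988, 497, 2485),
    "Myeloblast": CensusRow(868, 217, 1085),
    "Lymphoblast": CensusRow(5624, 1406, 7030),
    "Reactive lymphocyte": CensusRow(3524, 881, 4405),
    "Pencil cell": CensusRow(2976, 744, 3720),
    "Stomatocyte": CensusRow(40084, 10021, 50105),
    "Microcytic RBC": CensusRow(752984, 188246, 941230),
    "Macrocytic RBC": CensusRow(34012, 8503, 42515),
    "Schistocyte": CensusRow(6552, 1638, 8190),
    "Bite cell": CensusRow(3472, 868, 4340),
    "Spherocyte": CensusRow(43788, 10947, 54735),
    "Teardrop cell": CensusRow(7900, 1975, 9875),
    "Target cell": CensusRow(25400, 6350, 31750),
    "Knizocyte": CensusRow(5724, 1431, 7155),
    "Elliptocyte": CensusRow(181604, 45401, 227005),
    "Reticulocyte": CensusRow(8040, 2010, 10050),
    "Hypochromic RBC": CensusRow(176868, 44217, 221085),
    "Echinocyte": CensusRow(7784, 1946, 9730),
    "Sickle cell": CensusRow(2412, 603, 3015),
    "Platelets": CensusRow(84968, 21242, 106210),
    "Platelet clump": CensusRow(41832, 10458, 52290),
    "Normoblast": CensusRow(1424, 356, 1780),
    "Artifact": CensusRow(10128, 2532, 12660),
}

# Per-class confusion counts of the reference detector on its test split.
REFERENCE_CONFUSION: dict[str, ConfusionRow] = {
    "Basophil": ConfusionRow(131, 12, 9453, 9),
    "Neutrophil": ConfusionRow(4641, 499, 5772, 951),
    "Lymphocyte": ConfusionRow(4812, 575, 7299, 917),
    "Monocyte": ConfusionRow(509, 75, 6350, 90),
    "Eosinophil": ConfusionRow(320, 23, 5117, 71),
    "Hypersegmented neutrophil": ConfusionRow(110, 14, 5079, 52),
    "Band neutrophil": ConfusionRow(366, 33, 5071, 37),
    "Myeloblast": ConfusionRow(160, 89, 6362, 4),
    "Lymphoblast": ConfusionRow(1041, 495, 5978, 116),
    "Reactive lymphocyte": ConfusionRow(497, 48, 6522, 184),
    "Pencil cell": ConfusionRow(492, 168, 26699, 116),
    "Stomatocyte": ConfusionRow(5848, 2247, 26699, 2275),
    "Microcytic RBC": ConfusionRow(117604, 49006, 59759, 39202),
    "Macrocytic RBC": ConfusionRow(4838, 3372, 153141, 1790),
    "Schistocyte": ConfusionRow(875, 535, 9951, 412),
    "Bite cell": ConfusionRow(310, 393, 8136, 350),
    "Spherocyte": ConfusionRow(7261, 3717, 122565, 2293),
    "Teardrop cell": ConfusionRow(1120, 753, 26699, 480),
    "Target cell": ConfusionRow(4117, 1800, 6626, 966),
    "Knizocyte": ConfusionRow(778, 285, 4117, 334),
    "Elliptocyte": ConfusionRow(26699, 12443, 8934, 9875),
    "Reticulocyte": ConfusionRow(1428, 916, 12099, 357),
    "Hypochromic RBC": ConfusionRow(23625, 13268, 153738, 15105),
    "Echinocyte": ConfusionRow(1093, 573, 124865, 699),
    "Sickle cell": ConfusionRow(386, 112, 27191, 97),
    "Normoblast": ConfusionRow(309, 47, 7163, 24),
    "Platelets": ConfusionRow(13239, 6125, 16744, 3955),
    "Platelet clump": ConfusionRow(6877, 1667, 13465, 1614),
    "Artifact": ConfusionRow(1710, 181, 772, 279),
}

# The five metrics as reported alongside the confusion counts (2 decimals).
REFERENCE_METRICS: dict[str, MetricsReported] = {
    "Basophil": MetricsReported(0.94, 0.99, 0.92, 0.92, 0.93),
    "Neutrophil": MetricsReported(0.83, 0.92, 0.75, 0.90, 0.86),
    "Lymphocyte": MetricsReported(0.84, 0.93, 0.77, 0.89, 0.86),
    "Monocyte": MetricsReported(0.85, 0.99, 0.85, 0.87, 0.86),
    "Eosinophil": MetricsReported(0.82, 0.99, 0.86, 0.93, 0.87),
    "Hypersegmented neutrophil": MetricsReported(0.68, 0.99, 0.76, 0.89, 0.77),
    "Band neutrophil": MetricsReported(0.91, 0.99, 0.91, 0.92, 0.91),
    "Myeloblast": MetricsReported(0.98, 0.98, 0.77, 0.64, 0.77),
    "Lymphoblast": MetricsReported(0.90, 0.92, 0.73, 0.68, 0.77),
    "Reactive lymphocyte": MetricsReported(0.73, 0.99, 0.79, 0.91, 0.81),
    "Pencil cell": MetricsReported(0.81, 0.99, 0.77, 0.75, 0.78),
    "Stomatocyte": MetricsReported(0.72, 0.92, 0.64, 0.72, 0.72),
    "Microcytic RBC": MetricsReported(0.75, 0.55, 0.30, 0.71, 0.73),
    "Macrocytic RBC": MetricsReported(0.73, 0.98, 0.64, 0.59, 0.65),
    "Schistocyte": MetricsReported(0.68, 0.95, 0.60, 0.62, 0.65),
    "Bite cell": MetricsReported(0.47, 0.96, 0.41, 0.44, 0.45),
    "Spherocyte": MetricsReported(0.76, 0.97, 0.68, 0.66, 0.71),
    "Teardrop cell": MetricsReported(0.70, 0.97, 0.62, 0.60, 0.65),
    "Target cell": MetricsReported(0.81, 0.79, 0.58, 0.70, 0.75),
    "Knizocyte": MetricsReported(0.70, 0.94, 0.65, 0.73, 0.71),
    "Elliptocyte": MetricsReported(0.73, 0.42, 0.15, 0.68, 0.70),
    "Reticulocyte": MetricsReported(0.80, 0.93, 0.64, 0.61, 0.69),
    "Hypochromic RBC": MetricsReported(0.61, 0.92, 0.54, 0.64, 0.62),
    "Echinocyte": MetricsReported(0.61, 0.99, 0.63, 0.66, 0.63),
    "Sickle cell": MetricsReported(0.80, 0.99, 0.78, 0.78, 0.79),
    "Normoblast": MetricsReported(0.93, 0.99, 0.89, 0.87, 0.90),
    "Platelets": MetricsReported(0.77, 0.73, 0.49, 0.68, 0.72),
    "Platelet clump": MetricsReported(0.81, 0.89, 0.70, 0.80, 0.80),
    "Artifact": MetricsReported(0.86, 0.81, 0.65, 0.90, 0.88),
}

ANNOTATOR_PAIRS = ("PA-A1", "PA-A2")

# Interobserver agreement per class and annotator pair: (positive, negative,
# reported coefficient).  Only classes present in the 20-image subjective
# subset appear.
REFERENCE_AGREEMENT: dict[str, dict[str, AgreementReported]] = {
    "Neutrophil": {"PA-A1": AgreementReported(17, 2, 0.89), "PA-A2": AgreementReported(19, 0, 1.00)},
    "Lymphocyte": {"PA-A1": AgreementReported(7, 0, 1.00), "PA-A2": AgreementReported(6, 1, 0.86)},
    "Band neutrophil": {"PA-A1": AgreementReported(0, 2, 0.00), "PA-A2": AgreementReported(0, 2, 0.00)},
    "Reactive lymphocyte": {"PA-A1": AgreementReported(0, 1, 0.00), "PA-A2": AgreementReported(0, 1, 0.00)},
    "Pencil cell": {"PA-A1": AgreementReported(12, 3, 0.80), "PA-A2": AgreementReported(9, 6, 0.60)},
    "Stomatocyte": {"PA-A1": AgreementReported(14, 43, 0.25), "PA-A2": AgreementReported(27, 30, 0.47)},
    "Microcytic RBC": {"PA-A1": AgreementReported(447, 472, 0.49), "PA-A2": AgreementReported(358, 561, 0.39)},
    "Macrocytic RBC": {"PA-A1": AgreementReported(20, 39, 0.34), "PA-A2": AgreementReported(16, 43, 0.27)},
    "Schistocyte": {"PA-A1": AgreementReported(5, 1, 0.83), "PA-A2": AgreementReported(5, 1, 0.83)},
    "Bite cell": {"PA-A1": AgreementReported(1, 1, 0.50), "PA-A2": AgreementReported(2, 0, 1.00)},
    "Spherocyte": {"PA-A1": AgreementReported(43, 6, 0.88), "PA-A2": AgreementReported(42, 7, 0.86)},
    "Teardrop cell": {"PA-A1": AgreementReported(11, 22, 0.33), "PA-A2": AgreementReported(18, 15, 0.55)},
    "Target cell": {"PA-A1": AgreementReported(116, 12, 0.91), "PA-A2": AgreementReported(92, 36, 0.72)},
    "Knizocyte": {"PA-A1": AgreementReported(2, 7, 0.22), "PA-A2": AgreementReported(7, 2, 0.78)},
    "Elliptocyte": {"PA-A1": AgreementReported(380, 132, 0.74), "PA-A2": AgreementReported(264, 248, 0.52)},
    "Reticulocyte": {"PA-A1": AgreementReported(3, 17, 0.15), "PA-A2": AgreementReported(13, 7, 0.65)},
    "Hypochromic RBC": {"PA-A1": AgreementReported(360, 333, 0.52), "PA-A2": AgreementReported(425, 268, 0.61)},
    "Echinocyte": {"PA-A1": AgreementReported(1, 0, 1.00), "PA-A2": AgreementReported(0, 1, 0.00)},
    "Sickle cell": {"PA-A1": AgreementReported(10, 2, 0.83), "PA-A2": AgreementReported(9, 3, 0.75)},
    "Platelets": {"PA-A1": AgreementReported(35, 38, 0.48), "PA-A2": AgreementReported(51, 22, 0.70)},
    "Platelet clump": {"PA-A1": AgreementReported(15, 23, 0.39), "PA-A2": AgreementReported(27, 11, 0.71)},
    "Artifact": {"PA-A1": AgreementReported(2, 4, 0.33), "PA-A2": AgreementReported(0, 6, 0.00)},
}


class ReferenceTables(NamedTuple):
    census: dict[str, CensusRow]
    confusion: dict[str, ConfusionRow]
    metrics: dict[str, MetricsReported]
    agreement: dict[str, dict[str, AgreementReported]]


def table_fixtures() -> ReferenceTables:
    """All reference tables bundled together (census, confusion, metrics, agreement)."""
    return ReferenceTables(
        census=dict(REFERENCE_CENSUS),
        confusion=dict(REFERENCE_CONFUSION),
        metrics=dict(REFERENCE_METRICS),
        agreement={k: dict(v) for k, v in REFERENCE_AGREEMENT.items()},
    )
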