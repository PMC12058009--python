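import numpy as np
import pytest

from _oracles import duplicate_free_instance, greedy_counts, kappa_sklearn, oracle_counts
from smearkit.evaluation import (
    ConfusionCounts,
    MatchConfig,
    cohens_kappa,
    derive_tn,
    evaluate,
    f1_score,
    iou,
    match,
    precision,
    round_half_up,
    sensitivity,
    specificity,
    stratified_split,
)
from smearkit.records import Annotation, AnnotationSet, BoundingBox, Detection
from smearkit.synthetic import DetectorProfile, simulate_detector
from smearkit.tables import REFERENCE_CONFUSION


def box(x0, y0, x1, y1):
    return BoundingBox(float(x0), float(y0), float(x1), float(y1))


class TestIou:
    def test_identical_boxes(self):
        assert iou(box(0, 0, 10, 10), box(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(0, 0, 10, 10), box(20, 20, 30, 30)) == 0.0

    def test_half_overlap(self):
        # intersection 50, union 150
        assert iou(box(0, 0, 10, 10), box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_edge_adjacent_boxes_have_zero_iou(self):
        assert iou(box(0, 0, 10, 10), box(10, 0, 20, 10)) == 0.0

    def test_symmetry_and_range(self, rng):
        def random_box():
            x0, y0 = rng.uniform(0, 50, 2)
            w, h = rng.uniform(1, 30, 2)
            return box(x0, y0, x0 + w, y0 + h)

        for _ in range(50):
            a, b = random_box(), random_box()
            v, w = iou(a, b), iou(b, a)
            assert v == w and 0.0 <= v <= 1.0


class TestMatch:
    def gt(self, cls="Basophil", b=(10, 10, 40, 40)):
        return Annotation("img", cls, box(*b))

    def det(self, cls="Basophil", b=(10, 10, 40, 40), conf=0.9):
        return Detection("img", cls, box(*b), conf)

    def test_exact_same_class_is_tp(self):
        res = match([self.det()], [self.gt()])
        assert res.det_labels == ["TP"] and res.fn_gt == []

    def test_wrong_class_overlap_is_fp_plus_fn(self):
        res = match([self.det(cls="Lymphocyte")], [self.gt(cls="Basophil")])
        assert res.det_labels == ["FP"]
        assert res.fn_gt == [0]  # the GT object was never correctly found

    def test_wrong_class_switch_keeps_gt_available(self):
        cfg = MatchConfig(wrong_class_consumes_gt=False)
        dets = [self.det(cls="Lymphocyte", conf=0.95), self.det(cls="Basophil", conf=0.6)]
        res = match(dets, [self.gt(cls="Basophil")], cfg)
        assert res.det_labels == ["FP", "TP"] and res.fn_gt == []

    def test_below_confidence_threshold_discarded(self):
        res = match([self.det(conf=0.2)], [self.gt()])
        assert res.det_labels == ["discarded"] and res.fn_gt == [0]

    def test_duplicate_detection_is_fp(self):
        dets = [self.det(conf=0.9), self.det(conf=0.8, b=(11, 11, 41, 41))]
        res = match(dets, [self.gt()])
        assert res.det_labels == ["TP", "FP"]

    def test_low_iou_leaves_gt_as_fn(self):
        res = match([self.det(b=(100, 100, 130, 130))], [self.gt()])
        assert res.det_labels == ["FP"] and res.fn_gt == [0]

    def test_mixed_image_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed image ids"):
            match([self.det()], [Annotation("other", "Basophil", box(0, 0, 5, 5))])

    def test_higher_confidence_claims_first(self):
        # two detections over one GT: the higher-confidence one wins
        dets = [self.det(conf=0.5), self.det(conf=0.99)]
        res = match(dets, [self.gt()])
        assert res.det_labels == ["FP", "TP"]


class TestDeriveTn:
    def test_basophil_negative_sum(self, taxonomy):
        tn = derive_tn({"Lymphocyte": 100, "Neutrophil": 50}, taxonomy)
        assert tn["Basophil"] == 150

    def test_all_zero(self, taxonomy):
        tn = derive_tn({}, taxonomy)
        assert set(tn.values()) == {0}

    def test_never_counts_own_tp(self, taxonomy):
        tn = derive_tn({"Basophil": 1000}, taxonomy)
        assert tn["Basophil"] == 0

    def test_unknown_class_rejected(self, taxonomy):
        with pytest.raises(KeyError):
            derive_tn({"Megakaryocyte": 5}, taxonomy)


class TestMetricFormulas:
    """Spot checks against reference rows whose printed values are
    arithmetically consistent with their printed counts."""

    def test_sensitivity_examples(self):
        assert round_half_up(sensitivity(ConfusionCounts(131, 12, 9453, 9))) == 0.94
        assert round_half_up(sensitivity(ConfusionCounts(160, 89, 6362, 4))) == 0.98
        assert sensitivity(ConfusionCounts(tp=7, fn=0)) == 1.0

    def test_specificity_examples(self):
        c = ConfusionCounts(*REFERENCE_CONFUSION["Microcytic RBC"])
        assert round_half_up(specificity(c)) == 0.55
        assert specificity(ConfusionCounts(tp=1, tn=9, fp=0)) == 1.0

    def test_kappa_examples(self):
        assert round_half_up(cohens_kappa(ConfusionCounts(131, 12, 9453, 9))) == 0.92
        assert round_half_up(cohens_kappa(ConfusionCounts(366, 33, 5071, 37))) == 0.91
        assert cohens_kappa(ConfusionCounts(tp=5, tn=50, fp=0, fn=0)) == 1.0

    def test_precision_examples(self):
        assert round_half_up(precision(ConfusionCounts(131, 12, 9453, 9))) == 0.92
        assert round_half_up(precision(ConfusionCounts(310, 393, 8136, 350))) == 0.44
        assert precision(ConfusionCounts(tp=3, fp=0)) == 1.0

    def test_f1_examples(self):
        assert round_half_up(f1_score(ConfusionCounts(131, 12, 9453, 9))) == 0.93
        assert round_half_up(f1_score(ConfusionCounts(310, 393, 8136, 350))) == 0.45
        # equal precision and recall -> F1 equals both
        c = ConfusionCounts(tp=30, fp=10, fn=10, tn=100)
        assert f1_score(c) == pytest.approx(precision(c)) == pytest.approx(sensitivity(c))

    def test_zero_denominators_reported_missing(self):
        empty = ConfusionCounts()
        assert sensitivity(empty) is None
        assert specificity(empty) is None
        assert cohens_kappa(empty) is None
        assert precision(empty) is None
        assert f1_score(empty) is None


class TestMetricProperties:
    def test_kappa_matches_two_rater_oracle(self, rng):
        for _ in range(300):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, 4))
            ours = cohens_kappa(ConfusionCounts(tp, fp, tn, fn))
            theirs = kappa_sklearn(tp, fp, fn, tn)
            assert (ours is None) == (theirs is None)
            if ours is not None:
                assert ours == pytest.approx(theirs, abs=1e-12)

    def test_kappa_is_one_iff_no_errors(self, rng):
        assert cohens_kappa(ConfusionCounts(tp=3, tn=9)) == 1.0
        for _ in range(100):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 30, 4))
            k = cohens_kappa(ConfusionCounts(tp, fp, tn, fn))
            if k == 1.0:
                assert fp == 0 and fn == 0 and tp > 0 and tn > 0

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(200):
            tp, fp, fn = (int(v) for v in rng.integers(0, 50, 3))
            c = ConfusionCounts(tp, fp, 0, fn)
            f, p, r = f1_score(c), precision(c), sensitivity(c)
            if f is not None:
                assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12


class TestGreedyAgainstBruteForce:
    def test_counts_agree_on_duplicate_free_instances(self):
        rng = np.random.default_rng(777)
        cfg = MatchConfig()
        for _ in range(200):
            dets, gts = duplicate_free_instance(rng)
            assert greedy_counts(dets, gts, cfg) == oracle_counts(dets, gts, cfg)


class TestEvaluate:
    def test_perfect_detector(self, multi_image_truth):
        dets = simulate_detector(multi_image_truth, DetectorProfile(tpr=1.0, seed=1))
        result = evaluate(dets, multi_image_truth)
        for row in result.rows:
            assert row.sensitivity == 1.0 and row.precision == 1.0 and row.fn == 0

    def test_tp_plus_fn_equals_ground_truth_count(self, multi_image_truth):
        profile = DetectorProfile(tpr=0.7, jitter_sd=1.0, spurious_rate=2.0, seed=5)
        dets = simulate_detector(multi_image_truth, profile)
        result = evaluate(dets, multi_image_truth)
        for cls, n in multi_image_truth.class_counts().items():
            assert result.counts[cls].tp + result.counts[cls].fn == n

    def test_no_detection_double_counted(self, multi_image_truth):
        profile = DetectorProfile(tpr=0.8, jitter_sd=1.0, spurious_rate=1.5, seed=6)
        dets = simulate_detector(multi_image_truth, profile)
        cfg = MatchConfig()
        surviving = sum(1 for d in dets if d.confidence >= cfg.confidence_threshold)
        result = evaluate(dets, multi_image_truth, cfg=cfg)
        total_tp = sum(c.tp for c in result.counts.values())
        total_fp = sum(c.fp for c in result.counts.values())
        assert total_tp + total_fp == surviving

    def test_tn_column_is_negative_cluster_sum(self, multi_image_truth, taxonomy):
        dets = simulate_detector(multi_image_truth, DetectorProfile(tpr=0.9, seed=7))
        result = evaluate(dets, multi_image_truth, taxonomy)
        tp = {c: result.counts[c].tp for c in result.counts}
        expected = derive_tn(tp, taxonomy)
        for cls, c in result.counts.items():
            assert c.tn == expected[cls]


def _balanced_set(n_images=1000, per_image=10, n_classes=5, seed=0):
    rng = np.random.default_rng(seed)
    classes = [f"C{k}" for k in range(n_classes)]
    records, dims = [], {}
    for i in range(n_images):
        img = f"im{i:04d}"
        dims[img] = (200, 200)
        for _ in range(per_image):
            x, y = rng.uniform(0, 170, 2)
            records.append(Annotation(img, classes[int(rng.integers(n_classes))], box(x, y, x + 20, y + 20)))
    return AnnotationSet(records=records, image_dims=dims)


class TestStratifiedSplit:
    def test_fraction_on_balanced_set(self):
        aset = _balanced_set()
        train, test = stratified_split(aset, test_fraction=0.2, min_test_per_class=100, seed=42)
        frac = len(test) / len(aset)
        assert 0.17 <= frac <= 0.23
        assert len(train) + len(test) == len(aset)
        assert not set(train.image_dims) & set(test.image_dims)

    def test_min_per_class_floor(self):
        aset = _balanced_set()
        _, test = stratified_split(aset, test_fraction=0.2, min_test_per_class=100, seed=42)
        for cls, n in test.class_counts().items():
            assert n >= 100

    def test_determinism(self):
        aset = _balanced_set(n_images=200)
        a = stratified_split(aset, 0.2, 50, seed=7)
        b = stratified_split(aset, 0.2, 50, seed=7)
        assert sorted(a[1].image_dims) == sorted(b[1].image_dims)
        c = stratified_split(aset, 0.2, 50, seed=8)
        assert sorted(a[1].image_dims) != sorted(c[1].image_dims)

    def test_infeasible_class_warns_and_uses_all_available(self):
        aset = _balanced_set(n_images=60, per_image=2, n_classes=1, seed=3)
        # 120 annotations, floor of 100 at fraction 0.2 is infeasible
        with pytest.warns(UserWarning, match="infeasible"):
            _, test = stratified_split(aset, test_fraction=0.2, min_test_per_class=100, seed=1)
        assert test.class_counts()["C0"] >= 100  # all it can get

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_balanced_set(n_images=10), test_fraction=1.5)
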