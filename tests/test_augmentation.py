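import numpy as np
import pytest

from smearkit.augmentation import (
    IDENTITY_CONFIG,
    AugmentationConfig,
    CellCrop,
    augment,
    augmentation_census,
    build_training_corpus,
    extract_crop,
)
from smearkit.records import Annotation, AnnotationSet, BoundingBox
from smearkit.tables import REFERENCE_CENSUS


def _flat_image(w=200, h=150, value=200):
    img = np.full((h, w, 3), value, dtype=np.uint8)
    rng = np.random.default_rng(0)
    img += rng.integers(0, 20, img.shape, dtype=np.uint8)
    return img


def _ann(b, cls="Basophil", image_id="i"):
    return Annotation(image_id, cls, BoundingBox(*map(float, b)))


class TestExtractCrop:
    def test_zero_margin_crop_size(self):
        crop = extract_crop(_flat_image(), _ann((10, 10, 20, 20)))
        assert crop.pixels.shape == (10, 10, 3)
        assert crop.provenance == "original"

    def test_half_margin_doubles_window(self):
        crop = extract_crop(_flat_image(), _ann((50, 50, 60, 60)), margin=0.5)
        assert crop.pixels.shape == (20, 20, 3)

    def test_border_box_clipped(self):
        crop = extract_crop(_flat_image(), _ann((0, 0, 10, 10)), margin=0.5)
        assert crop.pixels.shape == (15, 15, 3)  # clipped at top-left

    def test_crop_is_a_copy(self):
        img = _flat_image()
        crop = extract_crop(img, _ann((10, 10, 20, 20)))
        img[:] = 0
        assert crop.pixels.max() > 0


class TestAugment:
    def base_crop(self, seed=1, size=24):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
        return CellCrop(pixels=px, source=_ann((0, 0, size, size)))

    def test_identity_config_is_bitwise_identity(self):
        crop = self.base_crop()
        out = augment(crop, IDENTITY_CONFIG)
        assert len(out) == IDENTITY_CONFIG.factor == 4
        for v in out:
            assert np.array_equal(v.pixels, crop.pixels)

    def test_mirror_variants_are_flips_and_involutive(self):
        cfg = AugmentationConfig(
            factor=8, mirror=frozenset({"horizontal"}), hue_delta=0,
            saturation_delta=0, exposure_delta=0, noise_sigma=0, seed=5,
        )
        crop = self.base_crop()
        flipped = crop.pixels[:, ::-1]
        kinds = set()
        for v in augment(crop, cfg):
            if np.array_equal(v.pixels, crop.pixels):
                kinds.add("orig")
            elif np.array_equal(v.pixels, flipped):
                kinds.add("flip")
                # mirroring the mirrored variant restores the original
                assert np.array_equal(v.pixels[:, ::-1], crop.pixels)
            else:
                pytest.fail("horizontal-mirror-only variant is neither original nor flip")
        assert kinds == {"orig", "flip"}

    def test_factor_zero_gives_empty_list(self):
        assert augment(self.base_crop(), AugmentationConfig(factor=0)) == []

    def test_label_and_provenance_preserved(self):
        out = augment(self.base_crop(), AugmentationConfig(seed=2))
        assert [v.provenance for v in out] == [f"augmented:{k}" for k in range(4)]
        assert {v.cell_class for v in out} == {"Basophil"}

    def test_determinism_under_seed(self):
        cfg = AugmentationConfig(seed=11)
        a = augment(self.base_crop(), cfg)
        b = augment(self.base_crop(), cfg)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_pixels_stay_uint8_in_range_after_jitter_and_noise(self):
        bright = CellCrop(np.full((16, 16, 3), 250, np.uint8), _ann((0, 0, 16, 16)))
        dark = CellCrop(np.full((16, 16, 3), 5, np.uint8), _ann((0, 0, 16, 16)))
        cfg = AugmentationConfig(noise_sigma=30.0, exposure_delta=0.5, seed=3)
        for crop in (bright, dark):
            for v in augment(crop, cfg):
                assert v.pixels.dtype == np.uint8
                assert v.pixels.min() >= 0 and v.pixels.max() <= 255

    def test_neighbor_paste_spares_target_center(self):
        cfg = AugmentationConfig(
            factor=6, mirror=frozenset(), hue_delta=0, saturation_delta=0,
            exposure_delta=0, noise_sigma=0, neighbor_placement=True, seed=9,
        )
        target = self.base_crop(seed=4, size=30)
        distractor = CellCrop(
            np.full((20, 20, 3), 40, np.uint8), _ann((0, 0, 20, 20), cls="Lymphocyte")
        )
        same_class = CellCrop(
            np.full((20, 20, 3), 90, np.uint8), _ann((0, 0, 20, 20), cls="Basophil")
        )
        out = augment(target, cfg, distractors=[distractor, same_class])
        cy, cx = 15, 15
        changed = 0
        for v in out:
            assert v.pixels[cy, cx].tolist() == target.pixels[cy, cx].tolist()
            if not np.array_equal(v.pixels, target.pixels):
                changed += 1
                # pasted pixels come from the different-class distractor
                assert (v.pixels == 40).any()
                assert not (v.pixels == 90).all(axis=-1).any()
        assert changed > 0


class TestCorpus:
    def test_basophil_row_counts(self):
        # 166 annotated basophils at factor 4 -> 664 augmented, 830 total
        img = _flat_image(400, 300)
        rng = np.random.default_rng(1)
        recs = []
        for _ in range(166):
            x, y = rng.uniform(0, 380), rng.uniform(0, 280)
            recs.append(_ann((x, y, x + 12, y + 12)))
        aset = AnnotationSet(records=recs, image_dims={"i": (400, 300)})
        manifest = build_training_corpus(aset, {"i": img}, AugmentationConfig(seed=1), keep_crops=False)
        row = manifest.census.set_index("cell_class").loc["Basophil"]
        assert (row["augmented"], row["annotations"], row["total"]) == (664, 166, 830)

    def test_count_law_on_miniaturized_census(self):
        # reference census scaled by ~1/1000, run through the real pipeline
        img = _flat_image(600, 400)
        rng = np.random.default_rng(2)
        recs = []
        mini = {c: max(1, r.annotations // 1000) for c, r in REFERENCE_CENSUS.items()}
        for cls, n in mini.items():
            for _ in range(n):
                x, y = rng.uniform(0, 580), rng.uniform(0, 380)
                recs.append(_ann((x, y, x + 10, y + 10), cls=cls))
        aset = AnnotationSet(records=recs, image_dims={"i": (600, 400)})
        manifest = build_training_corpus(aset, {"i": img}, AugmentationConfig(seed=3), keep_crops=False)
        census = manifest.census.set_index("cell_class")
        assert len(census) == 29
        for cls, n in mini.items():
            assert census.loc[cls, "total"] == 5 * n
            assert census.loc[cls, "augmented"] == 4 * n

    def test_factor_zero_manifest_equals_input_census(self):
        img = _flat_image()
        aset = AnnotationSet(
            records=[_ann((10, 10, 20, 20)), _ann((30, 30, 45, 45), cls="Lymphocyte")],
            image_dims={"i": (200, 150)},
        )
        manifest = build_training_corpus(aset, {"i": img}, AugmentationConfig(factor=0))
        census = manifest.census.set_index("cell_class")
        assert (census["total"] == census["annotations"]).all()
        assert (census["augmented"] == 0).all()

    def test_missing_image_is_hard_error(self):
        aset = AnnotationSet(records=[_ann((1, 1, 9, 9))], image_dims={"i": (50, 50)})
        with pytest.raises(KeyError, match="'i'"):
            build_training_corpus(aset, {}, AugmentationConfig())

    def test_census_arithmetic_reproduces_reference_totals(self):
        counts = {c: r.annotations for c, r in REFERENCE_CENSUS.items()}
        table = augmentation_census(counts, factor=4).set_index("cell_class")
        for cls, row in REFERENCE_CENSUS.items():
            assert table.loc[cls, "augmented"] == row.augmented
            assert table.loc[cls, "total"] == row.total
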