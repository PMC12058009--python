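"""Crop-level augmentation of annotated cell objects.

Training corpora of smear annotations are heavily unbalanced (one slide
yields thousands of microcytic RBCs per basophil), and a single cell can
appear in many orientations and staining conditions.  The augmentation
scheme therefore generates, for every annotated cell crop, ``factor``
label-preserving variants (default 4, giving a uniform x5 expansion of
each class): random mirroring, hue/saturation/exposure jitter in HSV
space, tinted Gaussian noise, and optionally a pasted "neighbor" cell of
clearly different size — mimicking the visual size comparison experts
use to separate microcytic, macrocytic, and normal red cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage import transform as _sktransform

from .records import Annotation, AnnotationSet
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy


@dataclass(frozen=True)
class AugmentationConfig:
    """Knobs of the crop augmentation scheme.

    ``factor`` variants are produced per crop.  Jitter half-ranges:
    ``hue_delta`` in degrees, ``saturation_delta`` and ``exposure_delta``
    as relative gains.  ``noise_sigma`` is the per-channel Gaussian std
    on the 8-bit scale; each variant picks one tint from ``noise_tints``
    (RGB channel weights) so the noise is colored, not gray.  Neighbor
    placement pastes a distractor cell whose diameter ratio to the
    target falls outside ``neighbor_ratio_band``.
    """

    factor: int = 4
    mirror: frozenset[str] = frozenset({"horizontal", "vertical"})
    hue_delta: float = 10.0
    saturation_delta: float = 0.10
    exposure_delta: float = 0.15
    noise_sigma: float = 4.0
    noise_tints: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.25, 0.25), (0.25, 1.0, 0.25), (0.25, 0.25, 1.0), (1.0, 1.0, 1.0),
    )
    neighbor_placement: bool = False
    neighbor_ratio_band: tuple[float, float] = (0.8, 1.25)
    neighbor_ratio_limits: tuple[float, float] = (0.5, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ValueError("factor must be >= 0")
        if not self.mirror <= {"horizontal", "vertical"}:
            raise ValueError(f"unknown mirror axes {self.mirror}")
        for v in (self.hue_delta, self.saturation_delta, self.exposure_delta, self.noise_sigma):
            if v < 0:
                raise ValueError("jitter half-ranges and noise sigma must be >= 0")


IDENTITY_CONFIG = AugmentationConfig(
    mirror=frozenset(), hue_delta=0.0, saturation_delta=0.0,
    exposure_delta=0.0, noise_sigma=0.0, neighbor_placement=False,
)


@dataclass
class CellCrop:
    """A sub-raster around one annotated cell, with provenance."""

    pixels: np.ndarray  # uint8, H x W x 3
    source: Annotation
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("crop pixels must be H x W x 3")
        if self.pixels.shape[0] == 0 or self.pixels.shape[1] == 0:
            raise ValueError("zero-area crop")

    @property
    def cell_class(self) -> str:
        return self.source.cell_class


def extract_crop(image: np.ndarray, annotation: Annotation, margin: float = 0.0) -> CellCrop:
    """Cut the annotation's box, expanded by ``margin`` x box size per side.

    The window is clipped at image bounds (cells at the field edge yield
    smaller crops); a window that clips to nothing is an error.
    """
    b = annotation.box
    mx, my = margin * b.width, margin * b.height
    x0 = max(int(np.floor(b.x_min - mx)), 0)
    y0 = max(int(np.floor(b.y_min - my)), 0)
    x1 = min(int(np.ceil(b.x_max + mx)), image.shape[1])
    y1 = min(int(np.ceil(b.y_max + my)), image.shape[0])
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"crop for {annotation.image_id!r} box {b} clips to zero area")
    return CellCrop(pixels=image[y0:y1, x0:x1].copy(), source=annotation)


def _jitter_hsv(pixels: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    hsv = _skcolor.rgb2hsv(pixels.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue_delta, cfg.hue_delta) / 360.0) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + rng.uniform(-cfg.saturation_delta, cfg.saturation_delta)), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + rng.uniform(-cfg.exposure_delta, cfg.exposure_delta)), 0, 1)
    rgb = _skcolor.hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def _tinted_noise(pixels: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    tint = np.asarray(cfg.noise_tints[rng.integers(len(cfg.noise_tints))], dtype=np.float64)
    noise = rng.normal(0.0, cfg.noise_sigma, size=pixels.shape[:2])[..., None] * tint
    return np.clip(np.rint(pixels.astype(np.float64) + noise), 0, 255).astype(np.uint8)


def _sample_neighbor_ratio(cfg: AugmentationConfig, rng: np.random.Generator) -> float:
    lo, hi = cfg.neighbor_ratio_band
    lim_lo, lim_hi = cfg.neighbor_ratio_limits
    # Distractor is clearly smaller or clearly larger, never near-equal.
    if rng.random() < 0.5 and lim_lo < lo:
        return rng.uniform(lim_lo, lo)
    return rng.uniform(hi, lim_hi)


def _paste_neighbor(
    pixels: np.ndarray,
    distractor: CellCrop,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    out = pixels.copy()
    h, w = out.shape[:2]
    ratio = _sample_neighbor_ratio(cfg, rng)
    target_diam = 0.5 * (h + w)
    dh, dw = distractor.pixels.shape[:2]
    scale = ratio * target_diam / max(0.5 * (dh + dw), 1.0)
    nh, nw = max(int(round(dh * scale)), 1), max(int(round(dw * scale)), 1)
    patch = np.clip(
        np.rint(_sktransform.resize(distractor.pixels, (nh, nw, 3), preserve_range=True,
                                    anti_aliasing=True)),
        0, 255,
    ).astype(np.uint8)
    # Paste flush against a random edge, clipped, skipping the crop center
    # so the target cell itself stays visible.
    side = rng.integers(4)
    if side == 0:
        y0, x0 = 0, 0
    elif side == 1:
        y0, x0 = 0, max(w - nw, 0)
    elif side == 2:
        y0, x0 = max(h - nh, 0), 0
    else:
        y0, x0 = max(h - nh, 0), max(w - nw, 0)
    y1, x1 = min(y0 + nh, h), min(x0 + nw, w)
    cy, cx = h // 2, w // 2
    if y0 <= cy < y1 and x0 <= cx < x1:
        # would occlude the target center: shrink the window away from it
        if side in (0, 1):
            y1 = min(y1, cy)
        else:
            y0 = max(y0, cy + 1)
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = patch[: y1 - y0, : x1 - x0]
    return out


def augment(
    crop: CellCrop,
    cfg: AugmentationConfig = AugmentationConfig(),
    rng: Optional[np.random.Generator] = None,
    distractors: Optional[Sequence[CellCrop]] = None,
) -> list[CellCrop]:
    """Produce ``cfg.factor`` independently jittered variants of a crop.

    Each disabled stage (empty mirror set, zero half-ranges, zero noise,
    neighbor off) is skipped entirely, so the identity configuration
    returns bit-identical copies.  Deterministic given a generator (or
    ``cfg.seed`` when none is passed).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    variants: list[CellCrop] = []
    for k in range(cfg.factor):
        px = crop.pixels.copy()
        if "horizontal" in cfg.mirror and rng.random() < 0.5:
            px = px[:, ::-1].copy()
        if "vertical" in cfg.mirror and rng.random() < 0.5:
            px = px[::-1].copy()
        if cfg.hue_delta or cfg.saturation_delta or cfg.exposure_delta:
            px = _jitter_hsv(px, cfg, rng)
        if cfg.noise_sigma:
            px = _tinted_noise(px, cfg, rng)
        if cfg.neighbor_placement and distractors:
            pool = [d for d in distractors if d.cell_class != crop.cell_class]
            if pool:
                px = _paste_neighbor(px, pool[rng.integers(len(pool))], cfg, rng)
        variants.append(CellCrop(pixels=px, source=crop.source, provenance=f"augmented:{k}"))
    return variants


def augmentation_census(
    annotation_counts: dict[str, int], factor: int = 4
) -> pd.DataFrame:
    """Expected corpus census: per class, augmented = factor x annotations.

    Pure count arithmetic (no pixels touched); the manifest of
    :func:`build_training_corpus` obeys the same law by construction.
    """
    rows = [
        {"cell_class": c, "augmented": factor * n, "annotations": n, "total": (1 + factor) * n}
        for c, n in annotation_counts.items()
    ]
    return pd.DataFrame(rows, columns=["cell_class", "augmented", "annotations", "total"])


@dataclass
class CorpusManifest:
    """Outcome of corpus construction: per-class counts plus the crops."""

    census: pd.DataFrame
    crops: list[CellCrop] = field(default_factory=list)


def build_training_corpus(
    annotations: AnnotationSet,
    images: dict[str, np.ndarray],
    cfg: AugmentationConfig = AugmentationConfig(),
    margin: float = 0.25,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    keep_crops: bool = True,
) -> CorpusManifest:
    """Extract every annotated crop, augment it, and tally the corpus.

    The manifest census satisfies ``total == (1 + factor) * annotations``
    per class.  All annotated images must be supplied.
    """
    rng = np.random.default_rng(cfg.seed)
    originals: dict[str, int] = {}
    augmented: dict[str, int] = {}
    crops: list[CellCrop] = []
    base_crops = []
    for rec in annotations:
        if rec.image_id not in images:
            raise KeyError(f"image {rec.image_id!r} not supplied to build_training_corpus")
        base_crops.append(extract_crop(images[rec.image_id], rec, margin=margin))
    for base in base_crops:
        cls = taxonomy.resolve(base.cell_class)
        originals[cls] = originals.get(cls, 0) + 1
        variants = augment(base, cfg, rng=rng, distractors=base_crops if cfg.neighbor_placement else None)
        augmented[cls] = augmented.get(cls, 0) + len(variants)
        if keep_crops:
            crops.append(base)
            crops.extend(variants)
    rows = [
        {
            "cell_class": c,
            "augmented": augmented.get(c, 0),
            "annotations": originals[c],
            "total": originals[c] + augmented.get(c, 0),
        }
        for c in sorted(originals, key=taxonomy.index_of)
    ]
    census = pd.DataFrame(rows, columns=["cell_class", "augmented", "annotations", "total"])
    return CorpusManifest(census=census, crops=crops)
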