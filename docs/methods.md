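# Methods

## Evaluation model

Detector output is scored against expert annotations per image, then
pooled corpus-wide (micro-averaging: the per-class rows are totals, not
averages of per-image rates).

**Matching.** Detections with confidence below 0.25 are discarded.
Survivors are processed in descending confidence (ties: input order) and
each greedily claims the still-unclaimed ground-truth box of highest
IOU ≥ 0.5; IOU ties break to the lowest ground-truth index. A claimed
pair with equal labels is a TP. A claimed pair with different labels is
an FP for the predicted class, *and* the ground-truth object — never
correctly found — is an FN for its own class; this is the reading under
which TP + FN equals the class's annotation count, which corpus-level
bookkeeping requires. It is isolated behind
`MatchConfig.wrong_class_consumes_gt` because the alternative (leave the
box available) is defensible. Unmatched survivors are FP; unclaimed
ground truth is FN. Boxes are continuous-pixel, origin top-left,
half-open, so edge-adjacent boxes have IOU exactly 0.

Greedy confidence-first matching is the de-facto standard of detection
evaluation (PASCAL VOC, COCO). It is *not* a maximum assignment: when a
spurious high-confidence box overlaps a ground-truth object harder than
its true detection does, greedy and optimal matching book different
TP/FP compositions. The test suite verifies equivalence with an
exhaustive assignment oracle on the family where the equivalence
genuinely holds — detections that are jittered copies of a subset of the
ground truth, without duplicate or spurious boxes — and treats the
general divergence as a known property of greedy matching, not a defect.

**True negatives.** A smear image has no background boxes, so TN for
class *c* is defined over its *negative cluster* — the set of
morphologically confusable classes recorded in the taxonomy (e.g.
basophil vs. {lymphocyte, neutrophil}): `TN(c) = Σ TP(n)` for *n* in the
cluster. Specificity is therefore a statement about the clinically
relevant discriminations, not about all other objects on the slide. The
clusters ship with the taxonomy and can be overridden (CLI
`--negatives`, or a custom `Taxonomy`).

**Metrics.** Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 = 2PR/(P+R), and Cohen's kappa in the 2×2 form
2(TP·TN − FP·FN)/[(TP+FP)(FP+TN) + (TP+FN)(TN+FN)], which is
algebraically the standard two-rater kappa of the contingency table
{TP, FP, FN, TN} (verified against scikit-learn on 10⁴ random count
vectors). A metric with a zero denominator is *missing* (`None`), never
0. Metrics are kept at full precision internally; CSV reports round to
2 decimals, half-up, the convention of printed clinical tables.

Recomputing the reference study's metric table from its printed
confusion counts under these exact formulas reproduces 133 of the 145
printed cells at 2 decimals (the acceptance script reports the match
rate). The 12 differing cells are rounding artifacts of the source
table itself: six specificity values ≥ 0.995 printed as 0.99, five F1
values that follow only from already-rounded precision/recall, and one
specificity cell consistent with no rounding rule. The package does not
imitate those conventions; it reports the exact arithmetic.

**Train/test split.** `stratified_split` assigns whole images (so no
object leaks across the split), targets a 20% test fraction by
annotation count, then moves train images into the test side until
every class reaches `min(min_test_per_class, class total)` test
annotations (default floor 100). Classes whose total is below
`min_test_per_class / test_fraction` cannot meet the floor without
distorting the split; they are named in a warning and topped up from
whatever exists. Deterministic under the seed.

## Interobserver agreement

Two annotators' labelings of the same images are compared by one-to-one
box matching, greedily by descending IOU at threshold 0.5; confidence
plays no role. Per reference-annotator class: `positive` counts
same-label matches, `negative` counts reference boxes unmatched *or*
matched with a different label (counting label disagreements as
negatives is what makes positive + negative equal the reference count),
and the coefficient is positive/(positive + negative). This is a raw
agreement ratio, deliberately not chance-corrected — no Fleiss or
Krippendorff — because the reference analysis defines exactly this
quantity.

## Augmentation

Each annotated crop yields `factor` variants (default 4, giving the
uniform ×5 corpus expansion that the reference census obeys in every
row; the factor is inferred from that census arithmetic, not from any
stated rule, and is configurable). Per variant, independently sampled:

- mirroring: each enabled axis flipped with probability 1/2;
- HSV jitter: hue shift ±10°, saturation gain ±10%, exposure (value
  channel) gain ±15% — conventional half-ranges, config-exposed since no
  published values exist;
- tinted Gaussian noise: one RGB tint per variant weighting a
  per-pixel N(0, σ) field, σ = 4 on the 8-bit scale;
- optional neighbor pasting: a distractor crop of a *different* class,
  rescaled so its diameter ratio to the target falls outside
  [0.8, 1.25] (clearly smaller or clearly larger — emulating the size
  comparison experts use among microcytic/macrocytic/normal red cells),
  pasted flush against a crop edge and never over the crop center.

Disabled stages are skipped entirely, so the identity configuration is
bit-exact; all arithmetic clips into [0, 255] before the uint8 cast, so
jitter cannot wrap around. The corpus manifest satisfies
`total = (1 + factor) × annotations` per class by construction.

Note the scheme enlarges every class uniformly; it increases variation
but preserves the census imbalance.

## Synthetic data

`generate_scene` places `cells_per_image` (default 80, the typical cell
count of one digitized smear field) axis-aligned ellipses with
class-dependent diameter and color, by rejection sampling under a
pairwise box-IOU cap (default 0.05) with 50 retries per cell; on
failure it returns fewer cells with a warning. Annotations are the
exact ellipse extents. `generate_layout` runs the identical sampling
without rasterizing, for large simulations. Default class frequencies
are proportional to the reference census (three orders of magnitude
between microcytic RBCs and basophils); per-class size/color defaults
are smear-like stand-ins (no per-class appearance statistics are
published) and matter only in that classes differ.

`simulate_detector` turns ground truth into detections: each box is
found with per-class probability `tpr`, found boxes get Gaussian corner
jitter, labels are drawn from a row-stochastic confusion matrix
(identity by default), confidences are uniform on [0.6, 1] for correct
labels and [0.3, 0.7] for incorrect ones, and spurious boxes arrive
Poisson per image, uniformly placed, sized by resampling truth boxes.
With identity confusion and zero jitter the measured sensitivity of
class *c* is an exact binomial estimate of `tpr[c]` — the basis of the
parameter-recovery acceptance check, which programs the reference
sensitivity column as the rates, simulates ~156,000 cells (≥ 5,000 per
class over ~1,950 layout-only scenes, a size chosen to make 3-standard-
error bands decisive), and recovers every rate within 3 binomial SE.

What the generator does **not** emulate: cell texture and internal
structure (cells are flat ellipses), staining gradients, focus and
illumination fields, touching/overlapping cell clumps, and annotator
subjectivity. Tests passing on this material validate the counting,
matching, and metric machinery — not the visual difficulty of real
smears.

## Baseline detector

A deliberately simple harness so the pipeline composes end-to-end:
Otsu threshold on the per-pixel distance from the border-median
background color, connected components (minimum area 30 px²), tight
boxes, then nearest-centroid classification on (mean RGB, area,
equivalent diameter, eccentricity) standardized to unit variance, with
confidence softmax(−distance) ∈ (0, 1] and exact-tie break to the
lexicographically first class. On synthetic classes separated by ≥ 4
color SD it reaches per-class sensitivity ≥ 0.95 (smoke test); it is
not expected to perform on real imagery.

## Conventions and degenerate inputs

- Class names resolve case- and punctuation-insensitively with explicit
  aliases for spelling variants ("Neutrophilband", "Artifacts",
  "Platelet"); the canonical order fixes the YOLO-dialect indices.
- Boxes extending past image bounds are clipped on load, with a warning.
- Empty annotation files are valid (empty set); malformed lines,
  unknown class indices, and out-of-range normalized coordinates are
  hard errors naming file and line.
- YOLO-dialect coordinates are written at 6 decimals; round-trip error
  is far below the 0.5 px quantization bound asserted in tests.
- Detections on images absent from the ground-truth registry are scored
  against an empty image (all FP); annotation sets with *disjoint*
  image sets are an error in interobserver comparison, while partial
  overlap compares the union.

## Problem sizes

The default test suite simulates a few hundred scenes at 640×480 with
25–80 cells; the acceptance script's largest computation is the
recovery simulation above (~1 minute total on one CPU). All fixtures
are generated programmatically; the only shipped data are the plain
reference tables.
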