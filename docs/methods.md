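# Methods

## The evaluation model

Ground truth for FTU segmentation is a set of simple polygons (one per
FTU, pixel coordinates, plus anatomical-region polygons such as kidney
cortex); predictions are one binary mask per WSI, exchanged as
run-length encodings. Object-level evaluation therefore needs three
stages, in order:

1. **Instance separation** — the prediction mask is split into single
   FTUs, because adjacent FTUs merge into one connected component and
   would otherwise be counted as one object.
2. **Matching** — each ground-truth instance is paired with at most one
   predicted instance by per-object Dice; Dice ≥ 0.5 ⇒ true positive,
   unmatched predictions ⇒ false positives, unmatched ground truths ⇒
   false negatives.
3. **Aggregation** — precision, recall, F-measure, accuracy, MCC,
   Jaccard, Hausdorff distance, pixel Dice per WSI, and the dataset
   mean in which a WSI with no submitted prediction scores zero.

The matching rule is stated in the literature only as "Dice per FTU
with a 0.5 threshold", without naming a pairing algorithm. We use
greedy one-to-one assignment in descending pairwise Dice with ties
broken by ascending (gt id, pred id). This is deterministic and is the
standard choice for object-level F-scores; an optimal (Hungarian)
assignment differs only in contrived tie configurations, which is why
the simpler rule was chosen. Pairs whose Dice falls below the threshold
are never accepted, so their members surface as FN + FP, and raising
the threshold can only reduce the TP count (a tested invariant).

Degenerate conventions, applied uniformly: Dice and Jaccard of two
empty sets are 1; precision with zero predictions is 1 if there is also
no ground truth and 0 otherwise (symmetrically for recall); MCC is 0
whenever a denominator factor vanishes; the mean instance Dice of an
empty match table is 1.

Two Dice flavors are deliberately kept distinct: *pixel Dice* of the
union masks (competition-leaderboard semantics) and *mean instance
Dice* over TP ∪ FP ∪ FN rows where an absent pairing contributes 0
(supplementary-table semantics). Reported tables carry both.

## Mask representations

* **Coordinates**: (x = column, y = row), y down, 0-based; pixel (r, c)
  covers [c, c+1] × [r, r+1] with center (c+0.5, r+0.5).
* **RLE dialect**: 1-based column-major pixel numbering with maximal
  (start, length) runs — the dialect of competition submission files.
  The ordering is not uniquely fixed by published descriptions, so the
  platform default is assumed; encode/decode are exact inverses and
  are property-tested as such.
* **Rasterization**: a pixel is set iff its center is inside the
  polygon (even-odd; interior rings subtracted); a center exactly on
  the boundary counts as inside. This rule is deterministic, monotone
  under polygon containment, and resolution-consistent.
* **Vectorization**: each label's polygon is the exact boundary of the
  union of its pixel squares (row runs merged into rectangles, then
  unioned). Rasterizing it back reproduces the pixel set exactly for
  4-connected instances — stronger than the Dice ≥ 0.99 contract —
  because no pixel center can sit on the (integer-coordinate) boundary.
  Labels that decompose into several parts under diagonal-only
  connectivity keep their largest part.
* **Label TIFFs** are uint16: a single WSI can carry thousands of
  instances, beyond uint8.

## Watershed separation

Foreground → Euclidean distance transform → local maxima as markers →
watershed of the negative distance map restricted to the foreground.
Determinism is enforced at the two places scikit-image leaves open:

* a connected plateau of equal distance values yields exactly one
  candidate marker, at its first row-major pixel;
* candidates are accepted greedily in (value desc, row, col) order
  subject to pairwise Euclidean distance ≥ `min_distance_px`.

Final labels are renumbered 1..K by the scan order of each region's
first pixel, so identical inputs give identical labelings. The
foreground pixel set is preserved exactly (every foreground pixel is
assigned to exactly one marker). `min_distance_px` is the only tunable:
it must exceed the typical object radius-to-split-spacing; presets of
30 px (kidney), 60 px (colon) and 80 px (antibody-stain data) are
exposed, all in pixels at the native 0.5 µm/px resolution. Watershed is
known to under-segment complex non-convex structures; no quantitative
failure criterion exists for that regime and none is tested.

Manual split lines are the curation alternative: 1-px Bresenham
polylines cleared from the mask before component labeling. Clearing
removes ~1 px of area along the cut, which is the same information loss
a manual cut introduces; split lines never add foreground.

## FTU density

Per WSI: `density = n_ftu / cortex_area_mm2`, with `n_ftu` the count of
FTU-category polygons (no size filtering — none is applied in practice)
and cortex area the **sum** of the individual cortex polygon areas
(shoelace, converted px² → µm² → mm²). The sum, not the union, is used
because that is how published density tables were computed; overlapping
cortex polygons would double-count, so a `cortex_union=True` option
exists but is off by default. Printed-style outputs round half away
from zero. Density is invariant under consistent rescaling of
coordinates and pixel size (tested).

## Synthetic scenes

The generator emulates the *geometry* of FTU annotation data, not its
stain appearance: flat-shaded instances, no PAS/H&E texture, no
imaging noise, no anatomical context beyond one rectangular cortex.
Passing tests therefore demonstrate the correctness of the evaluation
arithmetic and the separation/matching logic on realistic geometry —
they do not certify segmentation quality on real stained tissue.

* **Glomeruli**: equivalent diameter uniform in 100–350 µm, ellipse
  axis ratio in [0.8, 1.0] ("roughly spherical"); semi-axes scaled so
  the equivalent diameter equals the drawn value exactly. Zero-mean
  radial harmonics (orders 2–4, amplitude ≤ 3%) de-circularize the
  outline while perturbing the enclosed area only at second order, so
  diameter checks remain analytic to within one pixel of rasterization
  slack.
* **Crypts**: luminal diameter normal 73.5 ± 3.4 µm (truncated at
  ±3 σ), axis ratio 0.17 (tube length ≈ 433 µm).
* **Canvas**: default 2048×2048 px at 4 µm/px — a downscaled WSI where
  a glomerulus spans 25–88 px — so suites run in seconds; the native
  0.5 µm/px is supported by passing that pixel size. Tests and the
  acceptance script use 512² scenes (4–8 instances) for the
  perturbation oracle and 1024² scenes for cohorts; these sizes keep
  per-scene count quantization and packing failure probability
  negligible while exercising identical code paths.
* **Packing**: rejection sampling with pairwise polygon clearance
  ≥ `min_gap_px` (default 4 px), 300 attempts per instance, then a
  capacity error. The label mask is the rasterization of the placed
  polygons, so mask and annotations are mutually consistent by
  construction.
* **Perturbations**: `drop_n` omitted instances, `add_n` spurious discs
  (8–16 px radius) placed with clearance from all ground truth plus the
  jitter halo, `merge_pairs` nearest kept pairs bridged by a ~3 px
  line, and per-instance dilation/erosion by `jitter_px`. With no
  merges and jitter small enough that every kept instance keeps
  Dice ≥ 0.5 against its ground truth, the expected counts
  (tp = n − drop, fn = drop, fp = add) are exact; with merges they hold
  after watershed separation restores the bridged pairs.
* **Cohorts**: per-donor planted density uniform in 3–6 glomeruli/mm²
  (the physiological cortical range), alternating sex, age 25–70, BMI
  ≈ N(27.5, 4); each scene's instance count is the planted density
  times the exact cortex polygon area, rounded — so density recovery
  error is pure count quantization, below 2% at the default scene size.
* **Randomness**: one seed, split into counter-derived child streams
  per sub-task (shape, placement, perturbation selection/addition/
  jitter), so enabling a perturbation never shifts placement draws.

## Numerical and degenerate-input choices

* Areas via shapely's shoelace; orientation-independent.
* Half-away-from-zero rounding for printed-style values (Python's
  bankers' rounding would print 20,124 where tables print 20,125).
* Empty masks: labeling and watershed return empty labelings; RLE of an
  empty mask is an empty run list; vectorizing an empty mask returns [].
* Matching uses exact integer pixel counts; Dice ties in the greedy
  order are broken by ids, making match tables reproducible.
* Seeds are plain Python ints < 2³¹; all generators are
  `numpy.random.default_rng` seeded via `SeedSequence`.

## Known limitations

* The evaluator assumes ground-truth FTU polygons are mutually
  disjoint (true of curated FTU data); overlapping GT polygons would
  rasterize last-writer-wins.
* Greedy matching is not globally optimal under exotic Dice ties.
* The watershed cannot split structures whose distance-map maxima fall
  closer than `min_distance_px`, and over-splits strongly non-convex
  single objects if `min_distance_px` is chosen too small.
* The generator does not model stain texture, imaging artifacts,
  annotation ambiguity, or non-convex FTU shapes beyond mild radial
  noise; real-data performance claims are out of scope.
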