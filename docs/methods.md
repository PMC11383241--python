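# Methods

## Scope and data model

The toolkit covers the data engineering around a wildflower object detector:
annotation handling, resolution-preserving tiling, balanced subset
selection, count-unit conversion, and evaluation of detections from any
source. It does not train detectors.

All geometry uses 0-based, half-open pixel boxes `[xmin,xmax)×[ymin,ymax)`,
so areas and cut-crossing tests are exact integer arithmetic. On-disk
Pascal VOC XML is read and written as 1-based inclusive (`xmin_int =
xmin_voc − 1`, `xmax_int = xmax_voc`), the common interpretation of the
format; the conversion lives only in `voc.read_voc`/`voc.write_voc`.
Zero-area boxes are rejected at read time rather than silently dropped, so
invalid annotations surface immediately with the offending file and object.

Image ids follow `YYYYMMDD-HHMM-<landscape>` with the landscape drawn from
the five survey types. The source material fixes only "date and time
followed by the landscape type"; the separator and minute precision are
this package's convention.

## Floral count units

Counting wildflowers requires a species-specific countable unit: for most
species the botanical inflorescence, for some a pragmatic substitute (single
flowers where the inflorescence cannot be outlined from above, the outer
inflorescence of nested structures where it is compact). The registry
stores, per species, the FCU type and two positive factors: mean flowers
per FCU (`f ≥ 1`) and mean FCUs per plant (`g > 0`). Conversions are plain
linear maps — `flowers = N·f`, `plants = N/g` — and return real values;
because the factors are population means, rounding is presentation, not
arithmetic. Aggregate labels for field-indistinguishable species (e.g.
`Buttercup*`) are ordinary registry rows. The shipped
`example_fcu_registry.csv` carries illustrative factor values for
demonstration; real studies supply their own table. Whether published
factors are arithmetic means or range midpoints is immaterial here: they
are treated as plain multipliers.

## Smart tiling

Survey images (6720×4480 px) exceed typical detector input bounds
(`max_input = 1333` px per axis). Downscaling destroys the detail needed to
separate look-alike species, so images are tiled:

- **Grid size.** `n = ⌈dim / (max_input·(1+margin))⌉` tiles per axis — the
  fewest tiles whose uniform size respects the enlarged bound. With
  `margin = 0.2` the survey geometry gives 5×3 = 15 tiles.
- **Cut placement.** Starting from uniform cuts `c_j = round(j·dim/n)`,
  each cut may move within `±margin·(dim/n)`. A cut at `p` crosses a box
  iff `lo < p < hi` (half-open, so a cut flush with a box edge does not cut
  it). Per axis, the placement minimizing the total number of line–box
  crossings is found by dynamic programming over the integer candidate
  positions, subject to cuts being strictly increasing and **no tile side
  exceeding `max_input·(1+margin)`**. The size cap is needed because two
  neighbouring cuts moved to opposite band edges would otherwise create a
  tile of `(1+2·margin)·dim/n` px, past the bound the grid size was chosen
  for; the constraint couples neighbouring cuts, which is why a DP replaces
  a fully independent per-line search. When the constraint is slack — the
  typical case — the DP reduces to per-line minimization, which is exact
  for `margin < 0.5` because neighbouring bands cannot overlap. Ties are
  broken toward the uniform position, then toward the smaller coordinate,
  so an annotation-free image tiles uniformly.
- **Axes are independent**: a vertical cut's position never changes which
  boxes a horizontal cut crosses, so the two axes are optimized separately.
- **Fragment reassignment.** After cutting, an annotation intersecting
  several tiles is kept exactly once, in the tile holding the largest
  fragment of its box (ties to the smaller (row, col)), clipped to the tile
  in tile-local coordinates. This conserves the total annotation count —
  the property the whole counting pipeline rests on — and is kept even when
  the largest fragment is under half the original box (possible only with
  cuts on both axes): conservation is prioritized over the at-least-half
  visibility rule used for image borders. Fragments are clipped, never
  extended, since an extended box would leave the tile extent.
- **Inference tiling** uses the uniform grid unchanged: unseen images carry
  no annotations to protect. No cross-tile stitching or NMS is attempted;
  detections are evaluated per tile.

## Balanced subset selection

Field data is long-tailed; training on it as-is biases the detector toward
abundant species. The selection builds train/eval/test splits holding an
exact, preset number of annotations per species per split (default
250/50/50). Exactness is structural, not aspirational:

1. Tiles are shuffled with a seeded RNG and assigned greedily: each tile
   goes to the split with the greatest relative unmet need (unmet
   annotations over total quota) among the splits where it fits without
   pushing any species above its quota; a tile fitting nowhere stays
   unused. Overshoot is therefore impossible by construction.
2. If some species misses its quota, the pass restarts with a new derived
   shuffle, up to `max_attempts = 50` times.
3. Species still unmet after the attempt budget are dropped and the
   attempt loop reruns without them (repeat until stable). A dropped
   species' annotations inside selected tiles are stripped from the label
   set — downstream they are background, mirroring how a detector trained
   without a species treats its look-alikes.

The procedure is deterministic given `(tiles, quota, seed, max_attempts)`.
No constraint ties tiles of one parent image to one split: tiles from the
same photograph may serve different splits, which maximizes usable tiles.
The greedy-with-restarts heuristic is not complete — a feasible instance
can in principle be missed — but on small co-occurrence instances it is
cross-checked against exhaustive enumeration, and on instances where
single-species tiles suffice it never drops a species. `max_attempts = 50`
is this package's default; nothing in the source material fixes a number.

## Evaluation

- **Matching** is greedy by descending IoU over candidate pairs with
  `IoU > threshold` (strictly greater; default 0.5), one-to-one: the
  highest-IoU proposal on an annotation is the TP and duplicates are FPs.
  This follows the stated duplicate rule rather than the score-ranked
  greedy of some toolkits; the two differ only on overlapping proposals
  with inverted score/IoU order, and the matcher is cross-checked against a
  brute-force maximum-IoU-first oracle.
- **AP** per class: detections of the class are matched label-aware per
  image, pooled, ranked by descending confidence, and accumulated into
  (recall, precision) pairs; AP is the all-point interpolated area
  `Σ (r_i − r_{i−1}) · max_{j≥i} p_j`. Rank-based accumulation is used
  rather than re-matching at every threshold; with matching stable across
  thresholds the two coincide, and the tests verify agreement with an
  exhaustive threshold-sweep oracle to 1e−12. 11-point interpolation is
  available as an option for comparison. **mAP** averages classes present
  in the ground truth; classes with zero annotations have undefined recall
  and are excluded, matching standard practice. AP uses all detections
  regardless of score — the PR curve itself sweeps the confidence axis.
- **Confusion matrix**: detections with score strictly above the confidence
  threshold (default 0.5) are matched label-agnostically; matched pairs
  increment cell (true species, predicted species), unmatched annotations
  the background column, unmatched detections the background row.
  Label-agnostic matching is what lets species-for-species confusions
  appear off-diagonal. Each non-background row sums to that species'
  annotation count. **Percent correct** is 100 × diagonal sum / total
  annotations, background row excluded from the denominator; chance level
  under uniform guessing over K classes is 100/K (2.0% at K = 49).
- **Early stopping**: stop training when the current epoch's metric is
  strictly below the mean of the previous five epochs; with five or fewer
  epochs of history, never stop.

## Synthetic scenes

The generator emulates the statistical structure the pipeline depends on,
not the optics of real vegetation: multi-species top-view scenes with
tight, possibly overlapping boxes; long-tailed abundance (deterministic
rounded-Zipf, per-species Poisson, or fixed counts); background clutter;
and species-specific FCU morphologies drawn as flat-colour connected
silhouettes (disc, ringed disc, chained discs, radial clusters). Every
annotation box is the exact pixel bounding box of its silhouette, so box
arithmetic downstream can be checked to the pixel. Each species has a
unique saturated key colour distinct from the green/brown/grey background
palette.

The default test geometry is a 1/10-scale mirror of the survey setup
(672×448 px, `max_input` 133, margin 0.2), which reproduces the 5×3 mosaic
structure at a fraction of the cost; tests use smaller scenes still where
geometry allows. The Zipf option assigns `round(n_total · k^−a / H)`
instances to the rank-k species — deterministic per scene so that counts
are monotone in rank by construction; Poisson is the stochastic model.

The oracle detector reads the generator's ground truth (not the raster) and
corrupts it with independent per-annotation error modes: miss probability,
uniform integer box jitter (clamped to the image, validity preserved),
row-stochastic label confusion, Poisson-count spurious detections, and
uniform score ranges for TPs and FPs. Zero corruption returns the
annotations verbatim at score 1.0, giving the end-to-end identity the
pipeline tests rest on: generate → tile → balance → detect → evaluate
yields exact quotas and mAP 1.0. A colour-threshold detector (exact
key-colour match + connected components) exercises the raster path; on
non-overlapping scenes it reproduces the ground truth exactly.

What passing these tests does *not* show: robustness to photographic
nuisance (blur, lighting, occlusion by foliage, withered or budding
stages), to annotation subjectivity, or to detector-specific failure modes;
those require real imagery and a real detector.

## Numerical and degenerate-input choices

- Box coordinates, cut positions and candidate searches are integer;
  the only floating arithmetic is in rates, scores, AP and conversions.
- `mm_per_px` defaults to 0.15 (≈1 m across ~6720 px) for the minimum-size
  filter and is always overridable; the size rule uses the longer box side
  and removes boxes at or below the threshold.
- Empty inputs degrade, not crash: an empty dataset summarizes to zeros
  with null mean/median; an empty tile set with positive quotas drops all
  species; evaluation without ground truth for a class raises, since recall
  is undefined.
- Seeds: every stochastic component takes an explicit seed; derived seeds
  are drawn below 2³¹. Identical inputs and seeds give bit-identical
  outputs, including rasters.

## Problem sizes used in the checks

The automated checks run at desk scale by design: scenes of 224×160 to
672×448 px, 8–50 images per dataset, exhaustive search oracles on axes of
a few hundred pixels, and the full-quota (250/50/50) selection on 4,000
synthetic single-annotation tiles. The full-scale survey numbers
(6720×4480, 15-tile mosaic) enter through the geometry checks, which are
pure arithmetic.

## Known limitations

- Tile-border artifacts are inherited, not solved: small cut-off fragments
  whose annotation went to a neighbouring tile can produce spurious
  detections there; no cross-tile merging is attempted.
- The balanced-selection heuristic trades completeness for speed; a
  retained-species count on real data depends on the data and the seed.
- The AP construction assumes matching is stable under the confidence
  sweep; pathological instances where a lower-scored detection displaces a
  higher-scored one at some threshold can differ from a full re-matching
  sweep.
- Converted flower/plant counts inherit all the variance of the registry's
  mean factors; no uncertainty is propagated.
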