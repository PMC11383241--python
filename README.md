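# floracount

A data-centric toolkit for automated wildflower monitoring from annotated
top-view survey photographs ("relevées", ~1 m² plots imaged at ~30 Mpx).
It is aimed at ecologists and computer-vision practitioners who train and
evaluate object detectors that **classify and count** flowering plants, and
who need the data engineering around the detector to be exact and
reproducible:

- **`floracount.voc`** — Pascal VOC annotation I/O with a strict
  `YYYYMMDD-HHMM-<landscape>` naming convention (five landscape types:
  roadside, urban green, cropland, grassland, marsh), the ≥10 mm
  minimum-size annotation rule, and dataset summary statistics.
- **`floracount.fcu`** — *floral count units* (FCUs): the species-specific
  countable entity, usually the botanical inflorescence (capitulum, spike,
  umbel, …). A registry maps each species to two conversion factors — mean
  flowers per FCU and mean FCUs per plant — so detector counts convert
  linearly to flower counts `F(s) = N(s)·f(s)` and plant counts
  `P(s) = N(s)/g(s)`, plus richness/abundance summaries.
- **`floracount.tiling`** — *smart tiling*: cut a large annotated image into
  `⌈dim / (M(1+m))⌉` tiles per axis (input bound `M = 1333` px, margin
  `m = 0.2`; a 6720×4480 image gives a 5×3 mosaic of 15 tiles), moving each
  cut line inside its ±`m·(dim/n)` band to minimize the number of annotation
  boxes it crosses (an exact per-axis dynamic program). A cut annotation is
  kept once, in the tile holding its largest fragment.
- **`floracount.balance`** — exact-quota stratified subset selection: pick
  tiles so every retained species has exactly `(250, 50, 50)`
  train/eval/test annotations (parameterized); a randomized greedy heuristic
  with restarts drops a species only when no solution is found.
- **`floracount.evaluation`** — detection metrics: IoU = |b₁∩b₂|/|b₁∪b₂|,
  greedy highest-IoU-first TP/FP matching (duplicates are FPs), per-class
  AP as the all-point-interpolated area under the precision–recall curve,
  mAP as the unweighted class mean, a background-augmented confusion matrix
  (background row = spurious detections, background column = misses),
  percent-correct, and the early-stopping rule (stop when the current epoch
  metric falls below the mean of the last five).
- **`floracount.synth`** — seeded synthetic scenes with morphology-shaped
  FCUs (solitary, capitulum, spike, umbel, corymb), tight boxes, long-tailed
  abundance models, and a corruptible oracle detector (misses, jitter,
  label confusion, spurious hits) so the full pipeline is testable without
  any real imagery.

## Worked example

```python
import json
from floracount import pipeline, balance

cfg = pipeline.PipelineConfig(
    n_species=3, n_images=12, scene_width=336, scene_height=224,
    abundance_mean=4.0, quota=balance.Quota(10, 3, 3), seed=5,
)
report = pipeline.run_pipeline(cfg, "out/")
```

This synthesizes 12 annotated scenes, tiles them (336×224 at max input 133,
margin 0.2 → 3×2 mosaic each), selects an exact 10/3/3 split, runs the
zero-corruption oracle detector on the test split and evaluates it. The
report it prints (abridged):

```json
{
  "dataset": {"n_images": 12, "n_annotations": 134, "n_species": 3,
              "annotations_per_image": {"min": 7, "max": 16, "median": 11.0,
                                        "mean": 11.1667}},
  "tiling": {"n_tiles": 72},
  "split": {"all_exact": true,
            "retained_species": ["species_00", "species_01", "species_02"],
            "dropped_species": [],
            "totals": {"train": 30, "eval": 9, "test": 9}},
  "evaluation": {"mAP": 1.0, "percent_correct": 100.0},
  "counts": {"fcu_counts": {"species_00": 3, "species_01": 3, "species_02": 3},
             "richness": 3, "abundance": 9.0}
}
```

`all_exact: true` means every retained species hit its quota exactly in
every split (here 3 species × 10 training annotations = 30). A perfect
detector yields mAP 1.0 and a purely diagonal confusion matrix; with the
score threshold at 0.5 the detected FCU counts (3 per species on the test
tiles) feed richness (3 species) and abundance (9 FCUs).

The same stages are available as a CLI:

```bash
floracount synth --n 10 --n-species 4 --seed 7 raw/
floracount tile --max-input 1333 --margin 0.2 raw/ tiles/
floracount balance --train 250 --eval 50 --test 50 --seed 1 tiles/ splits/
floracount eval --iou 0.5 --score 0.5 tiles/ detections.csv
floracount convert --to flower counts.json
floracount run --seed 7 out/
```

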