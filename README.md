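# orchardtrack

Tools for monitoring individual fruit growth from fixed-point canopy
imagery:

* **Synthetic scene generation** (`orchardtrack.synthesis`) — cut-and-paste
  compositing of fruit/leaf sprites onto a background plate with randomized
  size, aspect, brightness, rotation, leaf shadows, and fruit-then-leaf
  layering. Every fruit gets an *amodal* mask (its full extent, including
  occluded pixels) and a visible mask, plus VIA- and COCO-style polygon
  annotations for detector training. Sprites can be supplied as image
  assets or drawn procedurally by the fixture generator.
* **Detection oracle** (`orchardtrack.detection`) — turns ground-truth
  masks into detection records (contour, bbox, centroid, equivalent-circle
  radius) with optional corruption (dropouts, jitter, spurious blobs), so
  the downstream pipeline can be exercised without a trained segmentation
  model. Any callable `(image, date) -> [Detection]` plugs in as a real
  detector adapter.
* **Multi-day tracker** (`orchardtrack.tracker`) — identifies the same
  fruit across days using three gates against a track's last observation:
  center distance `< 40 + 2T` px, radius change `<= 10 + 0.1T` %, and
  Hu-moment contour dissimilarity `<= 0.05`, where `T` counts consecutive
  non-detect days and linearly relaxes the first two gates.
* **Growth model** (`orchardtrack.growth`) — fits `Y = a / (1 + b e^{cX})`
  to per-fruit radius series by bounded nonlinear least squares (`X` =
  days since April 1), predicts the harvest radius as the curve's
  convergence value `a`, produces per-day real-time predictions from
  growing prefixes, and calibrates relative radii to physical units.
* **Evaluation** (`orchardtrack.metrics`) — precision / recall / IoU with
  one-to-one greedy matching, MAPE (as a fraction), Pearson r and
  regression R², and per-day filtered-vs-averaged IoU.
* **Annotation I/O** (`orchardtrack.annotation`) — VIA 2.x polygon JSON
  read/write, exact polygon↔mask conversion (pixel-center, even-odd
  rule), and tiling of full-resolution images into 1088×1088 sections
  (the default layout emits 11 tiles per 5184×3456 source).

## CLI

```sh
orchardtrack generate --config params.yml --n 3000 --seed 42 --out data/
orchardtrack detect --masks m1.png --masks m2.png --date 2016-07-01 --out dets.jsonl
orchardtrack track --detections dets.jsonl --out tracks/
orchardtrack fit --series tracks/track_0000_radius.csv --min-points 5 --out fits/
orchardtrack evaluate --pred pred_masks/ --truth truth_masks/ --iou-threshold 0.5
orchardtrack demo --seed 7 --out run1/
```

`demo` runs the whole chain on a self-generated multi-day scene whose
fruit sizes follow known logistic schedules, then reports identity
accuracy, radius MAPE, and asymptote-recovery error against that
schedule (`run1/report.json`).

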