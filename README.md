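# ctrkit

A toolkit for studying automatic cardiothoracic-ratio (CTR) measurement.
It provides every stage of a desk-scale validation study:

* **`ctrkit.phantom`** — synthetic chest-radiograph-like phantoms (ellipse
  composites with ground-truth lung/heart masks and a known, designed CTR),
  population sampling with configurable per-group CTR distributions
  (defaults: normal 0.454 ± 0.043, cardiomegaly 0.569 ± 0.047), and
  simulators for human observers (relative bias + noise) and an AI-only
  reader (heavy-tailed error mixture with group-dependent failure rates).
* **`ctrkit.segmentation`** — a self-contained numpy U-Net
  (encoder/decoder with skip concatenation; `reduced` preset trains on a
  CPU in minutes, `vgg16_like` preset mirrors the VGG-16 block structure),
  trained with cross-entropy + soft-Dice and Adam.
* **`ctrkit.ctr`** — CTR extraction from mask pairs via horizontal extreme
  points, with failure detection (empty masks, heart diameter < 3 mm,
  heart span exceeding the thoracic span).
* **`ctrkit.workflow`** — study-design emulation: two observers with 2+1
  replication, the AI-assisted accept/adjust loop with a ±1.8% acceptance
  window, excellent/good/poor outcome grading, and per-method consensus
  values.
* **`ctrkit.stats`** — Bland–Altman agreement with coefficient of
  variation, linear correlation with R² banding, paired t-tests, and
  cardiomegaly classification at standard / Youden-optimum /
  max-sensitivity cutoffs.

## Command line

```bash
# render a phantom population (PNGs + manifest CSV)
ctrkit generate --n-normal 50 --n-cardio 25 --seed 1 --outdir pop/

# measure CTR from ground-truth masks
ctrkit measure --manifest pop/manifest.csv --source truth --out ref.csv

# train the reduced segmentation network and predict
ctrkit segment train --manifest pop/manifest.csv --checkpoint model.npz --epochs 10
ctrkit segment predict --checkpoint model.npz --image pop/N00000_image.png --outdir pred/

# simulate the measurement workflows (bundled configs: smoke, paper_like)
ctrkit simulate --config smoke --outdir sim/

# agreement/correlation between two methods of a measurement table
ctrkit stats --measurements sim/measurements.csv --compare manual:ai_only --out cmp.csv

# the full pipeline: simulate, compare, classify, plot, log
ctrkit replicate-study --config paper_like --outdir report/
```

`replicate-study` writes `measurements.csv`, `decisions.csv`,
`grading.csv`, `comparisons.csv`, `classification.csv`, Bland–Altman and
scatter plots, a `run_log.json`, and an `outputs_manifest.csv` declaring
every file. Reruns with the same config are byte-identical for all CSVs.
Pass `--with-network` to also train the reduced segmentation network and
record held-out Dice in the run log.

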