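# fuzzyseg

Fuzzy-clustering segmentation and fuzzy-SVM classification toolkit for
mammogram-like grayscale images, exercised end to end on synthetic phantom
images (bright lesion on textured tissue over a dark background, with
benign = smooth vs malignant = spiculated lesion shapes).

## What's inside

| Module | Contents |
| --- | --- |
| `fuzzyseg.clustering` | FCM, PFCM (possibilistic typicalities), IFCM (Sugeno hesitation boost), the hybrid IPFCM, Otsu thresholding, hard-label extraction, permutation-invariant segmentation accuracy |
| `fuzzyseg.preprocess` | intensity normalization, Gaussian/median filtering, salt-and-pepper / Gaussian noise injection, PGM/PNG I/O |
| `fuzzyseg.features` | 32-ray radial profile, shape descriptors (area, perimeter, circularity, shape factor, NRL statistics, NCPS, boundary gradient) and gray-level-histogram texture moments — 16 features per ROI |
| `fuzzyseg.fsvm` | fuzzy-weighted SVM: Gaussian kernel, class-center fuzzy weights, SMO-style dual solver with per-sample box constraints, JSON model serialization |
| `fuzzyseg.metrics` | confusion-matrix metrics (sensitivity, specificity, accuracy, PPV, NPV, MCC) and ROC/AUC |
| `fuzzyseg.phantom` | seeded phantom generator with three-class ground truth and a nested noise-sweep suite |
| `fuzzyseg.pipeline` | experiment drivers: per-image segmentation, noise-sweep accuracy tables, feature extraction, stratified splits, full pipeline |
| `fuzzyseg.cli` | `fuzzyseg` command-line interface |

## CLI

```bash
# generate a phantom dataset (images + manifest.csv)
fuzzyseg simulate --n-benign 10 --n-malignant 10 --seed 1 --out data/

# segment it and score against the ground truth
fuzzyseg segment --data data/ --method ipfcm --out seg/

# extract the 16-feature table, train and evaluate a fuzzy SVM
fuzzyseg features --data data/ --method ipfcm --out features.csv
fuzzyseg train --features features.csv --sigma 4.0 --out model.json
fuzzyseg evaluate --features features.csv --model model.json --out metrics.json

# or run everything in one step
fuzzyseg pipeline --n-benign 20 --n-malignant 20 --method ipfcm --seed 1 --out run/
```

Options can also come from a JSON config file (`--config`); CLI flags win.
Every run directory receives a `config.json` echo for reproducibility.

## Notes

- All stochastic steps (center initialization, phantom synthesis, noise
  injection, train/test splits) take explicit seeds; identical seeds give
  bitwise-identical results.
- `fit_ifcm(sugeno_lambda=0)` reproduces `fit_fcm` exactly, and
  `fit_ipfcm(sugeno_lambda=0)` reproduces `fit_pfcm` exactly (same seed).
- Labels follow the convention malignant = +1, benign = −1.
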