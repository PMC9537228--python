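# gaitstream

Two-stream convolutional classification of walking motions from 3D skeleton
time series. The package classifies single walking cycles of a 20-joint
skeleton into four classes (healthy, joint problem, muscle weakness,
neurological defect) by combining two feature streams:

* a **joint-position stream**: the raw `(T, J, 3)` coordinate tensor,
  convolved with a 3-frame × 1-joint kernel;
* a **relative-displacement stream**: the `(T, J(J−1), 3)` tensor of all
  ordered joint-pair coordinate differences, convolved with a
  3-frame × (J−1) kernel at spatial stride J−1 so each filter placement
  covers exactly one joint's correlation block.

The stream outputs (identical `(T−2, J, C)` shapes by construction) are
concatenated along the channel axis and classified by a small convolutional
head (two convs → adaptive max pooling → fully connected → softmax), with
ablation variants (`no_cnn`, `sin_cnn`, `no_maxp`) and single-stream
baselines (`streams="jp"` / `"rjdp"`). Small, imbalanced datasets are
balanced with mixup augmentation (`λ·X_a + (1−λ)·X_b`, anchor label kept),
re-run inside each training fold of a stratified 5-fold cross-validation so
synthetic samples never reach a test fold. A sigmoid column gate on each
stream's input provides attention-based joint / joint-pair importance
scores.

Everything runs on plain numpy (the network, including backprop and Adam,
is implemented in `gaitstream/nn.py` — no GPU or deep-learning framework
required) and is exercised end-to-end on a bundled synthetic gait
simulator, so no data download is needed.

## CLI

```bash
# synthesize a labelled cohort (one motion CSV per sample + manifest)
gaitstream simulate --counts healthy=10,joint_problem=4,muscle_weakness=18,neurological_defect=13 \
    --seed 7 --out-dir data/raw

# normalize: fixed frame count, common start position and heading
gaitstream preprocess --manifest data/raw/manifest.csv --t-target 100 --out-dir data/norm

# store both stream tensors per sample (HDF5)
gaitstream featurize --manifest data/norm/manifest.csv --out features.h5

# mixup-balance a training manifest
gaitstream augment --manifest data/norm/manifest.csv --lam 0.9 --target-per-class 45 \
    --seed 7 --out-dir data/balanced

# cross-validated training + metric reports (JSON/CSV, ROC points, loss logs)
gaitstream train --manifest data/norm/manifest.csv --config cfg.yaml --out-dir runs/exp1
gaitstream evaluate --run runs/exp1 --report report.json

# attention-based joint/pair importance (CSVs + skeleton figure)
gaitstream interpret --manifest data/norm/manifest.csv --out importance/
```

Config files (YAML or JSON) may set `epochs`, `learning_rate`, `batch_size`,
`k_folds`, `lam`, `target_per_class`, `t_target`, `seed`, `variant`
(`full|no_cnn|sin_cnn|no_maxp`), `streams` (`both|jp|rjdp`),
`stream_out_channels`, `post_fusion_channels`, `gate_penalty`.

## Data formats

* **Motion CSV** — header `frame,<joint>_x,<joint>_y,<joint>_z` for each of
  the 20 joints, one row per frame, meters, lossless doubles.
* **Manifest CSV** — `sample_id,path,label` with label one of the four
  classes or `unlabelled`.
* **TRC** — best-effort reader for mocap exports (header units honored,
  millimeters converted to meters).

Coordinate convention: x = walking direction after alignment, y = up,
z = lateral.

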