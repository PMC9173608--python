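# reefscore

A tested pipeline for measuring the aesthetic value of reef-organism
images and relating it to evolutionary and ecological context:

- **`reefscore.synth`** — procedural organism images with known feature
  ground truth, simulated pairwise judgments from latent scores,
  pure-birth trees with lambda-structured Brownian traits, and
  mixed-type trait tables. Every input the pipeline consumes can be
  generated offline.
- **`reefscore.elo`** — Elo rating of items from pairwise matches with
  randomized match-order replay (mElo: mean and SD of final ratings over
  many shuffled replays), plus OLS calibration for merging two survey
  score scales via shared items.
- **`reefscore.features`** — a 17-feature image battery in four classes:
  color heterogeneity (CIELAB K-means segmentation with silhouette-based
  cluster-count selection), geometry of color patterns (8-connected
  patches, boundary sharpness and box-counting fractality), perceptual
  tone (HSV saturation/lightness moments), and outline shape (elliptic
  Fourier decomposition, second-moment elongatedness, circularity,
  convexity).
- **`reefscore.sampling`** — PCA of standardized features, convex-hull
  vertex-stratified plus uniform-fill survey selection, and a 99%
  confidence-ellipse Jaccard-overlap representativeness check.
- **`reefscore.modeling`** — pairwise-correlation filter (transitive
  closure, keep the most response-correlated member), ordered multiple
  regression with backward elimination, PCA projection of the retained
  features, species-grouped 5-fold cross-validation, a CPU-friendly
  image regressor (random-filter convolutional backbone + trainable
  linear head), and max/mean per-species score aggregation.
- **`reefscore.diversity`** — species age (pendant branch length),
  fair-proportion evolutionary distinctiveness, Pagel's lambda by
  maximum likelihood with a permutation p-value, Gower functional
  distinctiveness on mixed-type traits, PGLS with harmonic-mean p
  combination across tree sets, and one-way ANOVA with Tukey contrasts.

## CLI

One entry point with a subgroup per stage:

```bash
reefscore synth images --n 20 --seed 1 --out-dir imgs/
reefscore synth matches --scores scores.csv --n-matches 10000 --seed 1 --out matches.csv
reefscore synth tree --n-tips 100 --lambda 1.0 --seed 1 --out-dir sim/
reefscore synth traits --n-species 50 --seed 1 --out traits.csv

reefscore elo rate --matches matches.csv --k 100 --start 1500 --runs 1000 --seed 1 --out ratings.csv
reefscore elo calibrate --old old.csv --new new.csv --shared ids.txt --out merged.csv

reefscore features extract --images imgs/ --out features.csv --kmax 10 --seed 1
reefscore sample design --features features.csv --n-vertex 162 --n-fill 162 --dims 5 --seed 1 --out-dir design/

reefscore model features-fit --features features.csv --scores scores.csv --out model.csv
reefscore model cv-train --images imgs/ --scores scores.csv --species-map map.csv \
    --folds 5 --seed 1 --config train.cfg --out-dir train/   # key=value config file
reefscore model predict --model train/model.npz --images new_imgs/ --out preds.csv
reefscore model species-score --predictions preds.csv --species-map map.csv --out species.csv

reefscore diversity ed --tree trees.nwk --out ed.csv
reefscore diversity lambda --tree trees.nwk --scores scores.csv --n-perm 999 --seed 1 --out lambda.json
reefscore diversity di --traits traits.csv --out di.csv
reefscore diversity compare --scores grouped_scores.csv --out tukey.csv
```

## Assumptions

- The Elo k-factor (100) and start value (1500) are configurable
  assumptions; the source analysis does not publish them.
- mElo randomization replays uniform shuffles of the full match list; a
  with-replacement bootstrap is available via `RatingConfig(bootstrap=True)`.
- The image regressor's default backbone is a small fixed-random-filter
  convolutional network trained on CPU; a pretrained deep backbone can be
  substituted by replacing `ImageRegressor.embed`.
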