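# cocluster

Unsupervised discrimination of proteins with near-identical subcellular
distributions, from two-channel fluorescence microscopy images.

Closely related trafficking proteins (the motivating case: Rab GTPases of
the Golgi region) concentrate in the crowded juxta-nuclear area of the cell,
where their staining patterns look alike.  Classical per-cell texture
features (Haralick, Gabor, spot/edge/ridge, radial moments) cluster broad
localization differences well but fail on these subtle ones.  `cocluster`
implements the remedy of adding one quantitative co-localization feature —
the **rank-weighted co-localization (RWC) coefficient** against a reference
organelle marker channel — to the texture battery before PCA + k-means
clustering, and ships a synthetic two-channel image generator that controls
texture statistics and co-localization independently so the whole claim is
testable without real data.

## The RWC coefficient

For one cell with protein intensities `I1` and marker intensities `I2` over
the same pixels, with automatic per-channel thresholds `T1`, `T2` (Otsu):

```
C    = { i : I1_i > T1 and I2_i > T2 }          co-localized pixels
Rmax = |C|
R1, R2 = within-C ranks of I1, I2 (ties averaged)
D_i  = |R1_i - R2_i|
W_i  = (Rmax - D_i) / Rmax
RWC1 = sum_{i in C} W_i I1_i / sum_{I1_i > T1} I1_i     (RWC2 symmetric)
```

Pixels that co-occur **and** agree in intensity rank contribute their full
intensity; discordant pixels are down-weighted; the Manders-style
denominator bounds RWC in [0, 1].  No manual thresholding is needed.

## The analysis chain

1. segment cells on the protein channel (Gaussian smooth, log-domain Otsu,
   hole filling, optional nucleus-seeded watershed, area/border filters);
2. extract 24 texture features per cell (13 Haralick GLCM statistics at
   G = 8 levels, 4 Gabor filter-bank statistics, mean intensity, 3
   spot/edge/ridge responses, 2 radial moments, 1 radial-shift Haralick
   contrast);
3. compute per-cell RWC against the marker channel;
4. cluster: scale features to unit variance, full PCA, k-means (k = 2,
   Hartigan–Wong, 10 restarts) on all PC scores.  The with-RWC run uses the
   *texture PC scores* as independent variables (decorrelated, then scaled
   to unit variance) plus the RWC column — without this step the strong
   collinearity of texture features dominates the k-means objective and a
   single added feature could never change the partition;
5. score the clustering against known labels with best-permutation accuracy.

## Worked example

```bash
cat > sim.yaml <<'YAML'
classes:
  - {n_cells: 3, cell_radius_px: 16, puncta_count: 30, marker_puncta_count: 15,
     coloc_fraction: 0.2, class_label: low}
  - {n_cells: 3, cell_radius_px: 16, puncta_count: 30, marker_puncta_count: 15,
     coloc_fraction: 0.8, class_label: high}
YAML
cocluster run --config sim.yaml --out out --seed 9
```

prints

```
n_cells=6 accuracy_without_rwc=0.5 accuracy_with_rwc=1.0
```

Both classes have identical texture statistics, so texture-only clustering
is at chance (0.5); the two co-localization levels (20% vs 80% of protein
puncta duplicated into the marker channel) separate perfectly once the RWC
feature is added.  `out/report.json` carries the per-cell assignments,
explained-variance fractions and the PC1/PC2 scores for plotting;
`out/features.csv` is the per-cell feature table.

The same experiment at analysis scale — 2 x 70 cells, co-localization 0.3
vs 0.7, confocal-scale cell geometry — yields texture-only accuracy ≈ 0.51
and with-RWC accuracy ≈ 0.96 (see `scripts/acceptance.py` below), i.e. one
co-localization feature converts a chance-level clustering into a nearly
perfect one.

As a library, the clustering stage is a scikit-learn estimator:

```python
from cocluster import PCAKMeans
est = PCAKMeans(n_clusters=2, random_state=0).fit(X)   # X: cells x features
est.labels_, est.explained_variance_ratio_, est.scores_
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the headline synthetic experiment from scratch at the given
seed — two 70-cell classes with identical texture parameters and
co-localization fractions 0.3 / 0.7, segmented, featurized and clustered
end to end — prints the texture-only and with-RWC accuracies, and writes
the results JSON to `--out`.
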