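# teaphys

Estimating tea-plant physiology from UAV imagery: a tested, reusable
implementation of the full analysis chain — canopy segmentation, spectral
index extraction, feature ranking, regression benchmarking and field
statistics — with a seeded synthetic-data generator standing in for field
measurements so every stage is verifiable against known ground truth.

## Who this is for

Remote-sensing and precision-agriculture researchers who estimate canopy
physiological parameters — leaf area index (LAI), photochemical reflectance
index (PRI) and PSII quantum yield (ΦPSII) — from centimeter-resolution UAV
imagery of plantation plots ("designed square zones", DSZs), and who want
each processing step unit-tested rather than buried in a notebook.

## What it computes

- **Leaf-level forward formulas.** PRI = (R531 − R570)/(R531 + R570) from
  paired 531/570 nm leaf-clip reflectance; ΦPSII = (Fm′ − Fs)/Fm′ from
  light-adapted chlorophyll-fluorescence pairs.
- **Canopy segmentation** (`teaphys.segmentation`). SLIC superpixels →
  per-superpixel means of vegetation indices (RGBVI + VARI for RGB imagery,
  EVI + RVI for 5-band multispectral) → exact Otsu binarization with
  optional per-index limits → optional manual per-superpixel override.
  Classifying whole superpixels removes salt-and-pepper noise.
- **Spectral indices** (`teaphys.indices`). 19 color indices (CI) over RGB
  digital numbers and 50 multispectral indices (MI) over
  blue/green/red/red-edge/NIR reflectance, loaded from a versioned JSON
  registry; a DSZ's feature is the mean over canopy pixels, with undefined
  pixels excluded rather than epsilon-substituted.
- **Feature ranking** (`teaphys.ranking`). Pearson |r|; greedy
  minimum-redundancy maximum-relevance (MRMR) over discretized mutual
  information, argmax_j [I(x_j, y) − (1/|S|) Σ_{i∈S} I(x_j, x_i)]; and gray
  relational analysis (GRA), γ_i = mean_k (Δmin + ρΔmax)/(Δ_i(k) + ρΔmax)
  with ρ = 0.5.
- **Regression sweep** (`teaphys.modeling`). Eight regressors (polynomial,
  PLSR, lasso, ridge, decision tree, random forest, XGBoost, LightGBM),
  each grid-searched with 3-fold CV, refit over incrementally added ranked
  features; metrics R², RMSE, MAE; and the 95%-of-best parsimony rule that
  picks the smallest feature count within 5% of peak accuracy.
- **Field statistics** (`teaphys.field_stats`). Descriptive rows with
  CV = StDev/Mean; Levene-gated Student/Welch t-tests between farming
  methods; ANOVA/Welch-ANOVA across elevations with Tukey or Games–Howell
  post hoc compressed to letter groups; grouped residual (RMSE/bias)
  reports.
- **Synthetic scenes** (`teaphys.scene`). Seeded DSZ imagery with
  contiguous canopy blobs, separable class spectra and a known canopy mask,
  plus a planted linear forward model from indices to physiology with
  controlled noise — every generator is bit-reproducible under a fixed
  seed.

## Worked example

```python
import teaphys as tp

scene = tp.generate_scene(canopy_fraction=0.6, size_px=(128, 128), seed=7)
mask = tp.segment_canopy(scene)
print("IoU vs ground truth:", round(tp.iou(mask, scene.truth_mask), 3))

features = tp.extract_features(scene, mask)
print("NDVI =", round(features["NDVI"], 3), "| EVI =", round(features["EVI"], 3))

table, truth = tp.generate_feature_table(n_rows=500, n_noise_features=20, seed=7)
cols = truth.causal_features("LAI") + [c for c in table.columns if c.startswith("noise_")]
ranking = tp.rank_features(table[cols], table["LAI"], "GRA")
print("top-3 GRA features:", ranking.top(3))

fit = tp.fit_model(table[cols], table["LAI"],
                   tp.ModelSpec("XGBoost", grid=[{"max_depth": 6, "learning_rate": 0.1,
                                                  "n_estimators": 150}]), seed=7)
print("XGBoost 3-fold CV R2 =", round(fit.cv_R2, 3))

sel = tp.parsimony_select({1: 0.50, 2: 0.69, 3: 0.716})
print("parsimony: best k =", sel.n_best, "threshold =", round(sel.threshold, 4),
      "reduced k =", sel.n_reduced)
```

prints

```
IoU vs ground truth: 0.991
NDVI = 0.801 | EVI = 0.697
top-3 GRA features: ['NDVI', 'GNDVI', 'noise_05']
XGBoost 3-fold CV R2 = 0.711
parsimony: best k = 3 threshold = 0.6802 reduced k = 2
```

The segmentation recovers 99% of the generator's canopy mask; GRA places
both planted causal indices (NDVI, GNDVI) ahead of all 20 noise features;
XGBoost reaches CV R² ≈ 0.71 on a fixture whose signal-to-noise ratio caps
attainable R² near 0.8; and the parsimony rule keeps 2 of 3 features at a
0.6802 threshold (95% of the 0.716 peak).

There is also a CLI over the same library:

```bash
teaphys run-all -c config.yaml      # simulate | segment | indices | rank | sweep | stats
```

## Documentation

`docs/methods.md` describes the models, defaults, numerical choices and
limitations.
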