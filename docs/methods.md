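# Methods

## The problem setting

Tea plantations are surveyed plot-by-plot: each designed square zone (DSZ,
a 2 m × 2 m plot) is photographed from a UAV at ~0.8 cm/px by a visible
(R, G, B digital numbers) and a five-band multispectral sensor (blue,
green, red, red-edge, NIR reflectance), while three physiological
parameters are measured on the ground: leaf area index (LAI, one-sided
leaf area per ground area), photochemical reflectance index
(PRI = (R531 − R570)/(R531 + R570), tracking xanthophyll-cycle energy
dissipation) and the quantum yield of photosystem II
(ΦPSII = (Fm′ − Fs)/Fm′, with a physiological ceiling near 0.85). The
package turns DSZ imagery into per-plot spectral-index features and
benchmarks how well regressors predict the ground measurements from them.

Field measurements are not distributed with the originating study, so this
implementation is validated on synthetic data with planted, recoverable
structure instead. What that does and does not demonstrate is discussed at
the end.

## Synthetic scenes and physiology

`generate_scene` builds canopy geometry by region growth: blobs grow
outward from random seed points through a smooth random speed field
(Euclidean distance transform from the seeds plus Gaussian-filtered noise
at σ = 6 px, scaled to 0.35 of the distance field's spread), the growth
front is cut at the quantile matching the requested canopy fraction, and a
3 × 3 median filter smooths boundaries. This yields spatially contiguous
canopy patches — superpixel segmentation faces realistic geometry, not
i.i.d. pixel noise.

Class spectra default to a strong vegetation/soil contrast: canopy
blue/green/red/red-edge/NIR = 0.04/0.08/0.05/0.30/0.45, background
0.10/0.12/0.15/0.18/0.20, per-band Gaussian sd 0.015, clipped to
[0.01, 1]. The 0.01 floor matters: radiometrically calibrated reflectance
of real surfaces never reaches zero, and without the floor the ratio index
RVI = NIR/red becomes heavy-tailed over noise-darkened red pixels, which
destabilizes Otsu thresholds on superpixel means. RGB scenes use canopy
(60, 110, 50) vs background (150, 130, 105) DN with sd 8.

`generate_physiology` follows the field protocol's averaging convention:
PRI and ΦPSII are produced by simulating 10 leaf readings per DSZ — each
per-leaf target value (planted mean plus Gaussian noise) is realized as an
exact reflectance or fluorescence pair and pushed through the leaf-level
formula — then averaged; LAI receives a single canopy-analyzer noise draw.
Generated values are clipped to the physically plausible envelopes
(LAI 0.13–10.37, PRI −0.077–0.0766, ΦPSII 0.0729–0.8648) with every clip
logged; the defaults keep clipping rare.

The default planted model (`TruthModel.default`) gives each parameter two
causal indices (e.g. LAI = 0.4 + 6·NDVI + 3·GNDVI) and sets the noise sd
to half the signal sd under the fixture's feature distribution
(indices ~ N(0.55, 0.15²)), i.e. a signal-to-noise ratio of ~2, which caps
attainable R² near 0.8. `generate_feature_table` adds independent noise
features on the same scale so ranking methods must separate signal from
plausible-looking distractors.

## Canopy segmentation

The workflow is SLIC superpixels → per-superpixel index means → Otsu →
limits → manual override, classifying whole superpixels so no
sub-superpixel boundaries (salt-and-pepper noise) can appear.

- SLIC: RGB images are converted to Lab with compactness 20; five-band
  images use Euclidean distance in raw reflectance space with compactness
  0.05 (reflectance scale is far below Lab's, which that setting implies).
  The superpixel count defaults to pixels/400 (~20 × 20 px, ~16 cm patches
  at 0.8 cm/px) and is site-configurable.
- Fragment handling: at compactness 0.05 SLIC clusters are ragged;
  force-merging small fragments into neighbors creates mixed-class
  superpixels and measurably degrades mask recovery. Small connected
  fragments are therefore kept as their own superpixels
  (`min_size_factor = 0.01`), preserving class purity.
- Otsu runs exactly on the empirical distribution of superpixel means:
  candidate thresholds are midpoints between consecutive distinct values
  and the between-class variance is maximized by cumulative sums, so the
  result provably equals an exhaustive search (ties go to the lowest
  threshold). Superpixel-mean vectors are small enough that exactness
  costs nothing.
- Multiple segmentation indices combine by logical AND (a superpixel is
  canopy only if it passes every index) — the conservative reading of
  using two indices to exclude non-canopy areas. Optional per-index
  lower/upper limits clamp the canopy class; manual overrides apply last
  and are logged. Every run can emit a manifest (config hash, seed, class
  pixel counts) so the same hyperparameters are auditable across repeat
  surveys of a site.

## Index registry

Definitions live in `data/index_registry.json` (19 CI + 50 MI) so the
formula set is versioned and auditable. CI formulas evaluate on DN/255 in
[0, 1] plus chromatic coordinates r = R/(R+G+B) etc.; MI formulas on
reflectance. EVI uses the canonical constants G = 2.5, C1 = 6, C2 = 7.5,
L = 1. Pixels where a formula is undefined (zero denominator, negative
square root) are marked invalid and excluded from both the zonal-mean
numerator and the pixel count — epsilon substitution would silently bias
means. Per-index failures on a DSZ degrade to flagged missing values, not
a pipeline abort.

## Feature ranking

- Pearson ranking uses |r|, descending.
- Mutual information is estimated by equal-frequency discretization with
  plug-in entropy in nats. The bin count defaults to max(4, ⌈n^(1/3)⌉):
  the plug-in estimator's bias grows as ~(bins−1)²/2n, and at n = 500 a
  √n-bin rule (23 bins, ~0.48 nats bias) swamps the ~0.09 nats of true MI
  a weakly relevant feature carries, whereas the cube-root rule (8 bins)
  keeps weak signals above the noise floor. The bin count is an exposed
  argument for sensitivity analysis.
- MRMR selects greedily: first the feature with maximal relevance
  I(x_j, y), then at step m the maximizer of relevance minus the mean
  redundancy to the already-selected set (1/(m−1) normalization).
  Negative objectives are allowed; selection proceeds regardless of sign.
  The greedy order provably matches an exhaustive per-step evaluation of
  the objective (tested against that oracle).
- GRA min-max normalizes every sequence to [0, 1] (the dominant
  convention for eliminating range differences), computes per-point
  absolute differences to the normalized target, takes Δmin/Δmax globally
  over all features and points, and averages the gray relational
  coefficient with distinguishing coefficient ρ = 0.5. If every sequence
  matches the target exactly (Δmax = 0) the degree is 1 by continuity.
- All rankings break ties stably by input column order, so results are
  reproducible down to the byte.

## Regression protocol

Eight models are tuned by exhaustive grid search over their published
grids with 3-fold cross-validation (folds shuffled once per seed and
shared across grid entries); the selection criterion and the reported
accuracy are the mean CV R² — a separate held-out split is not part of the
specified protocol. Grid notes:

- Polynomial regression uses a degree-2 expansion solved by SVD
  pseudoinverse, so rank-deficient (collinear) designs return the
  minimum-norm solution with a warning instead of failing; its observed
  instability on collinear data is expected behavior.
- PLSR components run from 2 to the feature count (a single 1-component
  entry when only one feature is in play, so incremental sweeps have a
  k = 1 point); entries infeasible for a fold's training size are skipped
  and logged.
- Lasso/ridge α ∈ {0, 0.01, 0.1, 1, 10, 100} (α = 0 falls back to
  ordinary least squares). Integer ranges without a stated increment are
  enumerated at step 1; tree/boosting grids follow the published ranges
  (e.g. XGBoost max_depth 3–25, learning rate
  {0.001, 0.005, 0.01, 0.05, 0.1}, 50–150 trees in steps of 25).
- The full grids are the library default. Scripted runs (pipeline
  `grid_preset: fast`, the acceptance script) pass documented reduced
  grids through the `grid` override; model comparisons quoted in this
  repository use those reduced grids and state their sizes.

`incremental_sweep` refits with the top-k ranked features for k = 1..K
with a full grid search at every k. `parsimony_select` takes the best R²
over the curve, sets the threshold at 95% of it, and returns the smallest
k at or above the threshold. When the best R² is non-positive the
fractional threshold exceeds the best value and the rule degenerates; the
selection then falls back to the best point itself (n_reduced = n_best).

## Field statistics

Descriptive rows use the sample standard deviation (n−1) and
CV = StDev/Mean. A Levene pre-test on medians at α = 0.05 gates every
inferential branch: Student vs Welch t for the two farming methods,
classical ANOVA + Tukey HSD vs Welch ANOVA + Games–Howell across
elevations. Pairwise post-hoc significance is compressed to a compact
letter display by labeling maximal cliques of the
"not-significantly-different" graph, ordered by descending group mean —
groups share a letter exactly when their pairwise test is non-significant.
Grouped residual reports give RMSE and mean signed error per
elevation × season × farming-method cell; a positive mean marks
systematic overestimation. The gated t-test's type-I error is calibrated
(empirically within [0.03, 0.07] at α = 0.05 over 500 null simulations).

## Problem sizes used in tests and scripted runs

Scenes are 128 × 128 px (segmentation recovery uses 20 seeded scenes);
tabular fixtures are 500 DSZs with 2 causal + 20 noise features over 10
seeds; oracle equivalences run 100 random instances each; type-I
calibration runs 500 null simulations; the end-to-end pipeline test runs 2
sites × 3 DSZs × 2 months at 64 × 64 px. These sizes give stable
statistics while keeping a full run in the minutes range on one CPU.

## What the synthetic results do and do not show

Passing tests demonstrate that every operation implements its definition
correctly (oracle equivalence), that the pipeline recovers structure it is
supposed to recover (planted features ranked on top, canopy masks with
IoU ≈ 0.99, regressors approaching the noise ceiling), and that the
statistical machinery is calibrated. They do not demonstrate field-level
predictive skill: the generator's linear forward model, Gaussian noise,
two-class scenes and clean class spectra omit real-data difficulties —
mixed pixels, shadows and illumination drift, radiometric error, spatial
autocorrelation between neighboring DSZs, nonlinear physiology–reflectance
links and seasonal covariate shift. Reported field-scale accuracies for
LAI/PRI/ΦPSII therefore cannot be, and are not, reproduced here; the
package instead verifies all arithmetic derivable from the published
summary tables.

## Known limitations

- Scene output is plain multiband TIFF; geo-referencing tags are not
  written (synthetic scenes have no real-world coordinates).
- The SLIC stage relies on scikit-image's implementation; its
  determinism is grid-initialization-based, not seed-based.
- The MI estimator is the discretized plug-in; k-NN estimators may rank
  differently at small n.
- Letter displays are derived from pairwise tests at a fixed α = 0.05;
  they inherit those tests' multiplicity properties and are not an
  additional correction layer.
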