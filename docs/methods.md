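# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `soyield`, in the spirit of a model-description chapter
rather than an API reference.

## Imaging geometry and calibration

Each plant contributes seven views: six side views taken at 60° rotation
increments and one overhead view. Side-level features are the arithmetic
mean of the six per-view values; for the color ratios the six views' R, G,
B means are averaged first and the ratios formed from the averaged means
(a ratio of means, not a mean of ratios — the two differ whenever
brightness varies across views). Top-level features come from the single
overhead view.

A white reference board of known 30 cm diameter appears in every image;
its pixel span fixes the calibration cm/px = 30/span. Morphological
lengths are reported in cm and areas in cm² (`units="px"` disables
calibration); dimensionless descriptors (solidity, extent, circularity,
eccentricity, …) are unaffected.

## Segmentation

The built-in segmenter is excess-green (ExG = 2G − R − B) thresholding
with an Otsu split, followed by largest-4-connected-component selection
and hole filling. ExG is invariant to adding a constant to all three
channels, and the Otsu split is exact when foliage and background are
bimodal in ExG — which the synthetic renderer guarantees and real field
imagery does not. The stage therefore treats segmentation as a pluggable
contract: externally produced masks (e.g. from a trained encoder–decoder
network) pass through unchanged, and everything downstream depends only on
the mask. Training a learned segmenter is out of scope here (it needs
labelled imagery and GPU time). Masks are required to exclude the
reference board; the renderer enforces a margin around the board so the
largest-component rule cannot capture it.

## Gray–gradient co-occurrence texture

The texture bank is built on the gray–gradient co-occurrence matrix
(GGCM): the joint histogram of the quantized intensity level and the
quantized gradient-magnitude level *at the same pixel*. This differs from
the displacement-based Haralick GLCM, which co-occurs two gray levels at a
spatial offset; the GGCM instead couples tone with local edge strength.

Choices that the construction leaves open, fixed here:

- **Intensity**: the HSI I channel, I = (R+G+B)/3, kept real-valued.
- **Gradient operator**: 3×3 Sobel magnitude √(gx²+gy²) with
  replicate-padded borders (the unnormalised kernels: a step edge of
  height h yields an interior magnitude of 4h). The operator is a module
  parameter in the sense that any H×W gradient image can be passed to
  `quantize_pair` directly.
- **Quantization**: linear min–max onto 16 integer levels per axis,
  computed over foreground pixels only; a constant channel maps to
  level 1. Sixteen levels keep the 16×16 matrix dense enough at typical
  foreground sizes (10³–10⁵ px).
- **Inhomogeneity traits**: gradient-distribution inhomogeneity sums the
  squared gradient marginal, Σ_j[Σ_i H(i,j)]²/ΣH, and grayscale
  inhomogeneity the squared gray marginal, Σ_i[Σ_j H(i,j)]²/ΣH — the two
  printed formulas in the source material are near-identical typographs,
  and this assignment keeps each trait attached to its named marginal.
- **Entropies**: natural log, −Σp·log p with 0·log 0 := 0, so all
  entropies are ≥ 0 and a constant image scores 0.
- **Histogram traits**: computed on the normalized 256-bin histogram of
  the rounded foreground intensities. The variance trait keeps its
  as-printed divisor of 255 (a nonstandard normaliser, retained for
  fidelity rather than statistical convention).
- **Degenerate correlation**: when either marginal SD is zero the
  gray–gradient correlation is undefined; it is reported as 0.

Every trait is verified against an independent naive-summation oracle
(explicit Python loops over the 16×16 matrix) to 1e-9 on random fixtures.

## Morphology banks

The 30-descriptor side bank and 16-descriptor top bank cover the
descriptor families used in single-plant phenotyping (areas, fractional
widths, compactness, rectangularity, ellipse fits, calipers). Conventions:
height fractions are measured from the top of the plant bounding box;
perimeter uses scikit-image's weighted boundary estimate; orientation
comes from second-order central moments; the minimum Feret diameter is
computed by rotating calipers over the convex hull of pixel squares.
Pixel-grid quantisation bounds the accuracy of area/perimeter-derived
quantities to a few percent at small mask sizes, which the tests encode as
explicit tolerances (e.g. disk area within 2%, rescaling s ∈ [0.5, 2]
within 3%).

## Synthetic trial generator

The generator is the package's test bed and defines the conditions under
which the pipeline's statistical claims are verified.

**Table tier.** Per-plant yield is Gaussian:

    y = μ + g_v + l_v + (gy)_vy + t + e,

with variety effect g_v ~ N(0, Vg), a variety×location term l_v ~
N(0, Vll) (0 by default — single location), variety×year interaction
(gy)_vy ~ N(0, Vly), a fixed treatment offset ±Δ/2 and residual e ~
N(0, Vr). Defaults: μ = 25 g/plant, Vg = 10, Vly = 9, Vr = 27 (total SD
≈ 6.8 g, CV ≈ 27%, two-year H² ≈ 0.8 at three reps), Δ = 1 g — a mild
sole-vs-intercrop penalty small enough to keep the yield marginal
indistinguishable from Gaussian at n ≤ 2000. The default design mirrors
the motivating study's bookkeeping: 240 varieties × 3 reps × 2 treatments
in year one (1,440 plants) and 202 varieties in year two (1,212), seven
images per plant (18,564 images).

A feature planted at correlation r is r·z + √(1−r²)·ε with z the
standardized clean yield, so its expected sample correlation is exactly r;
the default signal map spans |r| 0.3–0.85 with both signs, echoing the
correlation pattern of side/top texture and morphology indicators in the
motivating analysis. Noise features are independent standard normals.

**Outlier injection.** Each year receives a configured number of gross
recording errors (defaults 149 and 121 on the default design): positive
yield offsets drawn uniformly from 7–60 SDs of the *outlier-test model's*
residual (the full yield SD, since the test model fits only intercept +
treatment). The spread of magnitudes matters: at ~10% contamination a
single common offset is masked — the inflated residual SD keeps every
studentized residual below the Bonferroni cutoff for *any* single
magnitude — whereas a ladder of magnitudes lets iterative deletion peel
the largest outlier, shrink the SD estimate, and unravel the rest. The
floor of 7 SDs keeps the smallest injected error above the cutoff with a
comfortable margin after its own residual noise. Exactness of the removal
count is still probabilistic in principle: the Bonferroni test carries a
~5% per-year family-wise chance of one extra (false) removal, an inherent
property of the procedure, though its conservativeness makes this rare in
practice.

**Image tier.** The renderer composites elliptical "leaf" blobs around a
stem (side) or a central core (top) on a soil-toned background, with the
white board disk in a protected corner. It is schematic by design — the
pipeline's contracts concern masks and statistics, not botany — but it
gives exact ground truth: the drawn mask, the per-view target area
(honoured within ±5% by a deficit-driven growth loop), and the board
scale. Side views are independent ±10% jitters of one latent plant, so
six-view averaging demonstrably reduces variance. Canopy area and
greenness scale with the plant's standardized yield, which is what lets
segmentation + extraction recover the planted yield ordering (Spearman
ρ ≥ 0.9 against latent area). What the renderer does *not* emulate:
occlusion, specularity, shadows, leaf morphology, background clutter —so a
passing image-tier suite says the pipeline's accounting is right, not that
the segmenter or features are field-robust.

All randomness flows from a single seed through named per-tier generators,
recorded in the truth object; identical seeds reproduce byte-identical
images and tables.

## Outlier removal

Within each year, yields are modelled as intercept + treatment effect;
externally studentized residuals are tested two-sided with Bonferroni
adjustment (α = 0.05 by default) and all qualifying rows are removed,
iterating until none qualify. The covariate set is configurable; intercept
+ treatment is the default because treatment is the only fixed effect in
the trial design. Each removal is logged with its residual, adjusted p and
iteration.

## Heritability estimation

Variance components come from balanced method-of-moments ANOVA on the
variety × year layout after removing the treatment fixed effect by
centring: Vr = MS_E, Vly = (MS_GY − MS_E)/m, Vg = (MS_G − MS_GY)/(m·Y),
with m the replicate count per variety×year cell and Y the number of
years; negative estimates truncate at 0. Varieties absent in any year are
dropped; mildly unbalanced cells fall back to the harmonic-mean cell size
with a warning. Vll is fixed at 0 (single location). H² divides Vr by n²
as printed in the source formulation (`conventional=True` switches to the
n·years divisor). The replicate count n defaults to the per-cell count m —
equal to the design's rep count when one treatment is analysed. At 200
varieties × 2 years × 3 reps the estimator is unbiased with an H²
sampling SD of ≈ 0.04, which is what the ±0.05 recovery checks reflect.

## Models and evaluation

The five regressors carry fixed hyperparameters (no grid search is
re-run): GBDT lr 0.1 / depth 5 / 800 trees; CatBoost-style histogram
boosting lr 0.05 / depth 10 / 2000 iterations; LightGBM lr 0.1 / depth 10;
RF 300 trees; MLP (100, 50) relu, L2 0.01, adaptive learning rate, SGD,
squared-error loss (a split criterion like friedman_mse has no meaning for
a perceptron). Features are z-scored with training statistics only;
zero-variance training features are pinned to 0 and flagged. The train/test
split is by year (earlier year trains); "Val" metrics are training-set fit
and "Cal" metrics the held-out year. Tenfold CV shuffles with the given
seed; single-row folds have undefined R² and are flagged rather than
silently averaged.

Metrics are RMSE, MAE and R² = 1 − Σ(ŷ−y)²/Σ(ȳ−y)². RMSE ≥ MAE always
(Jensen); R² requires non-constant truth.

Importance is normalized total split gain — the tree-ensemble default —
with ties broken alphabetically; models without split-gain importances
(the MLP, and the histogram booster which does not expose them) are
rejected rather than approximated. The incremental curve refits the model
on the top-k features for k = 1..K; the plateau index is the smallest k
from which R² never again changes by ε (default 0.01) — i.e.
|R²(j) − R²(k)| < ε for all j ≥ k. The ε has the character of a
noise floor: fixtures for plateau claims are sized so that R² jitter
between feature subsets sits below it (1,200 rows in the shipped checks).

## Problem sizes in the shipped checks

The test suite and the acceptance script run the full default trial
(2,652 plants; 18,564 images rendered at a 48 px canvas), texture-oracle
equivalence on 100 random 32×32 fixtures, heritability recovery at 200
varieties × 2 years × 3 reps, and the selection curve on 5 planted signals
among 20 nulls at 1,200 rows. Image canvases are small because every
image-tier contract (areas, masks, scale, counts) is resolution-scaled by
construction; nothing in the checks depends on high-resolution rendering.

## Known limitations

- The excess-green segmenter is a stand-in; on real imagery a trained
  model should be plugged in via the provided-mask path.
- The morphology bank's descriptor *names* are one concrete realisation of
  the families used in the motivating analysis; where the original
  abbreviation definitions are unavailable, the mapping is documented and
  provisional.
- The heritability machinery is single-location ANOVA, not a mixed-model
  BLUP fit; Vll cannot be estimated from the shipped designs.
- Multicollinearity among retained features is not pruned; the screening
  is marginal-correlation only.
- The synthetic generator's feature–yield coupling is linear-Gaussian;
  models that exploit nonlinearity will look no better than boosting here
  even where they might on real data.
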