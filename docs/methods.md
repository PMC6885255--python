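# Methods

`subtyperad` implements a radiomics pipeline for recognising breast-cancer
molecular subtypes (luminal A, luminal B, HER-2 over-expressing, basal-like)
from dynamic contrast-enhanced MRI (DCE-MRI): lesion segmentation by seeded
region growing with a dynamically determined threshold, a fixed
146-value feature schema over texture, kinetics, first-order statistics and
morphology, multi-model recursive feature elimination (mmRFE), and
imbalance-aware multi-class evaluation. Real subtype-annotated DCE-MRI
cohorts are not freely available, so the package ships a phantom generator
that plays the role of the data: every stage is exercised, measured and
tested on synthetic cases with known ground truth.

## Phantom model

A case is a stack of ≥ 3 grey-level phases (default 128×128, intensities
0–255): one pre-contrast phase T0 and post-contrast phases T1, T2. The
lesion is a star-convex region rasterised from the radial function

    r(θ) = r0 · (1 + Σ_j a_j cos(jθ + φ_j)),   j = 1..H,

with random phases φ_j and harmonic amplitudes a_j summing to a per-class
irregularity parameter; amplitude 0 gives a disk. T0 holds a flat
background (default 30) plus the lesion baseline (default 100) with an
additive smoothed-Gaussian texture field (per-class amplitude and
correlation length). Phase i ≥ 1 multiplies each lesion pixel by a
per-pixel enhancement ratio drawn as N(target_i, heterogeneity²); Gaussian
read-out noise (default sd 4) is added everywhere and intensities are
clipped to [0, 255] and, by default, rounded to integers (`quantize=False`
keeps the continuous model, used when exact enhancement identities are
asserted).

Class profiles are stand-ins chosen once to give controllable separation in
all three feature families — kinetics (enhancement ratios 1.4/1.7/2.0/2.3
for A–D), shape (irregularity 0.05–0.30) and texture (contrast 6–18) — with
no claim of biological fidelity: the clinical literature does not
characterise subtype-specific image appearance at this level. Cohort class
counts follow largest-remainder allocation of the clinical proportions
183/241/143/70 (n = 637), which reproduces those integers exactly at the
original cohort size. What passing tests show is therefore that the
*pipeline* recovers structure that is present by construction; they say
nothing about how separable real subtypes are.

`planted_feature_table` is the tabular analogue used for selection studies:
n samples at the same class imbalance, p features of which k carry
class-dependent Gaussian means (class separation 2.0, unit noise), the rest
pure noise, with the informative column identities returned.

## Segmentation

The lesion is annotated by a loose rectangular ROI (ground-truth bounding
box padded by 4 px in phantoms). The seed is the geometric centre of the
ROI; if the centre falls at or below the growth threshold (possible for
concave lesions) it is relocated to the brightest pixel within a 3-px
window. Two growth criteria:

* **dynamic** (default): the threshold t* is Otsu's level of the ROI patch
  — the smallest 8-bit level maximising between-class variance of the
  256-bin histogram — and the mask is the 8-connected component of
  {I > t*} ∩ ROI containing the seed. Parameter-free and deterministic.
  An alternative reading (|I(p) − I(seed)| < |I(seed) − t*|) is available
  behind `GrowOptions(criterion="seed_delta")`.
* **fixed**: the classical criterion |I(p) − I(seed)| < T with a preset T;
  the grown region is non-shrinking in T, so too large a T floods the ROI.

Otsu is applied to the ROI patch, not the whole image: the
lesion/background intensity classes only exist locally. A constant patch
has no threshold and raises a degenerate-threshold error; an empty grown
region raises rather than returning an empty mask. Quality is scored by
the Dice coefficient S = 2|X∩Y|/(|X|+|Y|).

The benchmark in `benchmarks.segmentation_benchmark` draws each case's
lesion/background contrast uniformly from [60, 180] so that no single
fixed T suits every case; the dynamic mode needs no per-case parameter and
its mean Dice is required not to fall below the best fixed T ∈ {20, 30,
40, 50}.

## Feature schema (146 values)

* **GLCM (F1–F15)** — per phase, grey levels min–max quantised to 16 bins
  over lesion pixels; symmetric co-occurrence at distance 1 in directions
  0°/45°/90°/135°, counting only pairs with both pixels in the mask; five
  statistics (energy Σp², contrast Σ(i−j)²p, correlation, entropy −Σp log₂p,
  and the inverse difference moment Σp/(1+(i−j)²), here called the deficit
  matrix) averaged over the four directions. Correlation is 0 by
  convention when a marginal variance vanishes.
* **LBP (F16_b/F17_b/F18_b)** — 8-bit codes Σ S(g_p − g_c)·2^p with
  S(u) = 1 for u ≥ 0 (ties set the bit), neighbours ordered top-left then
  clockwise, computed for every mask pixel whose 3×3 window fits in the
  image; neighbours are read from the raw image regardless of mask
  membership. The 256-bin histogram is normalised by the number of coded
  pixels and the 31 bins {1..15, 240..255} are retained per phase.
* **Kinetics (T1–T13)** — pixel-wise enhancement rates
  R = (I_T − I_t)/I_t over mask pixels with I_t > 0, summarised by
  population std/mean/max for phase pairs (1,0), (2,0), (2,1) (T1–T9);
  whole-lesion enhancement rate ER_i0 = S_i/S_0 and absorption rate
  AR_i0 = (S_i − S_0)/S_0·100% for i = 1, 2 (T10–T13), with S_i the mean
  lesion grey level of phase i. AR = (ER − 1)·100 holds identically.
* **Statistics (C1–C18)** — per phase: mean, population std, Shannon
  entropy (bits) of the 256-bin histogram, maximum, bias (skewness) and
  peak (excess kurtosis); skewness and kurtosis are 0 by convention for a
  constant region.
* **Morphology (M1–M7)** — boundary pixels (≥ 1 four-neighbour outside)
  ordered by polar angle about the mask centroid (ties by radius); radial
  lengths normalised by their maximum give the NRL sequence. M1/M2 = NRL
  mean/std; M3 tightness = P²/(4πA); M4 roughness = cyclic mean |ΔNRL|;
  M5 smoothness = cyclic mean second difference; M6 roundness = 4πA/P²;
  M7 = area. The perimeter P sums steps between consecutive angle-ordered
  boundary pixels (1 axial, √2 diagonal), which is the chain-code length
  for star-convex masks.

The schema is emitted in full for every case; `drop_invalid_columns`
removes columns that are zero across the whole cohort (typically LBP bins
never observed) and logs them, so the effective column count is
data-dependent by design. Every extractor is tested against an
independent brute-force enumeration (all pixel pairs for GLCM, per-pixel
codes for LBP, explicit loops for kinetics and moments) and Otsu against
an exhaustive cut-point search.

## Feature selection

`model_importance` ranks features per model: mean absolute standardised
coefficient over classes for the linear models (features z-scored inside
the fit pipeline), impurity importance for the tree ensembles; ties keep
column order. Single-model RFE removes the `step` least-important features
per iteration down to one feature, recording the surviving set and CV
accuracy each time.

mmRFE ranks with *all* models each iteration, sums each feature's rank
position across models (lower = more important; ties broken by best
single-model position, then label order — making the composite invariant
to model order), eliminates by the composite, and records every model's CV
accuracy at every subset size. Candidate subsets are the iterations where
every model reached the threshold θ (default 0.8; 0.85 is a documented
stricter choice); among candidates the subset maximising the minimum
per-model accuracy wins, ties resolved by higher mean accuracy and then by
smaller subset. If no iteration qualifies an explicit empty selection is
returned together with the best-available subset.

Default CV is stratified 5-fold with a fixed shuffle seed; leave-one-out
is available (`cv="loo"`) as the fidelity mode. Step defaults to 1;
elimination studies in the benchmarks use step 5 and 3-fold CV with
sized-down tree ensembles (RF 100 trees, GBDT 50), sizes at which the
planted-benchmark accuracies are already saturated.

## Classification and evaluation

Documented model defaults: LR (L2, C = 1), linear-kernel SVM (C = 1),
RF (500 trees), GBDT (300 stages, learning rate 0.1, depth 3); all
overridable via `ModelConfig.params`. No resampling or class weighting is
applied by default — the imbalance is addressed by feature robustness and
surfaced through per-class metrics; a class-weight option can be passed
through `params`. Out-of-fold predictions are pooled into a single
confusion matrix; the report carries overall accuracy, per-class
precision/recall/F1 (zero-denominator metrics reported as 0 with a
warning), and macro plus weighted averages — macro is the canonical
headline. The ensemble is a majority vote over the four fitted models;
vote ties are broken by highest mean predicted class probability over the
models exposing probabilities, residual ties by the fixed priority GBDT,
SVM, RF, LR. The combination rule is this package's definition — an
interpretation, since ensembling details are not standardised.

## Numerical and design choices

* 2D single-slice cases; three phases by default (configurable upward,
  later phases plateau at the T2 ratio) — the features use only T0–T2.
* Intensities are byte-scale so that 256-bin histograms (Otsu, LBP,
  entropy) are well defined; feature extractors round to the nearest
  integer only where a histogram bin is needed.
* Population (not sample) standard deviations throughout; log₂ entropies
  with 0·log 0 ≡ 0.
* Degenerate inputs are errors, not NaNs: empty masks, constant
  Otsu patches, all-zero reference phases, boundaries shorter than 3
  pixels.
* Pipeline artifacts are diff-stable (sorted-key pretty JSON, plain CSV)
  and every stage records a content hash of its inputs, so a rerun resumes
  after the last unchanged stage.

## Problem sizes

The shipped benchmarks use 50 phantom cases for segmentation, n = 640 /
60 features / 10 planted for selection recovery, n = 400 for the
permutation null, and 16-case cohorts for the end-to-end determinism runs
— sizes at which every measured quantity is stable across seeds while the
whole suite stays desk-scale.

## Known limitations

* The phantom has no MR physics: no bias fields, motion, partial volume,
  rib/skin structures, or background parenchymal enhancement; segmentation
  Dice values on phantoms are upper bounds on clinical behaviour.
* Star-convex lesions cannot represent diffuse or multi-focal disease, and
  the angle-ordered boundary walk assumes near-star-convex masks.
* One lesion per ROI; 3D growing and multi-lesion handling are out of
  scope.
* The feature count of the full schema (146) exceeds the effective count
  after zero-column removal, which varies with the cohort; downstream
  stages always operate on the post-removal table.
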