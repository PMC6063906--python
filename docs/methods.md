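# Methods

This note documents the models, algorithms and numerical conventions the
package implements, the assumptions behind the synthetic data generator,
and the design choices made where the underlying methodology leaves room.

## Problem setting

Destruction–replenishment contrast-enhanced ultrasound (CEUS) images a
tumour in B-mode while intravascular microbubbles flow through its
vasculature. A high-mechanical-index pulse destroys the bubbles in the
imaging plane; their re-inflow follows, to good approximation,

    I(t) = I0 + A · (1 − exp(−β t)),

where `A` is the plateau amplitude (proportional to relative blood
volume) and `β` (1/s) relates to mean blood flow velocity via the
elevational beam width: `v = β · w`. A single scan therefore carries
intensity, texture, vascular-morphology and perfusion information at
once. The package extracts a 235-feature radiomic vector per scan,
selects a stable four-feature signature, and classifies three tumour
phenotypes with a linear SVM.

## Synthetic phantoms (`phantom`)

Real CEUS study data of this kind are rarely deposited, so the package
ships a first-class generator whose defaults define the study conditions
used throughout the tests.

**What it emulates.**

* *Tumour background*: smoothed speckle — exponential noise low-pass
  filtered at `texture_granularity` (px), standardized, scaled by
  `speckle_scale` (intensity units) and offset by `background_level`.
  The field is static over time, as the interference pattern of
  stationary scatterers is; a per-frame additive sensor-noise term
  (`temporal_noise · speckle_scale`) provides the temporal noise floor.
* *Vasculature*: a branching curvilinear network grown by random walkers
  with direction persistence (turn sd 0.3 rad/step), per-step branching
  probability, and 1–3 px stamp widths, iterated until the vessel-pixel
  fraction of the ROI is within ±10 % (relative) of `vessel_density`.
* *Microbubble kinetics*: vessel pixels carry a bolus ramp to plateau
  `A`, a drop to 0 at `destruction_frame`, and `A(1 − exp(−βt))`
  replenishment. Per-frame, per-pixel lognormal flicker
  (`bubble_flicker` log-sd, mean exactly 1) models bubbles moving
  through the plane — this is what frame differencing detects.
* *Breathing*: every `breathing_period`-th post-bolus frame is globally
  shifted by `breathing_shift` px and recorded in the ground truth.
* *Study design*: per animal two imaging positions; each position
  acquired twice (dataset 1/test, dataset 2/retest) with identical
  phantom geometry but fresh noise; three observer ROIs per scan (the
  true ellipse, a smooth radial boundary jitter of ~2 px, and a uniform
  ±2 px dilation/erosion). Default cohort 5+5+4 animals → 28 scans per
  dataset, mirroring a small-animal xenograft study.

**Phenotype classes.** P1/P2/P3 differ in vascular density (0.08 / 0.14
/ 0.22), replenishment rate β (0.4 / 0.8 / 1.4 s⁻¹), background level
and speckle granularity, so vascular, kinetic, intensity and textural
features all carry class information. Frame rate 10 fps, 60 frames,
destruction at frame 20, 128×128 px. These acquisition values are
generator choices — plausible for preclinical high-frequency CEUS — not
claims about any particular scanner protocol.

**What it does not emulate.** RF-domain physics, depth-dependent
attenuation and beam geometry, nonlinear bubble oscillation, in-plane
flow (vessels flicker in place rather than advect), tissue deformation
(breathing is a rigid shift), or 3-D anatomy. Passing tests demonstrate
the analysis chain is correct and recovers known ground truth under this
noise model; they do not certify performance on scanner data.

## Speckle denoising (`denoise`)

Speckle is approximately multiplicative, so frames are log-transformed
(`log(x + 1)`; the +1 offset guards zero intensities) before a level-3
2-D discrete wavelet decomposition with the biorthogonal 3.7 wavelet and
symmetric boundary extension. The noise level is estimated from the
finest diagonal subband by the robust median rule
`σ_n = median(|d1|)/0.6745`. Each **level-3** detail subband is soft-
thresholded with the adaptive Bayes threshold `T = σ_n²/σ_x`,
`σ_x = sqrt(max(σ_y² − σ_n², 0))` (σ_y² the subband's mean square); when
`σ_x = 0` the whole subband is shrunk to zero (`T = max|coeff|`).
Levels 1–2 and the approximation are left untouched — thresholding only
the coarsest details is unusual relative to standard BayesShrink (which
shrinks every level) but is the behaviour this pipeline specifies. A
consequence worth knowing: only the coarse-scale share of the noise
energy is removed, so on pixel-iid speckle the mean-squared-error gain
is modest (well under 1 %), and on speckle that is already smooth at the
finest scale the noise estimator correctly reports σ_n ≈ 0 and the
filter is a near-identity.
`threshold_scale` multiplies all thresholds; 0 disables shrinkage and
makes the round trip an identity to ~1e-10, which the tests use as the
perfect-reconstruction oracle.

## Vessel segmentation and kinetics (`segmentation`)

1. **Local Wiener smoothing** (3×3): `out = m + max(v−nv,0)/max(v,ε)·(x−m)`
   with local mean `m`, local variance `v`, and noise variance `nv` the
   image mean of `v` — the classic wiener2 estimator.
2. **Breathing-artifact rejection**: per-frame motion score = mean
   |frame difference| to the previous frame; outliers exceed
   median + 3·MAD. A displaced frame produces two consecutive outlier
   scores (leaving and returning), so a frame is flagged only when both
   the difference into it *and* out of it are outliers; this pins the
   artifact on the displaced frame itself. The destruction frame is a
   known global intensity step and is never reported as an artifact.
3. **Difference MIP**: per-pixel maximum over time of |frame_t −
   frame_{t−1}| over consecutive *kept* frames, masked to the ROI.
   Differencing cancels static echoes; moving microbubbles survive.
4. **Adaptive thresholding**: pixel > local mean (15×15) + offset. The
   default offset is noise-adaptive: 3 × 1.4826·MAD of the MIP inside
   the ROI (floored at 1e-9·max(MIP) against floating-point dust on
   noise-free input). A fixed zero offset would mark roughly half of all
   pure-noise pixels — a noisy field exceeds its own local mean about
   half the time regardless of amplitude — so a positive, data-scaled
   offset is what makes this step the *noise-removal* it is meant to be.
   The MAD of the MIP is a noise-floor estimate as long as vessels cover
   < 50 % of the ROI. An absolute `offset` and the multiplier `offset_k`
   remain configurable.
5. **Speckle removal**: 8-connected components < 5 px are discarded.

**Replenishment fit.** The tumour time–intensity curve is the mean ROI
intensity of non-excluded frames strictly after the destruction frame,
with t in seconds. `I0 + A(1−exp(−βt))` is fitted by bounded nonlinear
least squares (start values: I0 = first point, A = last−first,
β = 2/t_max; bounds A, β ≥ 0). A flat curve (range below 1e-12 relative)
short-circuits to A = β = 0 instead of a degenerate optimizer run. Note
that the ROI-mean curve has plateau `≈ rBV · A_vessel`, which leaves β
unbiased. `beam_width` (default 1.0 length unit) converts β to velocity
and is an explicit calibration constant.

## Feature extraction (`features`)

All intensity/texture/wavelet features are computed on a single
reference image: the temporal mean of the *denoised pre-destruction*
frames (artifact frames excluded). A temporal mean is reproducible,
noise-robust, and uses the portion of the sequence where bubble signal
is at plateau.

* **Quantization**: min–max over the ROI to 32 grey levels (1..32),
  applied per image and per wavelet subband. Constant regions map to
  level 1.
* **First order (14)**: energy, entropy, kurtosis, maximum, mean, mean
  absolute deviation, median, minimum, range, RMS, skewness, standard
  deviation, uniformity, variance. Moments use 1/n normalization;
  kurtosis is non-excess; entropy/uniformity use the quantized
  histogram; skewness/kurtosis of a constant region are 0 by convention.
* **GLCM (19)**: symmetric normalized co-occurrence matrices at distance
  1 for the four 2-D directions, counted only over pixel pairs fully
  inside the ROI, matrices averaged over directions: autocorrelation,
  cluster prominence/shade, contrast, correlation, difference entropy,
  dissimilarity, energy, entropy, homogeneity, IMC1, IMC2, IDMN, maximum
  probability, sum average/entropy/variance, variance, inverse variance.
  Degenerate conventions: correlation 0 and IMC1 0 when a marginal is
  constant; logs are base 2 with 0·log0 = 0.
* **GLRLM (11)**: run matrices over maximal constant runs inside the ROI
  for the four directions (runs break at the ROI boundary), count
  matrices averaged: SRE, LRE, GLN, RLN, RP, LGLRE, HGLRE, SRLGLE,
  SRHGLE, LRLGLE, LRHGLE. Run percentage divides by the ROI pixel count.
* **Vascular (15)**: from the binary segmentation — number of vessels
  (8-connected components), mean/median/maximum component size, total
  vascular area, network length (skeleton pixel count), branch points
  (skeleton pixels with ≥3 skeleton neighbours), mean/sd/max of the
  Euclidean distance of non-vessel ROI pixels to the nearest vessel,
  rBV (vessel fraction of ROI), rBV of periphery and of core and their
  ratio, and mean blood flow velocity from the replenishment fit. The
  core is the innermost ~50 % of the ROI area obtained by iterative 1-px
  erosion until the area first drops to ≤50 %; the periphery is the
  remainder. Ten of these are classical; the other five (area, max size,
  branch points, the two rBV ratio components) complete the class to its
  stated count of 15 and are natural companions. Empty-vessel scans:
  counts and rBV are 0, the distance map falls back to the distance to
  the ROI boundary (the maximum feasible distance), and the
  periphery/core ratio uses a floored core rBV of one pixel per core
  area as a finite sentinel — feature vectors are finite by contract.
* **Wavelet (176)**: level-1 undecimated (stationary) transform with the
  coiflet-1 wavelet — shapes are preserved, so the ROI applies
  unchanged; odd extents are symmetrically padded and cropped. On each
  of the four subbands (A/H/V/D) the 14 + 30 features above are
  recomputed with fresh quantization: 4 × 44 = 176. The signature
  feature `wavD_glrlm_RLN` is the run-length nonuniformity of the GLRLM
  on the diagonal-detail subband.

14 + 30 + 15 + 176 = 235 is enforced structurally: `FeatureVector`
rejects any vector that is missing a name, carries extras, or contains a
non-finite value.

## Signature selection (`selection`)

Four per-feature rankings, each a strict permutation of 1..235 (ties
broken deterministically by feature name):

1. **Test/retest stability**: Lin's concordance correlation coefficient
   `ρc = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²)` (1/n moments) between dataset-1
   and dataset-2 values aligned by (mouse, position), computed per
   observer and averaged; ranked high→low. Identical constants are
   perfectly concordant (1); distinct constants have ρc = 0.
2. **Normalized dynamic range**: `DR = mean_i(1 − |test_i − retest_i|/R)`
   with R the pooled test∪retest range, per observer and averaged;
   ranked high→low; R = 0 ⇒ DR = 0 (no biological range).
3. **Observer independence**: Quade test (blocks = the 56 acquisitions,
   treatments = the 3 observers; within-block ranks weighted by the
   ranks of block ranges, F-approximation with (k−1, (n−1)(k−1)) df;
   internally constant blocks ⇒ p = 1), ranked high→low p. The
   implementation was validated against base-R `quade.test`.
4. **Discriminative power**: Kruskal–Wallis p across the three phenotype
   groups on dataset 1, observer 1 (config-switchable), ranked low→high.

The final score is the unweighted mean of the four ranks; ties break by
the stability rank, then name. The best-final-ranked feature of each
biomarker class forms the candidate signature; Pearson correlations on
dataset-1/observer-1 values are examined and, while any pair exceeds
|r| = 0.75, the worse-ranked member of the most-correlated offending
pair is replaced by the next feature of its class. The loop terminates
(each replacement moves strictly down one class's ranking) or fails
loudly when a class is exhausted.

## Classification and clustering (`classify`)

* **z-scoring**: per-column (x−mean)/sd; constant columns map to 0.
* **SVM**: linear kernel, C = 1, one-vs-one multiclass; stratified
  4-fold cross-validation with a seeded shuffle (plain folds when a
  class has fewer members than folds). Held-out predictions are pooled
  into one confusion matrix; accuracy = trace/n.
* **Wilson score interval** for the accuracy:
  centre = (p̂ + z²/2n)/(1+z²/n),
  half-width = z·sqrt(p̂(1−p̂)/n + z²/4n²)/(1+z²/n).
* **Clustering**: agglomerative, Euclidean distance, average (UPGMA)
  linkage, cut to 3 clusters. Enrichment: per cluster an exact
  multinomial test of the phenotype composition against overall
  frequencies (p = total probability of outcomes no more likely than
  observed, full enumeration); post-hoc per-(cluster, phenotype) exact
  binomial tests; Bonferroni over all post-hoc tests.
* **Group differences**: Tukey HSD via the studentized-range
  distribution.

## Problem sizes and runtimes

The default study (56 scans × 3 observers = 168 extractions at 128×128,
60 frames) extracts in ~30 s and the complete
simulate→extract→select→classify→cluster run takes about one minute on
one core. `scripts/acceptance.py` re-runs exactly this chain from
scratch for a given seed. The test suite uses the default study once
(session fixture) plus reduced 64×64 studies for end-to-end plumbing.

## Known limitations

* The phantom's noise model is a surrogate; absolute feature values have
  no physical calibration (velocity is in units of beam width/s).
* The GLCM/GLRLM/first-order catalogue follows the common radiomics
  definitions, but naming and degenerate-case conventions differ across
  ecosystems; the exact lists above are the package's frozen contract.
* Feature rankings are univariate; no multivariate or wrapper selection
  is attempted, and no hyperparameter search is performed for the SVM.
* The default class separation is generous: the cross-validated accuracy
  on the default phantom study is typically higher than what real
  inter-animal variability would allow.
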