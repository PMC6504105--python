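# Methods

`radstab` implements a two-part analysis of radiomic features on
respiratory-sorted (4D) CT of lung tumors: (1) quantifying each
feature's stability across breathing phases, and (2) measuring whether
pre-excluding phase-unstable features improves bootstrap out-of-bag
prediction of overall survival. Because no patient data ship with the
package, a synthetic-data module generates every input with known
ground truth; this note records the models, conventions and numerical
choices, and what the synthetic studies do and do not demonstrate.

## 1. Phase stability

For patient *p* and feature *f*, values across the breathing phases
(default 8) are summarized by the coefficient of variation

COV = |SD / mean| x 100 (percent),

with the *sample* SD (n-1 denominator; the usual estimator in small-n
stability studies). The per-feature population mean COV (average over
patients) drives a four-tier categorization — Very Small (COV <= 5%),
Small (5 < COV <= 10), Intermediate (10 < COV <= 20), Large (> 20) —
and a five-bin histogram that splits the Intermediate tier at 15%.
All boundaries are right-closed exactly as stated.

Degenerate input: a feature whose phase mean is exactly zero has an
undefined COV. We return NaN (never 0 or inf), exclude it from the
population mean with a reported exclusion count, and categorize it as
Large — silently dropping such features would bias the "stable" counts
upward. An exactly constant series has COV 0 by definition, bypassing
floating-point jitter in the mean.

Tumor motion magnitude is the maximum pairwise 3D Euclidean distance
between the phase centroids (28 pairs at 8 phases, brute force). The
patient-by-feature COV heatmap clusters features by complete-linkage
hierarchical clustering on Euclidean distances, with COVs capped at 20%
(the display scale saturates there; undefined values are imputed at the
cap so the linkage is defined), and orders patients by ascending motion
magnitude with ties broken by patient id. Whether the original display
clustered capped or raw COVs is not documented anywhere we could rely
on; capping is our choice and is applied consistently.

## 2. Feature panel

The catalog enumerates the standard 841-feature panel: 105 original
features in 7 IBSI classes (13 Shape, 18 FirstOrder, 23 GLCM, 14 GLDM,
16 GLRLM, 16 GLSZM, 5 NGTDM) plus all classes except Shape recomputed
on the 8 single-level wavelet subbands (8 x 92 = 736). The extractor
computes Shape, FirstOrder and GLCM (54 original features, optionally
FirstOrder+GLCM per subband); the other classes are cataloged for
bookkeeping and raise `NotComputableError` if extraction is requested —
an honest scope boundary that keeps all counts testable.

Preprocessing: linear resampling of intensities to 3x3x3 mm voxels
(nearest-neighbor for the mask; SimpleITK), then fixed-bin-width
discretization with width 25 anchored at the ROI minimum,
level(v) = floor((v - min)/25) + 1. Resampling is skipped when the
input is already on the target grid, which keeps whole-voxel
translation invariance exact.

Conventions where the field admits variants:

* **Shape.** Volume = voxel count x voxel volume. Surface area comes
  from a marching-cubes mesh of the mask (scikit-image): counting
  exposed voxel faces overstates a sphere's area by roughly 50% and
  would break the Sphericity -> 1 sphere limit. Diameters are maximum
  pairwise distances between surface-voxel centers (convex-hull pruned);
  axis lengths are 4*sqrt(lambda) from the physical voxel-center
  covariance (ddof=1), Elongation = sqrt(l2/l1), Flatness = sqrt(l3/l1).
* **GLCM.** Distance 1, the 13 unique 3D directions, symmetric
  accumulation restricted to in-mask pairs, per-direction normalization,
  then feature averaging over directions with at least one pair. Ng in
  the normalized homogeneity variants (IDN/IDMN) is the highest occupied
  level. A single-gray-level ROI leaves Correlation/IMC1/IMC2 undefined:
  NaN plus a warning, never a silent 0.
* **Wavelets.** Single-level undecimated separable decomposition so the
  8 subbands stay aligned with the mask. Filter taps come from
  PyWavelets (default Haar; any orthonormal kernel accepted), rescaled
  by 1/sqrt(2) per axis; with circular boundary handling an orthonormal
  kernel then partitions the input energy exactly across the subbands
  (a property the tests verify). Subband labels LLL..HHH follow
  lexicographic {L,H}^3 order, letter k = filter on axis k.
* **First order.** Entropy (base 2) and Uniformity use the discretized
  histogram; Kurtosis is uncorrected (Gaussian -> 3); Skewness/Kurtosis
  of a constant ROI are defined as 0.

## 3. Cohort clustering

Features are split at population COV 5% into Stable and Unstable
(undefined -> Unstable). Patients are clustered on the Stable block
only: per-feature z-scoring, then average-linkage hierarchical
clustering on Euclidean distances, dendrogram cut at k = 3 clusters
(cutree semantics — the published analysis reports three clusters with
no height rule). Radiomic features have wildly different units, so
clustering unscaled values would be dominated by a handful of
large-magnitude features; z-scoring is our choice and may alter cluster
membership relative to an unscaled analysis. The Unstable block gets
its own feature dendrogram but reuses the patient order. Associations
between cluster labels and clinical parameters use Kruskal-Wallis for
pack-years and chi-square independence tests without continuity
correction for the categorical parameters, warning when any expected
cell count is below 5 (no automatic switch to exact tests).

## 4. Survival pipeline

The cohort is patients x features with right-censored overall survival
(months). The model-development procedure for one configuration
(cov_cutoff, p_cutoff, q_cutoff):

1. **Screening** (once, on the full cohort): univariate Cox per feature;
   keep features with Wald P < p_cutoff and Benjamini-Hochberg
   Q < q_cutoff; then drop features with 4D COV > cov_cutoff (skipped
   for the no-pre-selection reference). An empty pool marks the
   configuration infeasible. A flag can move screening inside the
   bootstrap rounds to expose the leakage difference; the default
   mirrors the published once-on-the-full-cohort order.
2. **Bootstrap rounds** (default 500; per-round RNG streams derived from
   the master seed by counter, so rounds are order-independent and runs
   are bit-reproducible): draw n patients with replacement (in-bag);
   the never-drawn patients are the out-of-bag (OOB) test set. Rounds
   whose OOB set has fewer than 2 patients or no event are non-evaluable.
3. **In-bag ranking**: one univariate Cox fit per pool feature on the
   in-bag sample; patients are scored, split at the in-bag median score,
   and the in-bag logrank chi-square ranks the features. (The published
   univariate stage ranks by the median chi-square over its own 500-round
   bootstrap; inside the multiple-regression rounds a nested bootstrap
   would square the cost, so each round uses its single-pass analogue.
   `rank_features_bootstrap` implements the standalone multi-round
   univariate ranking, scoring all patients and splitting at the
   whole-cohort median, as in the published univariate evaluation.)
4. **Redundancy filter**: walk down the ranking, keep a feature iff its
   absolute full-cohort Pearson correlation with every kept feature is
   <= 0.75 (sign ignored: a negative duplicate is equally redundant),
   stop at the maximum model size (default 3 — the published optimal
   model had 3 features and no stopping rule is documented).
5. **Model and evaluation**: multiple Cox fit (Breslow ties; Efron
   available) on the in-bag sample; OOB patients are scored and split at
   the *in-bag* median risk score (using the whole-cohort median here
   would leak test information; the published text specifies the
   whole-cohort median only for the univariate stage, so this is left
   switchable via `oob_median`); the OOB two-group logrank chi-square is
   the round's performance.

Two configurations are compared by a one-tailed Welch t-test on the
natural log of the per-round chi-squares (alternative: pre-selected
better), dropping non-evaluable and exactly-zero rounds with reported
counts and requiring at least 3 rounds per side. Significance stars:
*** P < 1e-5, ** P < 1e-3, * P < 0.05. The cutoff grid crosses COV
cutoffs {5,10,15,20,25, none} with (P,Q) pairs {(0.005,0.04),
(0.007,0.045), (0.01,0.05), (0.03,0.07), (0.05,0.09)}; every cell and
its no-COV twin share the same master seed, so the comparison is paired
on identical bootstrap draws (a variance-reduction choice; the Welch
test ignores the pairing and is if anything conservative).

Numerics: the Cox partial likelihood is maximized by Newton-Raphson
with step-halving; the univariate screening/ranking path is vectorized
across features sharing one risk-set structure (suffix-sum risk sets),
which is what makes 500-round grids tractable on one CPU. Monotone
likelihoods (perfect separation) are capped at |beta| = 15 and flagged.
The logrank statistic is (sum(O-E))^2 / sum(V) over distinct event
times with the hypergeometric variance. Both are cross-checked in the
tests against lifelines and against brute-force/hand-tabulated oracles.

## 5. Synthetic data: what it emulates, and what it does not

* **Phase tensors.** Patient-level means mu_pf are log-normal across
  patients (median 100, log-sd 0.4 — the marginal distributions of real
  radiomic features are unknown; this is a stand-in, not a claim);
  phase values are Gaussian around mu_pf with sd = mu_pf x COV/100,
  redrawn (not clipped) to stay positive. At the study scale (20
  patients, 8 phases) the sample COV estimator has bias factor
  c4(8) ~ 0.965 and per-patient sd ~ COV/3.7, which fixes the
  Monte-Carlo tolerances used in the tests.
* **Motion.** A pure superior-inferior sinusoid sampled at the phase
  fractions, rescaled so the maximum pairwise excursion equals the
  requested magnitude exactly; defaults span 1-30 mm, the published
  observed range. No hysteresis, no deformation.
* **4D images.** A textured ellipsoid (smoothed Gaussian random field,
  default ~45 HU-equivalent texture sd on a -800/+60 background/tumor
  contrast) translated rigidly per phase with offsets snapped to whole
  voxels; with zero added noise every phase is an exact translation, so
  the end-to-end extractor COV is 0 — this validates the plumbing and
  the translation invariance of the features, not robustness to
  interpolation, deformation or CT artifacts, which real 4D data have.
* **Survival cohorts.** Each feature observes a standard-normal latent
  signal through additive "motion noise" with sd = 0.05 x COV(%): a
  COV-3% feature is a nearly clean measurement, a COV-30% feature
  carries 1.5 sd of noise. Event times follow a Weibull
  proportional-hazards model (scale 30 months, shape 1.2 — median
  survival near the published cohort when moderate hazards act) whose
  linear predictor uses the *clean* signals: motion noise dilutes the
  observed predictor rather than being prognostic itself, which is the
  mechanism by which unstable features degrade prediction. Censoring is
  independent exponential with its rate bisected against the realized
  event times to hit the requested censored fraction (default 0.59,
  matching the published 41% death rate); achievable accuracy is ~1/n.
  Clinical covariates are drawn from categorical/continuous
  distributions matching the published cohort mix and are independent
  of the features unless a flag plants an ECOG-cluster association or
  patient groups with shifted latent means (for the clustering tests).
* **The planted comparison design** (`planted_survival_spec`): three
  predictive latents (beta = 1.0 each, hazard ratio e per SD — a strong
  signature, consistent with the very large published model-comparison
  effect) observed cleanly at COV 3% and through noisy proxies at COV
  8/15/22/30%, plus stable and unstable null features. Raising the COV
  cutoff admits noisier proxies that can outrank the clean features
  in-bag and displace them through the redundancy filter, degrading OOB
  performance — reproducing the direction and monotone pattern of the
  published grid. The effect sizes were calibrated once to the
  detection margins the design targets and then frozen.

Passing tests on these generators show that the *pipeline* recovers
planted truth under its own assumptions (Gaussian phase noise, rigid
motion, proportional hazards, independent censoring); they say nothing
about segmentation uncertainty, scanner effects, non-proportional
hazards, or the marginal distributions of real features.

## 6. Problem sizes and defaults

Default study sizes mirror the published design: 20 patients x 8 phases
for stability, 140 patients for survival, 500 bootstrap rounds in the
CLI defaults. The repeated-measurement studies in the test suite use
100-round bootstraps and 50-200 meta-replicates — sizes chosen so the
Monte-Carlo standard error is comfortably below the margins being
asserted. Seeds: every generator and bootstrap derives per-stream RNGs
from a master seed via `numpy` SeedSequence with counter spawn keys;
identical seeds give bit-identical outputs.

## 7. Known limitations

* GLDM/GLRLM/GLSZM/NGTDM values are not computed (catalog-only), and no
  numerical parity with any existing radiomics extractor is attempted;
  conventions left open by the common descriptions (GLCM aggregation,
  wavelet kernel, bin anchoring) are fixed as documented above.
* The image generator cannot produce sub-voxel motion, deformable
  tumors, or CT artifacts.
* The comparison t-test treats paired configurations as independent
  samples (conservative under the shared-seed pairing).
* Undefined-COV handling (sentinel -> Large/Unstable) is a policy
  choice; alternatives would change category counts for pathological
  features.
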