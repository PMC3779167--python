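# Methods

## The analysis model

The package treats each subject's Belief>Photo contrast map as a 3-D
statistic volume (T units) on an MNI-affine grid, carrying the degrees
of freedom of the first-level statistic so that p-value thresholds can
be converted to statistic cutoffs. All spatial reasoning is done in
world millimetres (center-to-center Euclidean distance), never in voxel
counts, so anisotropic grids behave correctly.

### Hypothesis spaces

Group random-effects maps are one-sample t-maps (t = mean/(SD/√n),
df = n − 1) over subject maps. A region's hypothesis space is the
connected suprathreshold component (one-sided p < 0.001 at the map's
df) containing the region's seed point — the canonical printed center,
e.g. RTPJ (54, −52, 23). If the seed voxel itself is subthreshold the
nearest suprathreshold voxel within a 12 mm search radius is used;
beyond that the region is reported as not extractable. Optional z-axis
clamps separate the three medial-prefrontal tiers (DMPFC z > 20 mm,
MMPFC 0 < z < 20 mm, VMPFC z < 0) and keep temporal regions above
z = 6 mm, mirroring how the published spaces are delimited. The seed
mechanism is a reproducible surrogate for the original by-inspection
choice of "the cluster representative of the ROI".

The cohort is split into two group-balanced halves (per-group sizes
differ by at most one; a 462/31 cohort splits 247/246 with ASD 16/15)
and spaces built from one half are applied only to subjects of the
other, an invariant asserted inside the pipeline.

### fROI definition

Candidate voxels within a space must exceed the p < 0.001 cutoff and
belong to a connected suprathreshold cluster of total size ≥ 11.
"Contiguous with at least 10 other voxels" is read transitively
(cluster extent), the standard SPM-era interpretation — a literal
10-neighbour rule would exclude any chain-shaped cluster. Cluster
membership is evaluated within the masked map (masking precedes
candidate identification); a flag switches to whole-map clusters
clipped to the space. The ROI is grown from the candidate with the
highest T (ties broken by lowest linear voxel index, making results
order- and seed-independent): the peak plus every candidate within
9 mm (inclusive, Euclidean mm) connected to the peak through the
radius-restricted candidate set.

Parameters: voxel count, mean T, and T-weighted center of mass
Σ(T·x)/ΣT in mm. Not-found subjects get missing values (never zeros)
and are dropped listwise from continuous-parameter fits while remaining
in the found-flag fits — which is why the residual df differs between
the Gaussian and binomial rows of the group report.

### Reliability

Pearson correlation (Spearman by flag) between even-half and odd-half
parameter vectors over participants with the ROI found in both halves
(pairwise-complete is the only alignment-preserving option). The null
permutes the even-half vector across participants (default 5,000
permutations). The rank counts null values strictly below the observed
correlation, with ties at half weight (mid-rank convention, unbiased
for discrete nulls); "reliable" means rank > 90. Fewer than three
complete pairs, or a zero-variance half, yields an insufficient-data
flag rather than a number.

### Group GLM

Continuous parameters: ordinary least squares on the mean-centered
design (intercept uncentered); coefficient t = β/se at df = n − p,
two-sided p. Found-flag: binomial GLM with logit link via IRLS
(statsmodels); Wald z = β/se referred to the standard normal, df
reported for bookkeeping. This pairing — t reference for Gaussian fits,
normal reference for logit fits — is the only one that reproduces the
worked-example corrected p-values 0.008/0.01 (t-based) and 0.03/0.02
(normal-based) simultaneously. Categorical predictors are coded 0/1;
task type is one integer-coded column {TF=0, FITB=1, MTS=2} by default,
preserving the nine-column design, with dummy coding available.
Degenerate (constant) columns are dropped with a warning; rank
deficiency and perfect separation raise instead of silently reporting.

The multiple-comparison adjustment is corrected p = 1 − (1 − p)^m (the
Šidák form). m = 6 corrects a predictor of interest over the six ROI
parameters of one region; m = 12 covers the two ADOS scores; m = 54
covers exploratory predictors (6 parameters × 9 predictors).
Uncorrected p < 0.01 is labelled a trend in reports.

99% confidence intervals are recovered from (β, statistic, df) as
β ∓ q·β/statistic with q the 0.995 t-quantile (normal quantile for
logit fits).

### JZS Bayes factor

BF01 for a coefficient uses the two-sample Jeffreys–Zellner–Siow form:
under H1 the standardized effect has a Cauchy(0, r) prior, equivalent
to a normal prior with inverse-chi-square mixing variable g,

    BF10 = ∫₀^∞ (1+Ng)^{-1/2} (1 + t²/((1+Ng)ν))^{-(ν+1)/2}
           (2π)^{-1/2} r g^{-3/2} e^{-r²/(2g)} dg
           ÷ (1 + t²/ν)^{-(ν+1)/2}

with ν the residual df and effective sample size N = n1·n2/(n1+n2)
from the two group counts entering the fit — the standard adaptation
when the t comes from a multi-regressor GLM. The integral is evaluated
with adaptive quadrature in log space (rel. tolerance 1e-10;
non-convergence raises with diagnostics). The default prior scale is
r = 1, the classical default; with it the worked examples reproduce the
published values to three decimals (4.049 vs 4.048; 6.450 vs 6.450).
Tests cross-check against an independent fixed-grid quadrature with a
compactifying substitution g = z/(1−z).

### Collinearity and outliers

Belsley diagnosis: columns scaled to unit length, SVD, condition
indices σ_max/σ_k, and per-predictor variance-decomposition proportions
from squared right-singular-vector loadings over squared singular
values. A (predictor, index) pair is flagged when the proportion
exceeds 0.5 at a condition index above 30 (the MATLAB `collintest`
tolerances). The outlier screen standardizes ASD values by the NT mean
and SD and flags |z| > 3.

### Matched-sample permutation tests

Greedy nearest-neighbour matching pairs each ASD subject with an unused
NT control of the same gender, coil, modality and task, within ±5 years
of age and ±10 IQ points (cost = normalized age + IQ distance);
unmatched ASD subjects are dropped with a log line, and the tolerances
are asserted on every emitted pair.

The mean test computes a Student (equal-variance) two-sample t-test p
per parameter (Welch by flag; the permutation reference makes the
choice second-order), including the found-flag as a 0/1 proportion
test. Group labels are permuted (25,000 by default, sampled uniformly
and independently, seeded); all null p-values of a region are pooled
and sorted and the empirical familywise alpha is the (5/family_size)
percentile — 0.83% for the six-parameter family, as a lower order
statistic so the alpha is an attained null p-value. The variance test
substitutes the Ansari–Bradley statistic and omits the found-flag
(mean and variance of a 0/1 vector are functionally tied), giving
family size 5 and the 1% percentile. Pooling all parameters' nulls
into one vector (rather than per-parameter nulls with a shared cutoff)
follows the procedure's description as written.

Ansari–Bradley implementation: scores rank the pooled sample from both
ends inward (score min(i, n+1−i), mid-rank averaged within ties); the
statistic is the score sum over the first sample. Exact p by full
enumeration for pooled n ≤ 16; otherwise a normal approximation whose
moments come from finite-population sampling theory of a linear rank
statistic (reducing to the classical tie-free formulas). Inside the
permutation loop the scores are fixed, so null statistics are computed
for all permutations with one matrix product.

### Whole-brain split-half procedure

Voxelwise group-difference t-maps (pooled-variance two-sample t, or the
group coefficient of a per-voxel OLS when nuisance covariates are
supplied); clusters at one-sided p < 0.001 with a configurable minimum
size (30 for descriptive cluster tables; 0 for the split-half search,
which published a 14-voxel cluster). Each cluster discovered in one
run-half is validated by extracting its mean contrast per subject in
the other half and requiring a same-direction two-sample difference at
p < 0.05. Clusters carry their discovery-half tag and the validator
refuses a same-half validation. The externally-implemented corrected
whole-brain analysis (variance smoothing with combined voxel-cluster
inference) is out of scope; a max-statistic label-permutation threshold
is provided as the corrected alternative.

## The synthetic cohort generator

`generate_cohort` emulates the aggregated localizer study's covariate
structure: 462 NT / 31 ASD by default, 197/26 male, 74 of 493 on the
32-channel coil, 420 visual vs 73 auditory, task mixture 304/101/88
(TF/FITB/MTS), NT ages ~24.4 (SD 7.4) vs ASD ~32.5 (SD 12.4) truncated
to 18–69, IQ ~117 (SD 13) recorded for a subset (61 NT, 30 of 31 ASD),
and ADOS communication ~3.2 (1.3) / social ~5.9 (2.1) scores for ASD
only. Categorical marginals match their configured counts exactly
(largest-remainder rounding, shuffled assignment); covariates are
drawn independently of each other, which real aggregated cohorts are
not (e.g. coil correlates with task variant) — a deliberate
simplification.

`simulate_subject_maps` plants one isotropic Gaussian blob per region
at the seven canonical centers. Per subject and region the amplitude is
base + group_delta·1[ASD] + Σ slope·(covariate − cohort mean) +
N(0, subject_sd), and the center is jittered by isotropic N(0, 2 mm)
shared between the subject's two half-maps; the noise (SD 1 T,
optionally spatially smoothed and renormalized) is drawn independently
per half. Defaults: base amplitude 5 T, FWHM 16 mm, subject SD 0.7 T
(the observed between-subject spread of mean T is 0.5–1), jitter 2 mm.
The 16 mm width reflects the effective extent of a smoothed group
activation and yields found-rates near 90% on the default 4 mm grid,
matching the real-data range. Maps are generated directly at the
contrast level: no time series, hemodynamics, motion or physiological
artifacts, so passing tests validate the analysis logic, not robustness
to realistic fMRI noise structure. Ground truth (realized amplitudes
and centers) is recorded per subject and suffices to rebuild the
noiseless signal exactly; no analysis stage may consume it.

The default grid is 40×48×40 voxels at 4 mm (roughly MNI ±80/±96/±80),
with voxel (d//2) anchored at 0 mm so integer-mm region centers fall on
voxel centers; native acquisition resolution is unnecessary for testing
the logic.

## Problem sizes used in validation

The calibration and recovery studies in `tests/test_acceptance.py` run
at desk scale, chosen once as the package's own validation conditions:

* GLM type-I calibration: 200 replicate cohorts of 100 NT / 15 ASD,
  one region on a 16³ grid; familywise rate of corrected group
  p < 0.05 over the six parameters (m = 6) must stay ≤ 7%.
* Matched-test calibration: 200 replicates of a 27/27 cohort at
  parameter level, 2,000 permutations; per-region familywise error in
  [2%, 9%].
* Reliability calibration: 200 replicates of independent 100-subject
  halves, 500 permutations; verdict rate near the nominal 10%.
* Recovery: 100 high-SNR subjects (amplitude 5, noise SD 0.2) with the
  center of mass within 4 mm of the subject's true center ≥ 95% of the
  time; a planted 1.0 T group amplitude shift in a 27/27 cohort
  detected on ROI size (the parameter a uniform amplitude shift most
  directly enlarges under threshold-based ROI definition) in ≥ 80% of
  100 replicates; a bimodal ±1 T ASD arm flagged by the variance test
  but not the mean test in a majority of 50 replicates.

## Numerical choices

* Connectivity defaults to 26 (faces+edges+corners) everywhere and is
  configurable {6, 18, 26}; the convention of the original cluster
  definitions is not recorded, so it is exposed rather than guessed.
* Zero-variance voxels in t-maps: t = 0 when the mean is also 0, else
  signed infinity.
* Peak ties: lowest linear voxel index, deterministic.
* The 9 mm growth radius is inclusive (≤) and Euclidean in mm; whether
  the original used a voxel-count proxy is unknown.
* Permutation tests sample random permutations (not exhaustive
  enumeration) and are reproducible under a fixed seed; every stage
  seed is explicit in the pipeline config and recorded in the manifest.
* NIfTI I/O: masks as uint8 0/1, statistic maps as float32 (float64
  inputs kept at float64 so round trips are bit-exact); df stored in
  the header description field.

## Known limitations

* The generator's blobs are isotropic and unimodal; real ToM regions
  (especially RSTS) are elongated, so position parameters are easier
  here than in practice.
* Real-data quantities (per-region found-rates, reliability r values,
  cluster tables) are data-dependent and are not reproduction targets.
* The binomial GLM reports df = n − p for bookkeeping only; inference
  is asymptotic (Wald).
* Greedy matching is order-dependent and not guaranteed maximal; with
  sparse IQ coverage few pairs may form, and small matched samples can
  leave the GLM under-determined (reported as warnings, not results).
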