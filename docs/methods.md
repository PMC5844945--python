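# Methods

This note records the models, conventions, numerical choices and known
limitations behind `xeromics`.  It is the place where design decisions that
were genuinely open are written down.

## Geometry and lateralization

All volumes live on regular lattices in LPS axis order (x: right→left,
y: anterior→posterior, z: inferior→superior), with coordinates in mm and
dose in Gy; array index `(i, j, k)` maps to `origin + spacing * (i, j, k)`.
Grids are trilinearly resampled to isotropic resolution (1 mm by default)
before extraction; the resampled lattice keeps the original origin and
covers the original voxel-center extent to within one voxel.  Masks are
resampled by thresholding the trilinearly interpolated 0/1 field at 0.5
(equivalently nearest-neighbour at voxel centers), which keeps them binary;
when contours are available they can instead be re-rasterized at the target
resolution (voxel-center, even-odd rule).

Glands are analyzed as ipsi-/contralateral.  When the right gland's mean
dose strictly exceeds the left's, all volumes are mirrored through the
sagittal plane (index reversal along x) so that the ipsilateral gland sits
on a common side across the cohort.  Ties do not flip — the rule is strict,
which makes lateralization idempotent: a lateralized cohort never flips
again.  Mirroring is pure index reversal; since every coordinate-based
feature is translation-invariant, the unchanged origin is immaterial.

## Feature definitions

Exact formulas, since several variants circulate:

* sphericity = π^(1/3) (6V)^(2/3) / A, compactness = V / (√π A^(3/2)),
  eccentricity = √(1 − λ₃/λ₁), with λ the descending eigenvalues (mm²) of
  the covariance of mask voxel-center coordinates.  λ as covariance
  eigenvalues (not semi-axis lengths) is a deliberate choice; the two are
  related by a constant factor for ellipsoids.  The surface A comes from a
  marching-cubes mesh of the mask; the binary field is smoothed with a
  σ = 1 voxel Gaussian before meshing because the raw 0.5 level set is a
  voxel staircase that overestimates A by ~8% (a digitized r = 20 mm ball
  then scores sphericity within [0.95, 1.05]).
* Dx is the smallest dose received by at least x% of the gland volume —
  the (100−x)th linearly interpolated percentile of the within-mask dose;
  Vx is the volume *fraction* (0–1) at ≥ x Gy.  DVH entropy (bits, −Σp log₂p)
  and uniformity (Σp²) use fixed 1-Gy bins from 0 to the maximum dose:
  resolution-independent and reproducible.
* Subvolume mean doses cut the mask bounding box into three equal-width
  slabs per axis (remainder voxels join the last slab — the simplest
  deterministic rule) and average the dose over mask voxels per slab.
* Dose gradients are the least-squares affine fit D ≈ a + g·r over mask
  voxel centers, in Gy/mm.
* Dose moments are dose-weighted over mask voxels (not over a bounding
  region): η_pqr = μ_pqr / μ₀₀₀^(1+(p+q+r)/3) with central moments about the
  dose-weighted centroid.  This normalization makes η invariant under
  translation and under joint rescaling of dose and geometry.  All sixteen
  orders through total order 3 are reported; the morphological reference
  model uses (η₁₁₁ⁱ, η₀₀₂ᶜ, η₃₀₀ᶜ, η₁₁₀ⁱ·η₁₁₀ᶜ).

The redundancy filter computes Kendall's τ-b for every feature pair,
separately in the two glands, and calls a pair redundant when |τ| > 0.5 on
both sides (corresponding to 75% concordance probability, (1+τ)/2).  The
retained member is the conceptually simpler one, encoded in an explicit
priority ranking (mean dose before Dx, volume before compactness, …) that
callers can replace.

## End points

Follow-up grades (CTCAE dry mouth 0–3) are aggregated into three
time-specific windows — (0, 6], (6, 15], (15, 24] months for early, late,
long-term — by the arithmetic mean rounded half-up; the event is grade ≥ 2.
Windows are half-open with the boundary visit assigned downward (a 6-month
visit is "early"); the convention is arbitrary but fixed and documented.
The longitudinal end point instead keeps one observation per visit, labels
it by that visit's own grade, and carries the visit time (months) as an
ordinary model covariate.

## Univariate screen

Features are z-scored (population SD) for consistency with the multivariate
pipeline — a no-op for the rank statistics.  Discrimination is the AUC
derived from the Mann–Whitney U with midranks, AUC = U/(n₋n₊); the screen
reports the *oriented* AUC (≥ 0.5) with a direction flag, because protective
features (e.g. large parotid volume) are as interesting as risk features and
their directional AUC would sit below 0.5.  Confidence intervals are 95%
BCa bootstrap (scipy's implementation), stratified by class so every
replicate keeps both classes; B = 2000 by default.  Two-sided p-values use
the tie- and continuity-corrected normal approximation, appropriate at
n ≈ 100–150.  Multiplicity is controlled by the adaptive step-down
procedure with critical constants c_i = i·q / (m + 1 − i(1 − q)), which
rejects the largest prefix of sorted p-values passing all its constants;
under a 200-feature global null at n = 150 the observed FDR stays below
0.07 (test suite).  Tolerance values TVp = (logit p − β₀)/β₁ come from a
univariate logistic fit on the *raw* feature so they carry its units; a
slope numerically near zero raises instead of reporting a meaningless TV.
Truth bounds for R discoveries at level q treat each discovery as
independently false with probability q: P(all true) = (1−q)^R,
P(≤1 false) = (1−q)^R + Rq(1−q)^(R−1).

## Multivariate pipeline

The workflow is feature-group selection → z-scoring → sampling → feature
selection → classification.  Group selection keeps each of the nine groups
by an independent fair-coin-style Bernoulli trial (p = 0.5), repeating the
whole round if nothing survives.  The sampler vocabulary counts ten options
because explicit "no sampling" is one of them — that convention is what
makes the model-space arithmetic 7 × 7 × 10 = 490 per end point.  The
samplers themselves (ROS, SMOTE, ADASYN, OSS, TL, ENN, NCL and the two
SMOTE combinations) are implemented in-package from their literature
definitions, since no imbalance library is a dependency; SMOTE/ADASYN use
k = 5 minority neighbours (reduced with a warning when the minority class
is smaller), ENN edits majority points misclassified by their 3 nearest
neighbours, and cleaning methods never remove minority observations.

Hyperparameter spaces are package defaults, overridable per run: penalty
strength log-uniform 10⁻³–10³, elastic-net mixing uniform 0–1, kNN
neighbours 1–30, RBF width log-uniform 10⁻⁴–10, tree ensembles 50–500 trees
of depth 2–8 with log-uniform learning rate 0.01–0.3, selector size uniform
1–min(15, d).  Random search draws n candidates (300 by default), scores
each by cross-validated AUC on a shared set of splits, and retrains the
winner (ties: first drawn, for determinism) on all data.

Cross-validation is stratified MCCV (default 300 splits, 10% test, test
class ratio within one observation of the cohort's) for time-specific end
points, and modified LPOCV for the longitudinal one: each split tests one
positive and one negative observation from different patients and removes
from training *every* observation sharing a patient id with either — visits
of one patient differ only in time, and leaving them in would leak.  The
LPOCV AUC is the fraction of pairs ranked correctly (ties = ½) over a
random subset of pairs (default 300).  Scaler, sampler and selector are fit
inside each training fold only.

Nested CV reruns the entire random search inside every outer training fold
(outer default: 100-split MCCV or LPOCV) and aggregates outer-fold scores
into the generalization AUC with a BCa interval over per-fold scores.  The
comparison of tuning versus generalization AUC measures the optimism of
single-CV tuning; on synthetic cohorts its mean is positive (test suite),
matching the expectation that hyperparameter selection inflates single-CV
scores.

Fixed reference configurations (four mean-dose logistic models — ipsi,
contra, volume-weighted both, bivariate — and the four-moment morphological
model) are provided so the classical baselines can be evaluated on any
cohort through the same machinery.

## Algorithm comparison

Per family (classifiers, selectors, samplers; time-specific vs longitudinal
contexts) scores are ranked within each context (midranks on ties) and
tested with the classic Friedman chi-square
χ²_F = 12N/(k(k+1)) [Σ R̄_j² − k(k+1)²/4] on k−1 degrees of freedom — the
chi-square form rather than the Iman–Davenport F, as the simpler, directly
testable statement.  Pairwise separation uses the Nemenyi critical
difference CD = q_α √(k(k+1)/6N) with q_α the studentized-range quantile at
infinite df over √2, computed numerically (no hard-coded table; a small
reference table exists only in the tests).  The six family-level Friedman
p-values share one Holm–Bonferroni correction at FWER 0.05.  Win-proportion
matrices count head-to-head wins with ties worth ½, so M + Mᵀ = 1 off the
diagonal.

## Synthetic cohort generator

The generator emulates the structure of a realistic head-and-neck cohort:
153 patients by default on 1 mm isotropic grids; two mirrored ellipsoidal
parotids (semi-axes 8–18 mm with a shared per-patient size factor, volumes
roughly 5,000–35,000 mm³) centred ±25 mm from the midline; a composite dose
field made of per-gland affine patches joined at the midline, with
contralateral mean dose 5–28 Gy, ipsilateral excess 2–10 Gy, within-gland
lateral gradients of 1–2 Gy/mm pointing toward the midline, and 1.5 Gy
voxel noise; age ~ N(60, 9²) clipped to [25, 85] and 24% female; follow-up
visits at ~3-month jittered intervals over 0–24 months with 10% per-visit
dropout (at least one visit guaranteed).

Outcomes close the loop through the real extraction code: the linear
predictor applies the effect template — parotid volume protective, lateral
dose gradient and female sex adverse, plus a time slope — to *standardized
true features computed from the generated anatomy and dose*, and each
visit's grade is a Bernoulli draw of the logistic risk (grade 2/3 split
80/20 on events, grade 1/0 split 80/20 otherwise).  The default effect
sizes (intercept −3.5; volume −3.0, gradient +1.8, sex +0.7 per SD; time
+0.05/month) were fixed once so that the planted features reproduce
literature-scale univariate discrimination (oriented AUC ≈ 0.8–0.85 for
volume at n = 150) and realistic window prevalences (~20–30%); the latent
linear predictor is stored per patient for recovery tests but never enters
a feature table.

What the generator does **not** emulate: real parotid shapes (ellipsoids
only), CT texture, dose fields of actual treatment plans (affine patches
with Gaussian noise), gland shrinkage/motion over the treatment course, or
correlated missingness in follow-up.  Passing recovery tests therefore show
that the pipeline recovers effects *of the kind planted* at realistic n and
noise — not that clinical cohorts behave this way.

## Problem sizes in the validation suite

The shipped tests run the full chain at demonstration scale, chosen as the
package's own validation budget: cohorts of 60–150 patients at 2 mm
spacing, random search with 3–10 draws over 10–15 inner splits, 8–30 outer
splits, and 200–500 bootstrap replicates.  Null-calibration suites use 200
replicates (FDR) and 500 replicates (Friedman type-I).  Paper-scale sweeps
(300 search draws × 300 splits × 1,960 configurations) use identical code
paths and are reachable through the CLI budget flags; they are cluster-scale
work by construction, not validated here.

## Known limitations

* BCa intervals on LPOCV pair indicators treat pairs as exchangeable; pairs
  sharing a patient are mildly dependent, so those intervals are slightly
  narrow.
* MCCV outer folds at n ≈ 35–100 contain few positives; per-fold AUCs are
  coarse, and generalization estimates inherit that granularity.
* The GBS critical constants assume the step-down's standard regularity
  conditions (independent or positively dependent p-values); heavily
  correlated radiomic features push it toward conservatism rather than
  anti-conservatism in our null simulations.
* DICOM support covers axis-aligned RTDOSE/RTSTRUCT objects; oblique
  orientations are rejected explicitly rather than silently resampled.
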