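# Methods

## The generative model

`eigensynth` synthesizes functional brain images (PET/SPECT) that are new
draws from the population a co-registered cohort was sampled from. The
model has three stages.

**Eigenbrain decomposition.** The cohort is a matrix `X` of K subjects by
N in-mask voxels. After subtracting the dataset-global voxelwise mean,
the centered matrix is factored by economy singular value decomposition,
`X_c = U S V^T`. The columns of `W = V` are the *eigenbrains* — an
orthonormal basis of inter-subject variance modes — and the latent scores
are `S_L = X_c W_L` for a truncation `L ≤ rank(X_c) ≤ K − 1`. Because `W`
is orthonormal, the inverse map is the transpose: a score vector `s`
becomes the image `s W_L^T + mean`. The full N×N covariance is never
formed, so N in the millions is fine; cost is O(K²N).

Centering uses the *global* mean, not per-class means, because the basis
is deliberately a common reference for all classes; class structure lives
in the score distributions. The mean is re-added at reconstruction — the
inverse transform is only exact with it. Eigenbrain signs are fixed so
each column's largest-magnitude loading is positive, making bases
reproducible across SVD implementations.

**Per-class latent density.** Scores of each class c are modeled by one
of two estimators:

* *MVN*: a multivariate normal `N(μ^c, Σ^c)` where
  `Σ^c = (1−α) Σ_emp + α (tr(Σ_emp)/L) I`. The intensity α ∈ [0,1] is
  the Ledoit–Wolf minimum-MSE estimate (scaled-identity target,
  maximum-likelihood empirical covariance, i.e. divide-by-K_c — the
  Ledoit–Wolf convention). Shrinkage compresses the eigenvalue spread of
  `Σ_emp`, so `Σ^c` is positive definite even with fewer subjects than
  components. Note that α is not an error gauge: when the true covariance
  is close to isotropic, the optimal α is close to 1 by construction.
  The density normalizer uses the latent dimension L in `(2π)^{L/2}`.
* *KDE*: an independent Gaussian kernel density per component,
  `f(x) = (1/K_c h) Σ_i G((x − s_i)/h)`, with the bandwidth h selected by
  the diffusion (improved Sheather–Jones) fixed point: the data are
  binned on a 2^14-point grid spanning the component range padded by 10%,
  the characteristic-space fixed point `t = ξ γ^[5](t)` is solved by
  bracketed root finding to 1e-9, and `h = √t · range`. For small or
  pathological samples the fixed point may have no root; the estimator
  then falls back to the normal-reference rule `1.06 σ̂ K_c^{-1/5}` with a
  logged warning. Treating components independently discards
  cross-component dependence; PCA scores are uncorrelated (not
  independent), and the univariate KDE in exchange captures skew and
  heavy tails that a Gaussian cannot.

All densities are evaluated in log space internally.

**Sampling and reconstruction.** For the KDE, each component's PDF is
integrated (cumulative trapezoid, grid of 4096 points over the data range
± 6h, renormalized to end at exactly 1) into a tabulated CDF; uniform
variates are mapped through the inverse by linear interpolation, with
flat CDF runs collapsed so the interpolant is single-valued. Components
use independent uniform streams, consistent with the independence
assumption. For the MVN the draw is direct, `μ + C z` with `C` the
Cholesky factor — per-coordinate CDF inversion would destroy exactly the
cross-component correlations the MVN exists to keep. Sampled score
vectors are mapped back through the basis with the mean re-added;
clipping of negative voxels is available but off by default (it breaks
the exactness of the inverse transform and is meant for export to
viewers).

A consequence worth knowing: KDE sampling is distributionally identical
to a smoothed bootstrap (random data point + h·noise). Synthetic
marginals therefore inherit the fitting sample's empirical distribution
function and a variance inflation of `1 + h²/σ̂²`; at cohort-scale sample
sizes both are invisible, but a Kolmogorov–Smirnov test at 10⁴ draws can
detect them for some fitting samples. This is a property of kernel
density estimation itself, not of the inversion machinery (which is
exact; see the dual-route test in the unit suite).

## Preprocessing

Each subject is divided by `I_n`, the mean of its top-fraction (default
3%) in-mask intensities, so the top-fraction mean becomes exactly 1.
The top count is `ceil(fraction · N)`, minimum one voxel, selected by
count on the sorted array (boundary ties resolved deterministically).
Normalization is per subject, hence leakage-free in cross-validation,
scale-equivariant, idempotent and rank-preserving. Whether the 3% is
taken over in-mask or all voxels is not standardized in the field;
in-mask is used here because out-of-mask background is zero by
construction.

## Validation battery

* **VAF classification** — linear-kernel SVM on raw voxel intensities,
  stratified outer folds (default 10), regularization constant C chosen
  per fold by an inner stratified grid search (default 5 folds, grid
  {0.01, 0.1, 1, 10, 100}) on the training portion only. The first-named
  (disease) class is the positive class for sensitivity. Fold assignment,
  synthesis draws and permutations use separately derived seeds. The
  solver runs with an iteration cap of 10⁵: training sets synthesized at
  small L are rank-deficient, and on such data the dual solver at large C
  can iterate near-indefinitely after the decision function has
  stabilized; the cap never binds in non-degenerate regimes.
* **Generalization experiment** — per outer fold, eigenbrains and
  densities are fitted on the real training portion only; 200 images per
  class (the harness default) are synthesized; the SVM trains on them and
  predicts the held-out real fold. The requested L is capped at the
  training-fold rank when necessary (logged).
* **Resubstitution experiment** — one classifier trained on all real
  data, evaluated on itself (resubstitution accuracy) and on repeated
  synthetic draws from a model of that same data. The gap quantifies the
  independence of the synthetic images.
* **Optimal-L rule** — the largest L whose generalization accuracy lies
  within one standard deviation of the real-data baseline; if no L
  qualifies, the closest one is returned with a warning.
* **t-maps** — per-voxel pooled-variance two-sample t (df = K_a+K_b−2;
  zero-variance voxels get t = 0), two-sided. Family-wise error control
  is Bonferroni (threshold = t quantile at α/N) or permutation maxT
  (threshold = the (1−α) empirical quantile, upper interpolation, of the
  max-|t| null over label permutations). Random-field-theory thresholds,
  as used by common SPM pipelines, require smoothness estimation that is
  out of scope; Bonferroni is conservative and maxT is exact under
  exchangeability.

## The phantom generator

Phantoms emulate the statistical structure the model assumes about
co-registered nuclear-imaging cohorts, not scanner physics. Each subject
volume is

    ellipsoidal unit-uptake template
    + class-effect spheres (center, radius, amplitude)
    + Σ_m c_m · mode_m,   c_m ~ N(0, latent_sd_m)
    + noise_sd · white noise,

then Gaussian-smoothed (σ = FWHM/2.3548, default FWHM 2 voxels) and
clipped at zero. The modes are smooth random fields normalized to unit
RMS inside the brain, so `latent_sd` is in intensity units. Optionally a
*pattern-jitter* mode is appended: the mean class-effect map itself,
unit-RMS normalized, with its own per-subject N(0, sd) coefficient in
every class. This models a disease-severity spectrum shared by the whole
cohort and gives the classes an irreducible overlap that no classifier
can shave off by using more voxels — without it, focal effects of any
amplitude become perfectly separable at realistic noise levels.

Two presets (default 24³ voxels, which keeps the full pipeline — SVD,
nested CV, permutations — fast enough for routine testing):

* *Three-class progressive disorder* (FDG-PET-like): NOR / MCI / AD at
  60 subjects per class; AD has three hypometabolic spheres (amplitudes
  −0.42, −0.42, −0.30 intensity units), MCI exactly half; eight latent
  modes (sd 0.45…0.10), pattern jitter sd 0.04, voxel noise sd 0.25.
  Calibrated once so the VAF baseline sits in the regime reported for
  real progressive cohorts: strong-vs-control ≈ 0.86, clearly above
  intermediate-vs-control ≈ 0.66, both below ceiling.
* *Two-class focal-deficit disorder* (DaTSCAN-like): NOR / PD at 60 per
  class; two bright striatum-like foci (NOR amplitudes 2.0/2.0, PD
  1.1/0.8 — reduced and asymmetric), six latent modes, pattern jitter sd
  0.066, noise sd 0.20. Deliberately at the separable extreme
  (baseline ≈ 0.99): the asymmetric component of the deficit is
  orthogonal to the shared jitter direction, so overlap stays small.

What passing on phantoms does *not* show: robustness to registration
error, scanner/site effects, non-Gaussian subject variability beyond the
clipping nonlinearity, or anatomical realism of the effect geometry.

## Numerical choices and degenerate inputs

* Rank is the count of singular values above `1e-10 · s_max`; identical
  images (rank 0) are an error; rank deficiency after centering is
  normal and logged, with the default L = min(K, rank).
* Basis orthonormality is enforced to 1e-8; full-rank reconstruction to
  1e-6 relative Frobenius error.
* A class needs ≥ 2 subjects for any density; a KDE component with all
  scores identical is a named degenerate error.
* Tabulated CDFs must start ≤ 1e-6 and end ≥ 1 − 1e-6 after
  renormalization; inverse sampling clamps u = 0 and u = 1 to the grid
  ends.
* Affines are compared at relative 1e-4 per entry; volumes are stored
  float32 (modality standard), computed float64.
* The implicit mask (no mask file given) keeps voxels strictly positive
  in at least one subject, appropriate for zero-background PET/SPECT.

## Measuring class-mean separation

Parameter recovery compares the fitted latent class-mean distance with
the ground-truth template distance (the basis is orthonormal, so voxel
and latent distances agree). The naive `‖μ̂_a − μ̂_b‖` is upward-biased:
`E‖m̂_a − m̂_b‖² = ‖Δ‖² + tr(Σ_a)/K_a + tr(Σ_b)/K_b`.
`validation.class_mean_separation` subtracts the trace terms (estimated
from the fitted covariances) before the square root. Even debiased, the
realized within-class fluctuation is spread over only `latent_dim`
directions, so a recovery experiment must be designed with the estimand
dominating sampling error; the recovery phantom therefore uses a strong
effect (amplitude −0.5 spheres) and modest mode variability
(`latent_sd` 0.15…0.08), for a predicted sampling error of ~3% at 200
subjects per class. The overlap-calibrated presets are intentionally
*not* in that regime — their purpose is the classification experiments.

## Problem sizes in the acceptance battery

The acceptance computations use the preset cohorts (60/class) and, per
check: 50-subject phantoms for decomposition exactness; 10 fixed seeds of
2000-point KDE fits with 10⁴ draws for sampling; 20 seeds of 50-vs-50
original-vs-synthetic permutation maps (200 permutations); a 4-point L
sweep {5, 10, 20, 40} at 200 synthetic images per class with 5-fold outer
CV; 200-per-class phantoms for parameter recovery; and 200 global-null
repetitions at 10³ voxels with 100 permutations for FWE control. These
sizes are the package's own scaling of the study designs to phantom
scale.

## Known limitations

* Spatial registration is assumed done; nothing here corrects residual
  misalignment, and the model will happily encode it as variance modes.
* The MVN estimator at full L reproduces the training cloud's geometry
  so faithfully that synthetic sets are near-duplicates in the
  classifier's eyes (the dependence experiment makes this visible); use
  the optimal-L rule when independence matters.
* Per-component KDE discards cross-component dependence; its synthetic
  images can reproduce individual subjects' extreme scores on dominant
  components.
* Densities are fitted at the L of the eigenbrain model; synthesizing at
  a different L requires refitting (by design — truncating a fitted MVN
  is not equivalent to fitting a truncated one).
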