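# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `neuromodes`, in the order the pipeline runs.

## Data model and preprocessing

The package operates on two participant-aligned numeric tables: an imaging
block **X** (n × p₁) and a behaviour block **Y** (n × p₂), with a confound
table of categorical (site/scanner, scan sequence, sex, medication) and
continuous (age, household income, global brain volume) covariates.

Preprocessing runs in a fixed order — clean → impute → residualise →
normalise — because each stage's assumptions depend on the previous one:

* **Extreme-score censoring** uses a robust z on median and MAD
  (scale 1.4826·MAD). Default threshold |z| > 4; configurable, since any
  fixed cut is a judgement call. Zero-MAD columns are never censored on
  this criterion (the robust scale is undefined there).
* **Missingness pruning** drops variables, then participants, whose
  missing fraction exceeds 50% (both configurable). Variables go first so
  a participant is not removed for holes concentrated in doomed columns.
* **Imputation** is variables-as-rows k-nearest-neighbour: for a variable
  with a hole at participant j, candidate donors are the variables
  observed at j; distance is Euclidean over mutually observed
  participants; the fill is the unweighted mean of the k nearest donors'
  values at j. Default k = 1, matching the classical matrix-imputation
  tool this mirrors. A variable with no observed overlap with any donor is
  an error, not a silent fill.
* **Residualisation** is per-variable OLS against intercept + dummy-coded
  categorical confounds (first level = reference). Volumetric variables
  additionally get the global-volume covariate (eTIV) in their design; the
  covariate itself can still be carried as an analysis variable to retain
  global-volume associations. Residual columns have exactly zero mean —
  a property the projection algebra below relies on. Residualisation is
  idempotent (to 1e-10) and a rank-deficient design fails loudly, naming
  the collinear columns.
* **Rank-based inverse normal transform**: ranks (ties → average rank)
  mapped through z = Φ⁻¹((r − c)/(n − 2c + 1)). The Blom offset c = 3/8 is
  the default; Tukey (1/3) and van der Waerden (0) variants are available
  because the classical implementations differ and none is canonical.
  Constant columns either raise or pass through as zeros, per config.

Both blocks are residualised identically except for the volumetric-only
global covariate; whether behaviour should also lose site effects is
genuinely open, so it is a config choice rather than a hard rule.

## The decomposition

**PCA.** Each block is centered and reduced to its leading principal
components via SVD (never an explicit covariance inversion). This guards
the CCA against rank deficiency and noise fitting. Basis signs are fixed
deterministically (largest-magnitude entry positive) so repeated runs are
bit-identical.

**CCA.** With orthonormal bases Qx, Qy of the centered score matrices, the
singular values of QxᵀQy are the canonical correlations and the singular
vectors give the weights; canonical variates are scaled to unit sample
variance. This QR/SVD route is numerically stable for ill-conditioned
score matrices and handles rank deficiency by basis truncation.

**ICA rotation.** The canonical variates are orthogonal by construction
but rarely interpretable. The two sides' variates are stacked vertically,
[U; V] (2n × K), ZCA-whitened, and a single K × K orthonormal unmixing is
estimated by fixed-point ICA: log-cosh contrast (a = 1), symmetric
decorrelation each step, tolerance 1e-5, at most 500 iterations, 5
restarts keeping the best converged solution by the negentropy sum.
Estimating **one** unmixing from the stack and applying it to U and V
separately is what makes a pure imaging-side projection matrix exist: the
composed map

    brain_projection = pca_basis · cca_weights · unmixing

takes a de-confounded imaging block straight to brain-side mode loadings,
which is exactly what out-of-sample decomposition needs. (Alternatives —
ICA on U alone, or on (U+V)/2 — do not yield side-specific weights for
both sides from one rotation.)

Because the same rotation applies to both sides, each mode's between-side
correlation is a convex combination of the canonical correlations and is
therefore non-negative, and the maximum mode correlation can never exceed
the first canonical correlation.

*Identifiability caveat*: ICA can only identify non-Gaussian sources. The
synthetic generator therefore plants unit-variance **Laplace** latent
factors; with Gaussian factors any rotation of the canonical subspace is
equally "independent" and planted modes are unrecoverable in principle.
Real behavioural modes (skewed symptom scales, heavy-tailed scores) are
non-Gaussian, which is why the rotation is useful in practice.

**Conventions.** ICA sign and order are not identifiable, so a
deterministic convention makes runs comparable: modes are ordered by
descending between-side correlation, and each mode is oriented so the
behaviour variable with the largest absolute loading has a positive
loading. Any published polarity (e.g. "more negative = worse") is a
presentation choice recoverable by flipping.

**Mode interpretation** is by variable loadings: the Pearson correlation
of each original de-confounded variable with the mode's participant
loadings (behaviour variables against the behaviour side, imaging against
the brain side). Partial variants residualise both sides on named
covariates first. Constant variables report NaN, never a fake zero.

## Dimensionality selection

Candidate (pca_brain, pca_behav, K) triples are scored by split-half
reliability: participants are split at random (stratified by site when
available), the decomposition is fitted independently in each half, modes
are matched across halves by Hungarian assignment maximising the total
|correlation| of behaviour-side variable-loading vectors, and each matched
pair's reliability is the |r| of the concatenated brain+behaviour loading
vectors. The chosen candidate maximises the mean-over-splits of the
*minimum*-over-modes reliability — the weakest mode must be trustworthy —
with ties broken toward smaller total dimensionality. Default 10 splits.
Matching on the behaviour block (the richer side) and scoring on the
concatenation are deliberate, logged choices; nothing forces them.

## Permutation inference

Significance is tested by permuting the behaviour block's rows (the
imaging block's are equivalent by exchangeability — verified in the test
suite by a two-sample KS comparison of the two null distributions).
Family-wise error is controlled with the max statistic: each observed
correlation is referred to the permutation distribution of the maximum
correlation over components,

    p_fwe[k] = (1 + #{max-null ≥ observed[k]}) / (1 + n_perm),

which can never return zero. Because a block's PCA basis is invariant to
a row permutation of that block, each permutation restarts at CCA on
(fixed brain scores, row-permuted behaviour scores) — an exact shortcut.
Two nulls are available for the mode test: the full pipeline null
(re-estimating the ICA rotation inside every permutation; the default)
and a cheaper CCA-only null using the max canonical correlation. The
CCA-only null is stochastically larger (rotation cannot raise the max),
hence conservative for rotated modes; the default avoids that bias.

One subtlety mattered in practice: the observed and permuted statistics
must be computed by the *identical* function, including the ICA restart
selection rule, or the test drifts conservative. Both paths share one
rotation-selection helper. Inside permutation loops the ICA runs
non-strict: on structureless permuted data the fixed point has no
preferred direction and may never reach tolerance, and any orthogonal
rotation is a legitimate null draw; user-facing fits keep the strict
convergence failure. Calibration was verified by simulation: over 200
independent null datasets (n = 300, 20+20 variables, K = 2, 199
permutations) the family-wise rejection rate at α = 0.05 was 0.07, inside
the exact binomial 99% interval.

## Out-of-sample validation

**Projection** is a pure matrix product: new cohort (de-confounded with
its own design, hence zero-mean columns) × imaging projection. Variables
are matched by name; missing training variables raise rather than
zero-fill. Projection is exactly linear and reproduces the training
loadings in-sample to 1e-8.

**Spin permutations** test spatial overlap of two parcel-level brain-weight
maps while preserving spatial autocorrelation. Each spin draws one uniform
random rotation (Haar measure on SO(3)); the left hemisphere's centroids
are rotated and the right hemisphere uses the same rotation mirrored
through the midsagittal plane, preserving bilateral symmetry. Each parcel
takes the value of its nearest rotated neighbour (duplicates possible and
recorded — the standard centroid-level construction); a one-to-one
optimal-assignment variant that exactly preserves the value multiset is
also provided. Features without spherical coordinates (subcortical,
global summaries) are freely permuted among themselves. p is two-sided on
|r|. Calibration on unstructured maps was verified by simulation (200
repetitions, rejection rate within the binomial 99% interval).

**Bootstrap CIs** for loading–phenotype correlations resample participants
with replacement, re-project, re-correlate (optionally partialling named
covariates from both sides), and take 2.5/97.5 percentiles. Resamples with
a constant phenotype are recorded as undefined and excluded. Coverage of a
generator-implied true correlation was verified at ≈95% over 100
replications.

## Clinical association models

All post-hoc models use OLS with age, age², sex as covariates; age² is
built from centered age so the linear and quadratic terms are nearly
orthogonal. Diagnosis contrasts fit loading ~ diagnosis + covariates with
"no diagnosis" as reference; in this additive model the difference in
estimated marginal means between a category and the reference equals the
category's dummy coefficient, independent of where covariates are held.
Tukey adjustment evaluates the studentized-range survival function at
q = |t|·√2 with k groups and the residual df; with k = 2 this reduces
exactly to the pooled two-sample t-test. Whether k should count all
groups or only the tested contrasts (+ reference) is ambiguous in common
practice, so both are offered (`family="all-pairwise"`, the default, and
`"vs-reference"`). The comorbidity trend regresses loadings on the
diagnosis count, with and without the zero-diagnosis group. Robustness
reruns report, per mode, the Pearson concordance of the rerun
variable-loading vector with the original: a full refit on
sex-residualised behaviour (modes re-matched by assignment), partial
correlation variants for age/income/medication, and leave-one-diagnosis-
out projection through the original weights.

## The synthetic generator

The generator emulates the data-generating process the pipeline assumes:
K shared latent factors with per-mode cross-block correlation ρ_k built as
z_side = √ρ·z_shared + √(1−ρ)·z_unique (so corr(z_brain, z_behav) = ρ
exactly in expectation), unit-variance Laplace factor distributions (see
the identifiability caveat), random Gaussian mixing into p variables per
block, and isotropic Gaussian noise with σ = 1 — the same scale as one
latent's contribution path, a mid-range signal-to-noise for questionnaire
and morphometry data. Nuisance structure is injected separately: additive
site offsets and continuous-covariate trends, MCAR missingness, and
extreme cells planted at ≥ 8 population SD so any sensible cleaning
threshold catches them. Diagnosis labels tilt each category's base rate by
exp(−effect·z₂), making prevalence and the expected comorbidity count
monotone in the second latent mode.

Default desk-scale dimensions are n = 500, p_brain = 120, p_behav = 200
(roughly a quarter of the motivating cohort's 1732 × 447/793); validation
runs in this repository use n = 2000–2600. What the generator does *not*
emulate: realistic covariance among morphometric features, ordinal
questionnaire item distributions, site-by-variable interactions, or
longitudinal structure. Passing tests therefore demonstrate correctness of
the algorithms and calibration of the inference under the stated model,
not robustness to every pathology of real cohort data.

## Numerical and problem-size choices

* All SVD/eigen work is LAPACK via numpy/scipy; no covariance inversions.
* Determinism: every stochastic step (ICA restarts, splits, permutations,
  spins, bootstrap, generator) is driven by an explicit integer seed;
  identical configs reproduce outputs byte-for-byte (tested on the run
  manifest).
* Canonical correlations are clipped to [0, 1] against rounding excursions.
* The calibration simulations in the test suite use 200 repetitions with
  199 permutations/spins (the smallest counts giving a two-sided binomial
  99% interval clearly separated from both 0 and 2×α), split-half
  selection uses 3–4 splits per candidate, and the bootstrap-coverage
  study uses 100 replications at 500 resamples; these sizes were chosen as
  the smallest that make the pass/fail bands sharp.
* `scripts/acceptance.py` reports at n = 2000 training participants with
  1000 permutations/spins/resamples, matching the scale the method is
  intended for.

## Known limitations

* Modes are linear on both sides; non-linear brain–behaviour coupling is
  out of scope.
* The ICA rotation assumes non-Gaussian sources; on nearly Gaussian data
  the rotation (and hence mode identity, though not the correlated
  subspace) is arbitrary.
* Spin nulls operate at parcel-centroid level, not mesh vertices, and the
  free-permutation fallback for non-surface features ignores any spatial
  structure among them.
* The permutation scheme assumes exchangeable participants; family or site
  clustering that survives residualisation would need a restricted
  permutation scheme not implemented here.
* Percentile bootstrap CIs are first-order; no BCa correction.
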