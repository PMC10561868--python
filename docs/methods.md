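# Methods

This note documents the estimators implemented in `spatent`, their
assumptions, the tunable parameters and defaults, and the design choices
made where more than one reasonable construction exists.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Spatial entropy decomposition

**Model.** A subject's image is a marked planar point pattern: `n` cell
centroids (microns; origin and orientation arbitrary) with labels from a
set of `J` phenotypes.  Every unordered pair of cells realises a
co-occurrence category `z_r` — one of `R = J(J+1)/2` unordered label
pairs — at its inter-cell Euclidean distance.  Restricting to pairs with
distance in `(0, d_K]` and binning distance into `w_k = (d_{k-1}, d_k]`
yields the exact decomposition

```
H(Z) = SPI(Z) + H^W(Z),
SPI(Z) = Σ_k p(w_k) SPI_k,   SPI_k = KL( p(·|w_k) ‖ p(·) ) ≥ 0,
H^W(Z) = Σ_k p(w_k) H_k^W,   H_k^W = Shannon entropy of p(·|w_k).
```

`SPI(Z)` is the mutual information between pair category and distance;
`SPI_k` as a function of distance is the subject's SPI curve.  All
entropies are in nats (natural log) by default; a `base` argument
converts.

**Distance breaks.** `d_0 = 0`; `d_K` is the median of all `n(n-1)/2`
pairwise distances (the analysis targets local cell-cell interaction, so
the upper half of the distance distribution is discarded); interior
breaks decrease geometrically from `d_K` (equally spaced on the log
scale) down to a floor `d_1`.  The floor is the one genuinely open
choice:

- **Default `d_1 = d_K / 20`** (`floor="ratio"`, `floor_ratio=20`).  For
  an image of a few thousand cells this keeps every bin populated with
  hundreds of pairs, so the conditional distributions `p(·|w_k)` are
  estimable everywhere and a completely random pattern measures `SPI_k ≈ 0`
  at *every* bin.  On a 1000 µm window this puts `d_1` at ~10-25 µm —
  the scale of touching cells.
- `floor="min-distance"` anchors `d_1` at the smallest positive
  inter-cell distance.  Then the first bin contains O(1) pairs by
  construction and its empirical KL divergence is inflated by roughly
  `(R-1)/(2 m_k)` nats even under randomness; offered for sensitivity
  analysis only.

`K ≤ 50` is enforced: more bins than this guarantee empty short-range
bins with undefined entropies.

**Conventions.** Bins are left-open/right-closed, so pairs at exactly
`d_K` count and coincident pairs (distance 0) never do; duplicated
coordinates are excluded with a warning.  Empty bins carry NaN
("missing"), not zero, and drop out of the weighted totals and of the
downstream functional sample.  The marginal `p(z_r)` is computed from the
pairs within `(0, d_K]` only — the only convention under which
`Σ_k p(z_r, w_k) = p(z_r)` and the decomposition identity hold exactly.
Every quantity depends on coordinates only through pairwise distances,
so the curves are invariant under translations, rotations and
reflections (verified to float precision in the tests).

**Permutation null.** Holding coordinates fixed and permuting labels
destroys label-space association while preserving the geometry and the
type frequencies; the pointwise mean and quantile envelope over
permutations give a subject-level reference for judging observed SPI.

**Aspatial baselines.** Shannon (`Σ p_j log 1/p_j`) and Simpson
(`1 − Σ p_j²`) diversity of the type frequencies are provided for
comparison; both are blind to any spatial rearrangement.

## 2. Sparse functional PCA

**Model.** `SPI_ik = μ(s_ik) + Σ_l ξ_il φ_l(s_ik) + ε_ik` with
uncorrelated mean-zero scores of variance `λ_l` and iid error variance
`σ²`.  Estimation pools observations across subjects, so it works for
subjects with as little as one defined bin.

- **Working grid:** 51 equally spaced points over the pooled abscissa
  range (matches the `K ≤ 50` bin cap while keeping the eigenproblem
  small).
- **Mean:** local-linear Epanechnikov smoother of the pooled `(s, SPI)`
  cloud; data are pre-binned onto a fine lattice (201 cells) beyond 4000
  pooled points, carrying counts as weights.  Bandwidth by GCV over a
  geometric candidate grid (`0.02r … 0.5r`, `r` = domain range), with
  the exact hat-matrix trace as effective degrees of freedom so that an
  interpolating fit is properly penalized.  A fixed bandwidth can be set
  in `FPCAConfig` for reproducibility-critical pipelines.
- **Covariance:** within-subject cross-products of mean residuals with
  `j ≠ l` (the diagonal is excluded because it carries `σ²`), binned
  onto the grid lattice and smoothed by a 2-D local-linear smoother.
  By default every *curve* receives equal total weight (`cov_weighting=
  "subject"`, pair weight `1/(K_i(K_i−1))`): with `K_i` ranging 5–50,
  per-pair weighting would let the largest curves dominate (weights
  `∝ K_i²`), roughly halving the effective number of subjects;
  `"obs"` weighting is available.  The bandwidth is chosen by 5-fold
  **leave-subjects-out** cross-validation (folds assigned from a hash of
  each curve's content, hence order-invariant): raw covariances from the
  same curve are strongly dependent, so pointwise GCV would reward
  interpolation and undersmooth badly.
- **Noise variance:** `σ̂²` is the average gap, over the central half of
  the domain, between the smoothed diagonal of the raw second moments
  and the diagonal of the smoothed covariance, floored at 0.  Being a
  small difference of two large smoothed quantities, it is the least
  precise output of the fit (its error is a few percent of `λ_1`); it
  only modulates score shrinkage, to which the pipeline is insensitive.
- **Eigenanalysis:** trapezoid quadrature symmetrization
  `W^{1/2} Ĝ W^{1/2}`, discarding negative eigenvalues (smoothing can
  produce them) before the fraction-of-variance computation.
  Eigenfunctions have unit L2 norm and positive integral (first non-zero
  coordinate positive when the integral vanishes) — scores flip sign
  with the eigenfunction, so the convention is part of the contract.
- **Components:** `L` = smallest number of components whose eigenvalues
  reach `fve_threshold` (default 0.92) of the total eigenvalue mass.
- **Scores:** conditional expectations
  `ξ̂_il = λ̂_l φ̂_il' Σ̂_i^{-1} (SPI_i − μ̂_i)` with
  `Σ̂_i = Φ Λ Φ' + σ̂² I` built from the truncated expansion (guarantees
  positive semi-definiteness).  Systems are solved by Cholesky
  factorization shared across subjects with identical abscissae, never
  by explicit inversion; a ridge of `1e-8 ×` the mean diagonal is added
  with a warning only if factorization fails (e.g. dense noiseless
  data).  The cited conditional-expectation formula requires the inverse
  of `Σ_i`; it is implemented as such.

On densely and regularly observed data with a bandwidth below the grid
spacing, the local smoothers reproduce the empirical moments and the
eigenpairs coincide with plain matrix PCA of the sample covariance —
the dense-limit check in the acceptance tests.

## 3. Cox model and the spatial-effect LRT

`log h_i(t) = log h_0(t) + U_i'γ + ξ_i'β`, maximized by Newton–Raphson
with step halving on the partial likelihood.  Ties are handled by
**Breslow** by default (consistent with the Breslow baseline cumulative
hazard the simulator consumes); **Efron** is available by option.  The
solver is validated in the tests against brute-force maximization of the
hand-written product-form likelihood and against `lifelines` (which
implements Efron; the two coincide on tie-free data).

Covariates are mean-centered and unit-scaled internally; the
standardization is stored on the fit, predictions use it, and reported
coefficients are returned on the original scale.  Constant covariates
are dropped with a warning; exact collinearity raises an error naming
the offending columns; non-convergence raises with the iteration trace.

The LRT compares the full model (clinical + the `L` scores fixed by the
92% FVE rule — never re-selected inside the test, avoiding
selection-inflated type-I error) against the clinical-only model:
statistic `2(ℓ_full − ℓ_restricted)`, reference `χ²_L`.  Calibration is
verified by simulation (1000 null replicates; rejection level ≈ 5%).

## 4. The cohort simulator

The simulator defines the study conditions used by the acceptance
checks; its defaults are fixed and not data-dependent.

- **Patterns.** `J = 5` types, 600 cells/type (3000 cells) on a
  1000×1000 µm window.  *Random*: uniform independent placement.
  *Clustered*: per type, a Thomas process — 10 uniform parents,
  Gaussian offspring with SD 60 µm, wrapped onto the window (torus),
  which preserves counts exactly and keeps the marginal intensity
  uniform.  This geometry produces reference SPI curves peaking near
  0.2 nats at short range, the magnitude scale observed in real
  multiplexed-imaging cohorts; stronger clustering (fewer/tighter
  parents) is available through `ClusterGeometry`.
- **Reference curves.** Average SPI curve over 10 replicate patterns per
  configuration, interpolated onto a common log-spaced 40-bin grid.
- **Cohorts.** Each subject joins the clustered or random group by an
  independent fair coin flip (group sizes `Binomial(N, 1/2)`); their
  curve is the group reference plus a smooth mean-zero Gaussian-process
  deviation (squared-exponential kernel, correlation length 0.25 of the
  distance range) with SD 0.01 / 0.05 / 0.15 for the small / medium /
  large noise levels.  Smooth subject-level deviations — rather than
  independent per-bin jitter — represent biological heterogeneity
  around the group archetype; sparse FPCA retains them as additional
  components (the FVE rule selects 2–3 here), so the spatial scores
  carry more than the bare group contrast, matching the regime in which
  score-based models clearly out-predict a clinical-only model.
  `noise_correlation = 0` recovers independent per-bin noise, which the
  covariance estimator routes into `σ̂²` instead.
- **Survival.** FPCA scores of the simulated curves and an age-like
  covariate `Z* ~ N(64, 8.6²)` are mean-centered and unit-scaled; the
  true linear predictor is `η* = Z*_std + Σ_{l≤L*} ξ*_l,std`.  Times are
  drawn by inverse transform from
  `S_i(t) = exp{ −e^{η*_i} Λ_0(t) }` with a parametric Weibull baseline
  `Λ_0(t) = (t/b)^a`, `a = 1.2`, `b = 60` (time units arbitrary) — a
  configurable stand-in for a data-estimated baseline.  Censoring is
  independent exponential with its mean calibrated (by root-finding on
  the drawn event times) to a 40% expected censoring fraction.
  Refitting a Cox model to a large simulated cohort recovers unit
  coefficients on the standardized components of `η*`, the generator's
  internal validity check.
- **Experiment.** For each (sample size, noise level, iteration):
  simulate a cohort, split 75/25 train/test, fit (1) clinical + scores,
  (2) scores only, (3) clinical only on the training set, and score each
  by the test-set `NRMSE = sqrt(mean (η̂ − η*)²) / mean |η*|` (the
  plainly "normalized MSE" variant is available via `root=False`).
  Everything derives from one master seed through hierarchical
  substreams, so runs are exactly reproducible.

**Problem sizes used by the acceptance checks** (chosen to exercise the
claimed behaviour at cohort scale while keeping a laptop run in
minutes): 120 random histograms for the decomposition identity; 50
patterns (n ≤ 200, J ≤ 5) against naive enumeration; 20 rigid motions;
20 CSR replicates at 3000 cells; an n = 300 sparse cohort (K_i uniform
on 5–50) for FPCA recovery plus an n = 150 dense cohort for the
matrix-PCA limit; 1000 null replicates at n = 300 for LRT calibration;
N = 100 with 100 iterations (medium and large noise) plus an N = 500
dispersion arm for the NRMSE comparison; n = 5000 for generator
validity.

## 5. What the synthetic data do and do not show

The generator reproduces the *structure* of real multiplexed-imaging
cohorts — multitype patterns with controlled clustering, subject-varying
smooth SPI curves, right-censored outcomes linked to spatial scores —
but not their messiness: no segmentation or phenotyping error, no
per-image cell-count variation, no tissue-scale anisotropy or holes,
equal type frequencies, an exchangeable censoring mechanism, and a
parametric rather than data-derived baseline hazard.  Passing tests
therefore demonstrate correctness and calibration of the estimators
under the stated model, and the *direction* of the predictive-performance
comparison; they do not certify effect sizes, p-values, or NRMSE
magnitudes on any particular clinical dataset.

## 6. Known limitations

- `σ̂²` is imprecise at moderate cohort sizes (Section 2); downstream
  results are insensitive, but the value itself should not be
  interpreted quantitatively.
- Smoothing attenuates high-curvature eigenfunctions; eigenvalues of
  rapidly oscillating components are biased downwards by O(h²·curvature).
- The LRT takes `L` as fixed by the FVE rule; uncertainty in the choice
  of `L` is not propagated.
- The entropy decomposition is isotropic by construction (unordered
  pairs, distance-only binning); directional interactions are out of
  scope.
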