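# Methods

## The problem

Functional-connectivity matrices — full-rank correlation or covariance
matrices over `n` regions of interest — are symmetric positive-definite
(SPD) and live on the curved cone `Sym_n^+`, not in a vector space. When
such matrices are pooled across imaging sites, two geometric batch effects
appear: site means are displaced from one another on the manifold
(*inter-site bias*, visible as block structure in pairwise-distance
matrices and as site clusters in low-dimensional embeddings), and sites
disperse unequally around their means (*intra-site bias*). Entrywise group
comparisons run on pooled multi-site data then confound site with
condition. `spdharm` removes the inter-site component with transforms that
provably preserve within-site geometry, and quantifies the gain with a
repeated-subsampling permutation battery.

## Geometry

Two Riemannian structures are supported. Under the affine-invariant metric
(AIRM) the geodesic distance is
`d(Σ, Π) = ||Log(Σ^{-1/2} Π Σ^{-1/2})||_F`, invariant under congruence
`Σ → C Σ C^T` by any invertible `C`; the associated inner product at base
point `Σ` is `g_Σ(X, Y) = Tr(Σ^{-1} X Σ^{-1} Y)` with exponential and
logarithmic maps `exp_Σ(V) = Σ^{1/2} Exp(Σ^{-1/2} V Σ^{-1/2}) Σ^{1/2}` and
`log_Σ(Π) = Σ^{1/2} Log(Σ^{-1/2} Π Σ^{-1/2}) Σ^{1/2}`. Under the
log-Euclidean metric (LERM) the manifold is flattened by the matrix
logarithm and `d(Σ, Π) = ||Log Σ − Log Π||_F`. The two distances coincide
exactly for simultaneously diagonalizable pairs. All matrix functions go
through symmetric eigendecomposition with explicit re-symmetrization of
outputs, so the symmetry invariants hold to machine precision.

The Fréchet mean `argmin_Σ Σ_i d²(Σ, Σ_i)` has the closed form
`Exp(mean_i Log Σ_i)` under LERM. Under AIRM it is computed by the
fixed-point gradient iteration `Σ ← exp_Σ(mean_i log_Σ(Σ_i))`,
initialized at the LERM mean (cheap and typically close), stopping when
the Frobenius norm of the mean tangent update — exactly the Riemannian
gradient — falls below `tol` (default 1e-8) or after `max_iter` (default
200) iterations; non-convergence is flagged on the result, not raised. A
damping factor for the update step exists for ill-conditioned sets but
defaults to 1 (the plain iteration).

## Harmonization transforms

All transforms are *condition-blind*: one transform per site, never per
diagnostic group, so patient–control distances within a site are untouched
and unlabeled data can be harmonized. Outputs are SPD by construction;
the unit diagonal of correlation inputs is deliberately not restored
(re-projection to the correlation submanifold is a distortion the method
avoids; harmonized matrices are covariance-like).

* **Matrix whitening (MW)** conjugates each site by the inverse square
  root of its AIRM Fréchet mean: `Σ_i^{(k)} → (Σ̄^{(k)})^{-1/2} Σ_i^{(k)}
  (Σ̄^{(k)})^{-1/2}`. Affine invariance preserves within-site AIRM
  distances; equivariance sends every site mean exactly to `I`.
* **Parallel transport (PT)** moves each site along the AIRM geodesic to
  the common reference `Σ₀ = Σ̄` (AIRM mean of the site means) via the
  closed-form congruence `C = (Σ₀ (Σ̄^{(k)})^{-1})^{1/2}`, then whitens
  the pooled cohort by `Σ̄`. The principal square root of the
  non-symmetric product is computed through a similarity with an SPD
  matrix (`C = A^{1/2}(A^{1/2} B^{-1} A^{1/2})^{1/2} A^{-1/2}`), and the
  contract `C Σ̄^{(k)} C^T = Σ₀` is verified post hoc — the verifiable
  postcondition, rather than the delicate non-symmetric root itself, is
  the interface contract. When all site means commute with the global
  mean, PT and MW coincide matrix-by-matrix; the commutator
  `[Σ̄, Σ̄^{(k)}]` is exposed as the diagnostic for how close a cohort is
  to that regime.
* **Rigid log-Euclidean translation (RLET)** maps each subject's log
  matrix by `L_i → L̄_target + λ_k (L_i − L̄_k)` where `L̄_k` is the site
  log-mean and the target is the global log-mean (mean of site log-means,
  weighting sites equally regardless of size) or zero (identity variant).
  With `λ_k = 1` this is an exact isometry of the LERM metric, and the two
  targets yield point sets with identical pairwise distances. The
  rescaled variant uses `λ_k` = (across-site average of mean intra-site
  pairwise distances) / (site k's mean intra-site pairwise distance),
  which equalizes mean dispersion across sites; it is provided as an
  extension and has no validated reference output.

MW and PT are stated in the AIRM framework and RLET in the LERM framework;
each transform's isometry and relocation guarantees are therefore checked
in its own metric.

## Permutation battery

The two-group test statistic is the entrywise absolute difference of the
group Fréchet means. For each of `T` iterations the pooled subjects are
randomly re-partitioned into groups of the original sizes and the
statistic recomputed; the entrywise p-value is the plain ratio of
iterations whose statistic meets or exceeds the observed one (this
estimator can return 0 and is mildly anti-conservative; a
permutation-inclusive `(count+1)/(T+1)` variant is available but off by
default). The metric used for the in-test means is configurable: AIRM is
the default, LERM is a fast alternative (its group mean reuses
precomputed logs, reducing each iteration to two small eigendecompositions).

Because a single full-cohort test is statistically unreliable (e.g.
partitioning 160 subjects into 80+80 admits ~10^47 splits), the battery
runs many small experiments: each draws a subsample per condition without
replacement (subjects may recur across experiments), pools across sites,
tests, and binarizes at a strict α (strictly `p < α`; diagonal entries are
excluded throughout, as self-connections carry no information). The binary
maps are summed into the frequency matrix `F`. Modeling each experiment as
an independent Bernoulli trial, the binomial distribution gives the chance
probability of recurrence: at α = 0.001 and 100 experiments, appearing
once has probability ≈ 0.09, at least twice ≈ 0.005, at least three times
≈ 0.00015 — so `F` can be thresholded at a chosen confidence. The
sensitivity `S(n)` — entries with `F ≥ n` as a fraction of entries with
`F ≥ 1`, over the strict upper triangle — summarizes how coherently a
pipeline accumulates detections; `S(1) = 1` and `S` is nonincreasing.

## Network summarization

ROIs are assigned to 10 functional components: the Yeo-17 cortical
networks collapsed as 1–2 → VIS, 3–4 & 14 → MOT, 5–6 → DA, 7 → VA,
8 & 11–13 → FP, 9–10 → LIM, 15–17 → DMN, plus explicit subcortical labels
BS, CRB and BG (coordinate-based assignment is atlas tooling outside this
package; the module consumes per-ROI labels). Anomalies (entries surviving
a frequency threshold) are accumulated into a symmetric 10×10 count
matrix, then normalized in two stages: each row's off-diagonal by that
component's total inter-network anomaly count, the diagonal by the total
intra-network count — after which the matrix is generally asymmetric, by
design. Distribution matrices are compared by binarizing entrywise
absolute differences at an inclusive 15% cutoff. In contribution
histograms each anomaly adds one count to each *distinct* endpoint
component (an intra-network anomaly counts once — double-counting its
single component would inflate it); fractions sum to 1.

## Synthetic cohorts

The generator works in log space: `Log Σ_i = M + S_k + c_i Δ + E_i`, with
`M` a global base symmetric matrix (entrywise scale 0.5 by default —
log-matrix entries of order unity, comparable to logs of generic
correlation structure), `S_k` a per-site symmetric offset (default scale
0.3; the "strong bias" studies use 0.5), `Δ` a sparse symmetric condition
effect added for patients, and `E_i` per-subject symmetric noise whose
scale may differ per site (defaults 0.1). Symmetric draws fill the upper
triangle i.i.d. Gaussian and mirror it. Exponentiating guarantees SPD
validity structurally. A commuting-sites variant draws all offsets and
noise diagonal in one fixed random orthogonal basis, so every empirical
site mean commutes with the global mean — the engineered regime for the
PT ≡ MW equivalence check. An optional post-step rescales matrices to
unit diagonal for correlation-matrix realism.

What the generator does *not* emulate: BOLD time series, estimation noise
with its rank structure, spatial autocorrelation of ROIs, or any
quantitative match to a specific real multi-site cohort. Passing tests
therefore demonstrate the geometric contracts and the *direction* of the
harmonization benefit, not effect sizes transferable to real data.

A consequence of planting effects on log-matrix entries while testing
entries of the SPD means: the matrix exponential mixes entries, so a
planted effect at log-entry `(i, j)` induces genuine (smaller) group
differences at SPD entries sharing index `i` or `j`. In planted-recovery
experiments such induced entries can occasionally out-rank a weaker
planted entry in the frequency matrix; this is a property of the
entrywise statistic, not a false positive.

## Problem sizes and numerical choices

The packaged experiments use sizes chosen to exercise every code path at
interactive cost: geometric identity suites on a 4-site, dim-20 cohort
with 10+10 subjects per site; null calibration at dim 6 with T = 500
permutations and 15 experiments (225 entry-level null p-values); the
harmonization-benefit battery with 20 experiments, 8+8 subsamples,
T = 200, α = 0.01, using the LERM in-test mean. Symmetry tolerance is
1e-8 relative to the matrix norm; positive-definiteness requires the
smallest eigenvalue to exceed 1e-10; an optional eigenvalue floor
(default off, 1e-6 when enabled) handles rank-deficient correlation
matrices estimated from fewer time points than ROIs — whether real
pipelines need it for large (e.g. 190×190) matrices depends on the
upstream estimator, and the validator surfaces the failure rather than
silently regularizing. t-SNE embeddings use the √2-weighted
upper-triangle vectorization of matrix logs (dimension `n(n+1)/2`), so
the embedded similarity is exactly the LERM distance; other
hyperparameters follow scikit-learn defaults and are recorded in logs.

## Known limitations

* The AIRM fixed-point mean has no global convergence guarantee for badly
  conditioned inputs; non-convergence is reported, and damping is the
  manual fallback.
* The plain-ratio p-value is anti-conservative at small `T`; switch on
  the permutation-inclusive estimator when calibration matters more than
  fidelity to the classical three-step recipe.
* λ-rescaled RLET changes intra-site variability by construction; it
  equalizes dispersion under the assumption that dispersion differences
  are site artifacts, which cannot be verified from the data alone.
* Harmonized matrices are not correlation matrices; downstream tools
  expecting a unit diagonal must rescale explicitly (and thereby leave
  the harmonized geometry).
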