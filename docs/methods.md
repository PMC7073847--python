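# Methods

## Model

Each class k supplies n_k i.i.d. observations of a p-vector Y^(k) assumed
nonparanormal: there exist strictly increasing transforms f_j such that
X = (f_1(Y_1), …, f_p(Y_p)) is multivariate Gaussian with precision matrix
Ω^(k). Conditional dependence between genes i and j within class k is
measured by the partial correlation
ρ_ij·^(k) = −ω_ij^(k)/√(ω_ii^(k) ω_jj^(k)). The hypotheses
H0_ij: ρ_ij·^(1) = … = ρ_ij·^(K) are tested for all p(p−1)/2 pairs.

Key assumptions: the transformed vector is exactly Gaussian; the
differential network (set of pairs violating H0) is sparse; within each
class the precision matrix is sparse enough for node-wise sparse regression
to be consistent. When the differential network is dense, FDR control can
degrade — this is a known limitation of the approach, not of the
implementation.

## Winsorized imputation

The latent Gaussian data are imputed per margin as
x*_mj = μ̂_j + σ̂_j Φ⁻¹(F̃_j(y_mj)) where F̃_j is the empirical CDF clamped
to [δ_n, 1−δ_n], δ_n = 1/(4 n^{1/4} √(π log n)) (natural log). μ̂_j and
σ̂_j are the raw column mean and 1/n-normalised scale, so the imputed column
carries the observed location/scale; `standardize="latent"` uses 0/1
instead. The clamp keeps every quantile finite; ties share their eCDF value
(the convention for duplicates is a choice — nothing in the estimator
prescribes an ordering within ties). Missing or non-finite entries are
rejected rather than imputed.

Because the estimator sees the data only through ranks (plus μ̂, σ̂), the
standardized scores (x* − μ̂)/σ̂ are *exactly* invariant under strictly
increasing marginal transforms — this is the property that makes the
pipeline distribution-free over margins, and it is asserted exactly in the
tests.

## Node-wise regression and the bias-corrected statistic

For Gaussian X, regressing X_j on X_{−j} gives coefficients
β_j = −Ω_{−j,j}/ω_jj and residuals with cov(ε_i, ε_j) = ω_ij/(ω_ii ω_jj).
Coefficients are estimated from a correlation-scale Gram matrix: either the
Pearson correlations of the imputed columns (`gram_source="imputed"`, the
oracle arm) or the adjusted Spearman matrix 2 sin(π ρ_S/6) computed from
ranks (`adjusted_spearman`, the default — consistent for the latent
correlation under any margins). Two solvers operate directly on the Gram
matrix:

- lasso — cyclic coordinate descent with soft thresholding, tolerance 1e−7
  on the maximum coefficient change, at most 10,000 sweeps, warm-started
  along the penalty path (the inner loop is numba-compiled);
- Dantzig selector — min ‖β‖₁ subject to ‖G_{−j,−j}β − G_{−j,j}‖∞ ≤ λ as a
  linear program (HiGHS) after the positive/negative split.

The penalty is tuned per node by AIC = n log(RSS/n) + 2 df over a 20-point
log-spaced grid, with RSS evaluated on the imputed data and df the support
size; ties go to the larger λ. Two numerical choices matter here and were
made on calibration grounds (measured against the exact-normal behaviour of
the downstream statistics under a global null):

- **Grid range.** The grid runs from λ_max = max_i |G_ij| down to
  max(λ_max/4, √(2 log p / n)). Descending further admits predictors whose
  sample correlation with the target is indistinguishable from noise; AIC
  compared *after* adaptive selection is optimistic for exactly those
  candidates and, at p = 50, n = 100, accepts ~10 spurious coefficients per
  node, inflating the null standard deviation of the edge statistics by
  10–30%. The √(2 log p/n) floor is the universal noise level for n
  samples and p candidates.
- **OLS refit.** Every candidate along the path is refit by ordinary least
  squares on its selected support before AIC scoring and downstream use
  (relaxed lasso; the Dantzig analogue is the classic two-stage
  Gauss–Dantzig estimator). The downstream correction removes only the
  first-order shrinkage bias of the residual cross-products; at n = 100 the
  remaining second-order bias of heavily shrunk fits is visible as 13–54%
  variance inflation of the null statistics. With the refit the null
  standard deviation is 1.00 on both benchmark graphs. `refit=False`
  restores the raw shrinkage estimator.

With B[a,b] the fitted coefficient of variable b in the regression of
variable a and r_ij = (1/n)Σ_m ε_mi ε_mj, the bias-corrected cross-product
is N_ij = r_ij + r_ii B[j,i] + r_jj B[i,j], and the partial-correlation
estimate is ρ̂_ij = N_ij/√(r_ii r_jj), clipped to magnitude 1 − 1e−10. The
index pairing (variance of node i multiplied by the coefficient *of* i in
the regression of j) is the one for which the first-order errors cancel and
the population limit is exactly ρ_ij·; with unequal precision diagonals the
opposite pairing converges to a different quantity (verified numerically at
n = 2×10⁶). The raw statistic with the r_ii·r_jj denominator (inverse-
covariance scale) is exposed as `s_star` for inspection; the test operates
on the bounded ρ scale throughout, which is also the scale on which the
plug-in variance (1 − ρ²)² is meaningful.

A hard threshold at 2√(log p / n) produces the variance plug-in ρ̃: entries
below it are treated as zero in the denominator of the two-sample statistic.

## Multi-class test and FDR control

For classes k < k′,

    S_ij^(k,k′) = (ρ̂_ij^(k) − ρ̂_ij^(k′)) / √((1−ρ̃_k²)²/n_k + (1−ρ̃_k′²)²/n_k′),

and S_ij = Σ_{k<k′} (S_ij^(k,k′))². Under H0 each standardized difference is
asymptotically standard normal, so S_ij is referred to a mixture
Σ_m λ_m Z_m² with M = K(K−1)/2 terms and mapped to
T_ij = Φ⁻¹(P(Σ λ_m Z_m² ≤ S_ij)), with the CDF value clamped to
[1e−15, 1−1e−15] so every T is finite. For K = 2 the reference law is
exactly χ²₁; equal weights give a scaled χ²_M in closed form; unequal
weights are evaluated by scrambled-Sobol quasi-Monte Carlo with 2²¹ points
and a fixed scramble seed (deterministic, absolute error well below 1e−3).
The weights for K > 2 are not canonical; all-ones is the default and a
configuration hook accepts alternatives. K = 2 is the fully supported path.

The threshold t(α₀) is the smallest observed T value in
[0, √(4 log p̃)] (p̃ = p(p−1)/2) satisfying

    1 − Φ(t) ≤ α₀ · A(t) · max(1, #{T_ij ≥ t}) / p̃,

where A(t) = (1 + |A| t φ(t) / (2(1−Φ(t))))⁻¹ and A = (P₀ − P̂₀)/Q₀ with
P₀ = 2Φ(1)−1, Q₀ = 2φ(1) and P̂₀ the observed fraction of |T_ij| ≤ 1. The
left side is read as the standard-normal tail probability (a density there
would be uninterpretable as a tail). If no observed value qualifies the
threshold falls back to √(4 log p̃), the upper end of the search domain, so
only extreme statistics are rejected. Rejection is one-sided (T_ij ≥ t);
|T| enters only through P̂₀. All upper-triangle entries contribute to P̂₀,
including those whose variance plug-in was thresholded to zero.

## Synthetic benchmarks

The generator reproduces the two standard scenarios at their reference
configuration (p = 200 band graph with 50 sign-flipped edges is constructed
and tested; the test suite and acceptance script run the same protocol at
p = 50, 10 flips, n₁ = n₂ = 100, 25–50 replicates, which one CPU completes
in minutes while preserving the p > n/2, strong-signal character of the
original design):

- **band**: ω_ii = 1, ω_ij = 0.6 for |i−j| = 1; a chosen number of
  first-off-diagonal edges flip sign in class 2;
  max(|λ_min(Ω₁)|, |λ_min(Ω₂)|) + 0.05 is added to both diagonals.
- **Erdős–Rényi**: pairs connect with probability 0.05, weights uniform on
  ±[1/4, 1/2] shrunk by 5, unit diagonal, 5% of existing edges flipped.
  This construction is not guaranteed positive definite after flips; when
  λ_min ≤ 0 the band-graph remedy (|λ_min| + 0.05 on both diagonals) is
  applied. Flips are restricted to existing edges — "differential edges"
  are perturbations of present dependencies, not newly created ones.

Observations are latent draws from N(0, Ω⁻¹) pushed through per-variable
monotone transforms (identity = oracle arm; exp, cube and a
logistic-quantile map exercise the nonparanormal claim). The latent draw is
returned alongside the observed matrix so both arms can run on identical
randomness. A master seed spawns independent substreams per replicate and
class.

What the generator does *not* emulate: count-valued margins with ties and
zeros, heteroscedastic sequencing depth, correlated batch structure, or
dense differential networks. Passing benchmarks therefore demonstrates
correctness of the statistical machinery under the model's assumptions, not
robustness to every feature of real RNA-seq data; the batch-correction
module addresses one such feature upstream.

Scoring: per replicate, FDP = FP/max(R, 1) and power = TP/#differential
edges, averaged over replicates per nominal level.

## Batch correction

g*_ijk = M_i + (g_ijk − M_ij)·σ̂_i/σ̂_ij recenters gene i in batch j to the
gene's overall median and rescales to its overall SD (sample SD, 1/(n−1) by
default, configurable). The same operation with age-group labels removes
age-group effects. After one pass the per-batch medians agree exactly (odd
batch sizes); exact idempotence does not hold in general because medians
are not means and the pooled SD of per-batch standardized values is not
exactly 1 — with the 1/n convention and batches that are affine copies of
one another the map is exactly idempotent, and on generic data a second
pass moves values by well under a percent of scale. A batch with zero
within-batch spread for some gene cannot be rescaled and raises an error
naming the gene and batch. Samples with missing values are dropped on read
(threshold configurable), never imputed.

## Degenerate inputs and numerical conventions

Constant columns are rejected everywhere (zero scale); Gram matrices are
symmetrized and their diagonals forced to 1; ρ estimates are clipped at
1 − 1e−10 before any (1−ρ²) computation; the coordinate-descent tolerance
is 1e−7 with a warning (not an error) on non-convergence; Dantzig LPs are
guarded against solver failure although β = G⁻¹g is always feasible for
λ ≥ 0. Edge sets are stored as unordered pairs with i < j.

## Known limitations

- FDR control presumes a sparse differential network and sparse
  class-specific graphs; dense alternatives can inflate the realized FDR.
- The K > 2 mixture weights are a convention, not derived.
- Power on weak-edge (Erdős–Rényi) graphs at n = 100 is near zero — the
  sign-flipped weak edges simply do not separate from the null at that
  sample size; the procedure remains calibrated there.
- The joint-Gaussianity of the transformed variables is assumed, not
  tested; high-dimensional normality checking is an open problem.
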