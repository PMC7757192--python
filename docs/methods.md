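# Methods

## Model

GTM is a constrained Gaussian mixture.  Latent points **x** live on a
regular k×k grid over [−1, 1]²; a fixed basis of M Gaussian RBFs on an
m×m sub-grid maps them into descriptor space, y_k = φ(x_k) W, and every
node k is the center of an isotropic Gaussian of shared precision β.  The
per-compound log-likelihood is

    ln p(t_n) = ln[(1/K) Σ_k (β/2π)^{D/2} exp(−(β/2)‖y_k − t_n‖²)]

and training maximizes its mean over compounds, minus a weight-decay
penalty (λ/2N)‖W‖²_F.

**RBF width.**  σ² is the mean squared Euclidean distance between
distinct RBF-center pairs multiplied by the width factor w, and
φ_km = exp(−‖x_k − μ_m‖²/(2σ²)).  Treating the distance–factor product
as σ² (not as σ to be squared again) keeps w = 0.4 consistent with
standard GTM practice; a `sigma_convention="direct"` switch provides the
other reading.

**Initialization.**  W solves φ W ≈ t̄ + X U in least squares, where X is
the K×2 node-coordinate matrix and U the first two eigenvectors of the
data covariance (sample covariance, ddof = 1; eigenvector signs fixed by
making the largest-magnitude component positive, so the whole pipeline is
deterministic).  φ is K×M and non-square, so a pseudo-inverse/lstsq solve
is the only consistent reading.  Including the data mean t̄ in the target
is what makes the fit translation-equivariant; for standardized input the
mean is zero and the term is inert.  β is initialized to the reciprocal of
the third eigenvalue (the variance the 2-D plane cannot explain), floored
at 1e−12 for rank-deficient data.

**EM.**  The E-step computes responsibilities as a max-shifted softmax of
−(β/2)‖y_k − t_n‖² (the shared prefactor cancels).  The M-step solves

    (φᵀ G φ + (λ/β) I) W_new = φᵀ R T,

with G the diagonal of summed responsibilities, followed by

    1/β_new = (1/ND) Σ_n Σ_k r_nk ‖y_k(W_new) − t_n‖².

The (λ/β) scaling is the MAP M-step for a *fixed* zero-mean Gaussian
weight prior of precision λ — the form in the original GTM literature —
and it provably never decreases the penalized objective
LLh − (λ/2N)‖W‖².  The alternative convention that adds λI directly
(an effective prior that tightens as β grows) is available as
`reg_convention="literal"`, but no fixed objective is monotone under it
(numerically, relative decreases up to ~1e−2 occur), so the provably
ascending form is the default.  With λ = 0 and a near-singular system
(more RBFs than populated nodes) the normal equations square the
condition number; the implementation then falls back to the direct
weighted least-squares solve and warns.

**Convergence.**  Relative change of the penalized objective below
`rel_tol` (default 1e−4), capped at `max_iter` = 100; hitting the cap
flags `converged=False` rather than raising.  The history records the
objective at every iteration, including the initialization.

## Incremental and parallel training

iGTM initializes on the first block (PCA of that block) and runs EM to
convergence on each subsequent block, warm-starting from the previous
state; the result depends on block order, which is exactly the defect
pGTM removes.

pGTM computes one PCA of the whole frame set by streaming per-block
sufficient statistics (count, mean, centered scatter, merged with the
pairwise update of Chan et al., so the result equals batch PCA to float
precision), builds a single shared initialization, fits every block
independently by standard EM, and merges by uniform element-wise
averaging of W and β.  Uniform per-block weights follow the published
averaging rule even when the last block is short; compound-weighted
averaging is deliberately not the default.  Block tasks are pure
functions, so any worker count (joblib) gives bit-identical results and a
serial fallback is exact.  Merging N identical manifolds is the identity
up to one rounding step of the mean ((x+x+x)/3); permuting the block list
changes nothing beyond ~1e−16 summation noise.

## Landscapes, classification, applicability domain

The density landscape is the column sum of the responsibility matrix
(mass = N).  The class landscape stores per node the responsibility-
weighted mean class code s_k = Σ r_nk c_n / Σ r_nk with 1 = inactive,
2 = active; nodes receiving less than 1e−12 total mass are *undefined*.
Prediction projects a compound and averages node scores over defined
nodes, renormalizing by the defined-node mass; the label is the nearest
integer with 1.5 rounding up to "active" (a literal ceiling of any score
above 1 would declare everything active).  Compounds whose whole mass
sits on undefined nodes receive a "no prediction" marker, which the
balanced-accuracy computation counts as an error for their true class.

The applicability domain fits a Gaussian (unweighted least squares,
scipy `curve_fit`, moment-based start, Sturges binning by default) to the
histogram of per-compound log-likelihoods and discards compounds strictly
below peak − 3σ; a value exactly at the threshold is kept.  If all LLh
values coincide, σ = 0 and the threshold degenerates to that value.  The
count-vs-frequency choice for the histogram does not affect the threshold
(the Gaussian's location and width are scale-invariant).

## Metrics

*KLD*: per descriptor, 20 equal-width bins spanning the full collection's
range; both histograms smoothed by ε = 1e−10 before normalization;
natural logarithm; mean and standard deviation across descriptors.
Zero-range descriptors contribute 0.  *Entropy*: cumulated
responsibilities are renormalized to a probability vector before the
entropy sum (otherwise the 0–100 normalization fails), with 0·ln 0 := 0 and
the result clamped to [0, 100] against float round-off.  *CV*: stratified
3-fold splits (seeded; the published protocol says only "three folds"),
class landscape refitted per fold on the fixed responsibilities — the
manifold itself is never retrained.  Targets need ≥ 15 compounds per
class.  N_BA counts targets with mean BA ≥ 0.7, inclusive.

## IC50 labeling

Active threshold: smallest of {10, 50, 100, 300, 500, 700, 1000} nM with
≥ 15 compounds at or below it.  Inactive threshold: smallest of the 10×
grid (100 nM … 10 μM, ascending) classifying ≥ 30 % of records or ≥ 15
compounds as inactive while keeping Inact/Act ≥ 10; compounds strictly
between the thresholds are discarded, boundary values are classified.
The inactive candidate grid is not prescribed anywhere; 10× the active
grid is this package's choice, and it has a structural consequence:
because the inactive count is non-increasing in the threshold and every
10×Act value is on the grid, the smallest qualifying candidate always
lands at exactly 10×Act, so the "relax Act to Inact/10" stage is kept
only for custom grids.  Duplicate (target, compound) records collapse to
their median IC50 before labeling.

## Synthetic data

`generate_gtm_universe` samples exactly from the generative model: node
drawn uniformly, observation = node image + N(0, 1/β) noise.  The planted
W is random but rescaled so the manifold has unit per-dimension spread —
curved enough that the PCA plane is not already the answer, which would
hide EM bugs.  Defaults (N = 2000, D = 20, β = 4, 10×10 nodes, 5×5 RBFs)
are the scale at which noise-precision recovery is tested; the end-to-end
pipeline run uses 20 000 compounds, 40 descriptors and 10 targets at the
published 29×29/18×18 resolution with 5000-compound blocks — sizes chosen
so the whole suite stays desk-scale while still exercising the four-block
merge of the published 20 K worked example.  Activity planting makes
log10 IC50 grow linearly (slope 2 per latent unit, base 3 nM, Gaussian
noise 0.3 log units by default) with distance from a random per-target
center, so labels are spatially coherent and learnable.
`generate_sparse_countlike_descriptors` mimics fragment counts only in
statistical shape (sparse, non-negative, heavy-tailed column frequencies,
with constant/near-constant marker columns for the 2 % filter).

What the synthetic universes do *not* emulate: real descriptor
correlation structure, tautomer/salt artifacts, assay noise
heterogeneity, or the 10⁴-dimensional sparsity of real fragment
descriptors before filtering.  Passing tests therefore certify the
algorithmic machinery (EM correctness, merge algebra, metric
definitions), not predictive performance on real chemistry.

## Numerical choices and limitations

Underflow in responsibilities is handled by max-shifting before
exponentiation.  Standardization removes columns with frame-set std = 0
or < 2 % of the frame-set range (strict inequality) and reuses the
frame-set mean/std for every projected compound.  Descriptors must number
at least 3 (β initialization needs a third eigenvalue).  Only square
latent grids are supported; landscapes are two-class only; plain
averaging is the only merge rule offered — the known mild accuracy cost
of that rule is inherent to the method, and alternative merges are out of
scope.  Exact translation equivariance would need a constant function in
the RBF span (a bias column, which the model formulation omits); at the
default 18×18 basis the representation error is below 1e−6 and the
property-test tolerance reflects that.
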