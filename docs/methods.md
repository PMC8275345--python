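# Methods

## The factorization

`projnmf` fits projective NMF: minimize ‖X − W WᵀX‖_F over W ≥ 0, where
X is the p×n log-transformed, *unnormalized* gene-by-cell count matrix.
Working on unnormalized data is deliberate: depth effects are left in
the data and handled explicitly by the basis-selection screen, where
they are observable, instead of by an upfront normalization whose
residuals would be invisible downstream.

The objective is reported without squaring (‖·‖_F, not ‖·‖_F²);
monotonicity diagnostics are invariant to that choice.

**Updates.** The multiplicative rule
W_ik ← W_ik · 2(XXᵀW)_ik / [(W WᵀXXᵀW)_ik + (XXᵀW WᵀW)_ik]
is applied to all entries simultaneously, followed by a rescaling of the
whole matrix by 1/‖W‖₂. The norm is read as the induced 2-norm (largest
singular value), which keeps WᵀW on the scale of the identity; the
Frobenius norm is available via `norm="frobenius"` since the rescaling
norm is a convention, not a derivation. A guard ε = 1e−10 is added to
every denominator entry: it prevents 0/0 on all-zero genes and is far
below the scale of converged weights, so it does not perturb fixed
points. Multiplicative updates preserve exact zeros, so the support of W
only shrinks; entries are *reported* as zero below 1e−8
(`zero_fraction`), because exact zeros are reached only in the limit.

**Initialization.** W₀ = |W_PCA|: the entrywise absolute value of the
first K PCA loading vectors (left singular vectors of the gene-centered
matrix, computed by a full SVD — deterministic, affordable at panel-design
scales). Centering is a convention choice exposed as `center_init`;
the uncentered variant reproduces textbook examples such as
X = diag(2,1) → coordinate axes. The abs erases PCA's sign ambiguity,
making the whole fit deterministic; the `seed` argument exists only for
interface uniformity.

**Convergence.** Iteration stops when the relative objective change over
one iteration falls below `tol` (default 1e−6) or `max_iter` (default
5000) is reached. The defaults are chosen so that sparsity and mutual
exclusiveness — the properties the rest of the pipeline depends on —
have developed: on the standard synthetic bundle, stopping at relative
change 1e−4 leaves the weight matrix essentially dense (zero fraction
~2%, orthogonality deviation 0.48) and the basis screens have nothing to
work with, while 1e−6 yields zero fraction ~63% and orthogonality
deviation ~0.013. Looser tolerances are fine for a quick embedding; panel
design should keep the default.

**Choosing K.** `k_diagnostic` tabulates, per K, the final objective and
an orthogonality measure: normalize each non-zero column of W, form the
Gram matrix G = W̃ᵀW̃, and report ‖G − I‖_F / √(K(K−1)) — 0 for
perfectly orthogonal bases, 1 when all columns coincide. No automatic
choice is made; K = 20 is the package default, a reasonable operating
point across datasets of a few thousand genes.

## Basis selection

Bases are filtered in three stages; a basis must survive all that apply.

1. **Annotation exclusion (optional).** Users can name bases to drop, or
   supply a housekeeping gene list: a basis is excluded when at least
   half of its top 10% genes by weight fall in that list. The functional
   annotation itself (GO enrichment and the like) is out of scope — the
   per-basis top-gene lists in the report are the hook for external
   services.
2. **Depth screen.** The library size of a cell is approximated by its
   total log-transformed count. A basis is removed when |Pearson r|
   between its score row and the library sizes is ≥ 0.7. The absolute
   value matters: an anti-correlated basis is equally depth-driven. A
   zero-variance score row has no defined correlation; it is recorded as
   r = 0 with a degenerate flag and left for the multimodality test.
3. **Multimodality.** Bases whose scores separate cell populations are
   multimodal across cells. Each non-excluded basis (including those
   failing the depth screen — the test family does not depend on screen
   outcomes) is tested for unimodality; Benjamini–Hochberg at FDR 1%
   across exactly the tested bases decides retention (rejection of
   unimodality ⇒ retained).

## The multimodality test

The statistic is the excess-mass difference between the best two-mode
and best one-mode empirical excess mass, computed as twice Hartigan's
dip statistic (Cheng–Hall identity). The dip itself — the sup-distance
from the empirical cdf to the nearest unimodal cdf — is computed by the
classical greatest-convex-minorant / least-concave-majorant cycling
algorithm, numba-jitted (~0.1 ms at n = 500); the test suite validates
it to 1e−7 against an independent linear-programming oracle that solves
the defining minimax problem directly.

The null distribution of the statistic depends on the shape of the
underlying unimodal density (the uniform is least favorable), so fixed
reference tables are miscalibrated for peaked densities. Calibration is
by smoothed bootstrap from a unimodality-constrained estimate: resample
the data with replacement, add Gaussian noise at the *critical
bandwidth* (the smallest KDE bandwidth at which the density estimate is
unimodal, found by bisection on the mode count over a 512-point grid),
and reflect the result back into the observed sample range. The
reflection is what preserves calibration for compact-support nulls: the
kernel smear otherwise softens the distribution's edges and the test
over-rejects (measured type-I at α = 0.05 of 0.28 on the uniform null
without reflection, 0.02–0.04 with it, across Gaussian, uniform,
exponential, beta(2,2) and t₃ nulls at n = 500). No Silverman variance
rescaling is applied, for the same boundary reason.

P-values are the plain Monte-Carlo proportion #{stat* ≥ stat}/B
(B = 500 by default), deliberately without the add-one correction: the
add-one floor of 1/(B+1) can never clear the BH step-up threshold
fdr·i/K for small rejection counts at K = 20 and FDR 1%, which would
make the multimodality strategy vacuous exactly when it is decisive. A
decisively multimodal basis thus reports p = 0. Samples smaller than 10
or constant return p = 1 with a degenerate flag. A faster, conservative
fallback (`method="dip_uniform"`) calibrates the same statistic against
the uniform null.

## Panel design (M-truncation)

A gene's relevance is its maximum weight across the selected bases —
its strongest contribution to any retained program. Given M, the cut
w_(M) is the M-th largest per-gene maximum; entries strictly below
w_(M) are zeroed (ties at the cut survive) and the M surviving rows,
ordered by descending maximum with ties broken by input gene order, form
W_S,(M). Panels are nested in M except at tie boundaries, where a
warning names the tied genes.

## Projection and label transfer

Reference and new data are restricted to the panel genes (explicit
reordering; missing genes are an error unless `fill_missing=True`
zero-fills) and pass through the same linear map S = W_S,(M)ᵀ X_(M).
The log base used for the reference travels with the weight files as a
metadata tag and is validated against new data, since the map is only
meaningful between identically transformed matrices. Label transfer is
a majority vote among the k = 15 nearest reference cells by Euclidean
distance in score space; vote ties break by smaller mean distance, then
lexicographic label order, and are flagged. Batch-effect correction
between the two embeddings is out of scope: both embeddings are exported
so any external integrator can be applied before classification.

## Synthetic data

The generator plants exactly the structures the pipeline must react to:
disjoint per-cluster marker sets (log fold change `marker_log_fc`,
default 2 natural-log units), a housekeeping block (default 10% of
genes at uniformly high mean 25) whose basis tracks depth, and a
per-cell log-normal depth factor (default sd 0.4) applied to every
gene's mean *before* counts are drawn, so the depth confound is real.
Baseline gene means are log-normal (median 1 count); counts are
negative binomial via gamma–Poisson (dispersion 0.2, the realistic
overdispersed UMI regime) or Poisson for sharper oracle tests. The
standard bundle is 600 cells × 300 genes in 3 clusters with 20 markers
each.

Not emulated: gene–gene correlation beyond cluster structure, batch
effects, zero inflation beyond the count model, continuous trajectories,
and real-data gene-name semantics. Passing tests on this generator
demonstrate that the pipeline recovers planted discrete structure under
depth confounding — not performance on any particular tissue or
platform.

## Problem sizes and numerical choices

The test-suite and acceptance computations run at deliberately small
scales chosen to exercise every code path while staying desk-sized:
factorization descent on 50 random matrices up to 60×80 with K ≤ 6;
multimodality calibration with 200 replicates per null at n = 500 and
B = 500; the full pipeline on the 600×300 bundle at K = 20, M = 60; label
transfer on a held-out 20% of a 500-cell two-cluster dataset. Closed-form
anchors (rank-one SVD limits, a hand-computed update step, dip of two
points = 1/4) are asserted at tight tolerances; Monte-Carlo quantities at
tolerances implied by their replication counts.

## Known limitations

* Multiplicative updates converge slowly near sparse fixed points; very
  large references (tens of thousands of genes) would need a smarter
  solver or a gene pre-filter, since XXᵀ is p×p.
* The depth screen uses a single global correlation threshold; a basis
  both depth-driven and identity-carrying is removed outright.
* The multimodality test detects multimodality, not cluster count;
  a basis separating populations with heavily overlapping score
  distributions can be missed at small n.
* M-truncation ranks genes by maximum weight only; it does not optimize
  panel-level redundancy, and the choice of M itself is left to the
  user.
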