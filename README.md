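# projnmf

Projective non-negative matrix factorization (PNMF) for single-cell
RNA-seq: learn a sparse, non-negative, near-orthogonal low-dimensional
gene encoding of a reference dataset, keep only the components that carry
cell-identity signal, distill them into a fixed-size informative gene
panel, and project new targeted-gene-profiling measurements into the
reference space for cell-type annotation.

## Who this is for

Targeted gene profiling assays (MERFISH, seqFISH, BART-Seq, targeted
sequencing panels) measure tens to a few hundred pre-chosen genes per
cell. Two questions follow: *which genes should go on the panel*, and
*how do the new panel-only measurements get cell-type labels*. `projnmf`
answers both from one reference scRNA-seq dataset, with an unsupervised
factorization rather than per-cluster marker tests, so no clustering of
the reference is required up front.

## The model

For a log-transformed, unnormalized gene-by-cell matrix
X ∈ ℝ≥0^(p×n), PNMF solves

```
min_W ‖X − W Wᵀ X‖_F   subject to   W ≥ 0,     W ∈ ℝ≥0^(p×K)
```

Unlike plain NMF (X ≈ WH), the coefficient matrix is forced to be WᵀX, so
Wᵀ is simultaneously a *projection map* (like PCA loadings) while the
non-negativity makes the columns of W sparse and largely mutually
exclusive (like NMF meta-genes). Each column — a *basis* — is a small
gene program; row k of the score matrix S = WᵀX holds all cells'
coordinates on basis k.

The solver is the classical multiplicative update,

```
W_ik ← W_ik · 2(XXᵀW)_ik / [(W WᵀXXᵀW)_ik + (XXᵀW WᵀW)_ik],   W ← W/‖W‖₂
```

initialized from the entrywise absolute value of the PCA loading matrix.

Downstream, three screens pick the informative bases: an optional
annotation-based exclusion list, removal of bases whose scores correlate
with per-cell sequencing depth (|Pearson r| ≥ 0.7 with total log
counts), and retention of bases whose score distribution is *multimodal*
across cells — judged by an excess-mass (dip) statistic calibrated by a
bootstrap from a unimodality-constrained density estimate, with
Benjamini–Hochberg FDR control at 1%. The selected weight matrix W_S is
then *M-truncated*: the M genes with the largest maximum weight across
selected bases form the panel, sub-threshold weights are zeroed, and
W_S,(M)ᵀ projects both reference and new panel data into the shared
K₀-dimensional space, where any classifier (a KNN vote is built in)
transfers labels.

## Worked example

```python
import projnmf as pj

raw, truth = pj.simulate_counts(seed=1)        # 300 genes x 600 cells, 3 clusters
X = pj.log_transform(raw)
W, S, diag = pj.fit_pnmf(X, K=20)
W_S, reports = pj.select_bases(W, S, X, B=500, seed=3)
panel = pj.informative_genes(W_S, 60)
```

Running `python examples/01_simulate_and_fit.py` through
`04_project_and_transfer.py` prints, on this data:

```
converged: True after 3465 iterations
objective ||X - W W'X||_F: 5271.8 -> 198.5
weight sparsity (zero fraction): 63.2%
orthogonality deviation (0 = orthogonal bases): 0.0127

selected 3 of 20 bases
most depth-correlated basis: basis1 (r = 0.96, 77% housekeeping in its top genes)

panel of 60 genes, weight cut w_(M) = 0.0266
planted markers recovered: 60/60 (100%)

label-transfer accuracy on held-out cells: 100.0%
```

Reading: the fit produced sparse near-orthogonal gene programs; the
selection step discarded the basis tracking sequencing depth (driven by
the planted housekeeping block) and kept the three multimodal bases that
separate the three clusters; the 60-gene panel recovered every planted
marker; and held-out cells projected through the panel were labeled
perfectly by the 15-nearest-neighbour vote.

The same pipeline is scriptable from the shell:

```
projnmf simulate --seed 1 --out-counts counts.mtx --out-truth truth.tsv
projnmf run-all --input expr.tsv --outdir out --seed 1 --m 60
```

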