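"""Simulate clustered counts and fit the projective NMF encoding.

Generates a 300-gene x 600-cell negative-binomial count matrix with three
cell clusters, planted marker genes, a housekeeping block and per-cell
depth variation; log1p-transforms it; and fits K=20 non-negative bases.
"""
import projnmf as pj

raw, truth = pj.simulate_counts(seed=1)
X = pj.log_transform(raw)
print(f"data: {X.n_genes} genes x {X.n_cells} cells, "
      f"clusters: {sorted(set(truth.cluster_of_cell))}")

W, S, diag = pj.fit_pnmf(X, K=20)
print(f"converged: {diag.converged} after {diag.iterations_run} iterations")
print(f"objective ||X - W W'X||_F: {diag.objective_trace[0]:.1f} -> "
      f"{diag.objective_trace[-1]:.1f}")
print(f"weight sparsity (zero fraction): {100 * pj.zero_fraction(W):.1f}%")
print(f"orthogonality deviation (0 = orthogonal bases): {diag.orthogonality:.4f}")

# A sparse, near-orthogonal W means each basis is a small, largely
# disjoint gene set -- an interpretable gene program -- and W' doubles as
# a projection map for new data.
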