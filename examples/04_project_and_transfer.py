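"""Project held-out cells through the panel and transfer their labels.

A fifth of the cells are held out as "new" targeted-panel measurements.
Both cell sets pass through the same linear map W_(M)', so they land in
one shared low-dimensional space where a K-nearest-neighbour vote
annotates the new cells from the reference labels.
"""
import numpy as np

import projnmf as pj

raw, truth = pj.simulate_counts(n_clusters=2, n_cells=500, seed=11)
X = pj.log_transform(raw)

rng = np.random.default_rng(0)
idx = rng.permutation(X.n_cells)
test, train = np.sort(idx[:100]), np.sort(idx[100:])
sub = lambda cols: pj.LogExpressionMatrix(
    X.values[:, cols], X.gene_ids, [X.cell_ids[i] for i in cols],
    log_base=X.log_base)
Xtr, Xte = sub(train), sub(test)

W, S, _ = pj.fit_pnmf(Xtr, K=20)
W_S, _ = pj.select_bases(W, S, Xtr, B=500, seed=3)
W_M = pj.m_truncate(W_S, 40)

ref = pj.embed(W_M, pj.align_genes(W_M, Xtr), "reference")
new = pj.embed(W_M, pj.align_genes(W_M, Xte), "new")
labels = pj.LabeledCells(Xtr.cell_ids, [truth.cluster_of_cell[i] for i in train])
pred = pj.knn_label_transfer(ref, labels, new, k=15)

truth_te = np.array([truth.cluster_of_cell[i] for i in test])
acc = np.mean(pred["predicted_label"].to_numpy() == truth_te)
print(f"embedded {len(train)} reference + {len(test)} new cells "
      f"into {len(W_M.basis_labels)} dimensions via a {W_M.n_genes}-gene panel")
print(f"label-transfer accuracy on held-out cells: {100 * acc:.1f}%")
print(pred.head().to_string(index=False))
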