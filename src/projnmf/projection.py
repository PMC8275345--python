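"""Embedding reference and targeted-panel data, and transferring labels.

With a truncated weight matrix ``W_(M)`` the embedding of any matrix
restricted to the panel genes is the linear map ``S = W_(M)ᵀ X_(M)``.
Reference data and new targeted-gene-profiling data pass through the
same map, so both cell sets land in the same K₀-dimensional space and a
classifier trained on labeled reference embeddings can annotate the new
cells. A K-nearest-neighbour majority vote is provided as the built-in
transfer; the exported embeddings can feed any external classifier or
batch integrator.

New data must be log-transformed with the same base as the reference;
the base travels with the weight files as a metadata tag and is checked
here.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import Embedding, LabeledCells, LogExpressionMatrix, TruncatedWeights
from .errors import ValidationError

__all__ = ["align_genes", "embed", "knn_label_transfer"]


def align_genes(
    W_M: TruncatedWeights,
    X: LogExpressionMatrix,
    fill_missing: bool = False,
) -> LogExpressionMatrix:
    """Restrict X to the panel genes, in panel order.

    Missing panel genes are an error naming the genes; with
    ``fill_missing=True`` they become all-zero rows instead (for panels
    measured incompletely by the targeted assay).
    """
    index = {g: i for i, g in enumerate(X.gene_ids)}
    missing = [g for g in W_M.gene_ids if g not in index]
    if missing and not fill_missing:
        raise ValidationError(
            f"{len(missing)} panel gene(s) absent from the expression matrix: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}; "
            "pass fill_missing=True to zero-fill"
        )
    rows = np.zeros((len(W_M.gene_ids), X.n_cells))
    for i, g in enumerate(W_M.gene_ids):
        if g in index:
            rows[i] = X.values[index[g]]
    return LogExpressionMatrix(rows, list(W_M.gene_ids), X.cell_ids, log_base=X.log_base)


def embed(
    W_M: TruncatedWeights, X_M: LogExpressionMatrix, source: str = "reference"
) -> Embedding:
    """Project panel-restricted expression into the selected basis space."""
    if X_M.gene_ids != W_M.gene_ids:
        raise ValidationError(
            "expression rows are not in panel order; run align_genes first"
        )
    if (
        W_M.log_base != "unknown"
        and X_M.log_base != "unknown"
        and W_M.log_base != X_M.log_base
    ):
        raise ValidationError(
            f"log base mismatch: weights fitted on {W_M.log_base!r} data, "
            f"expression is {X_M.log_base!r}"
        )
    return Embedding(W_M.weights.T @ X_M.values, list(W_M.basis_labels),
                     X_M.cell_ids, source=source)


def knn_label_transfer(
    ref: Embedding,
    labels: LabeledCells,
    new: Embedding,
    k: int = 15,
) -> pd.DataFrame:
    """Majority vote among the k nearest reference cells in embedding space.

    Distances are Euclidean in score space. Vote ties are broken by the
    smaller mean distance to the voting neighbours, then by lexicographic
    label order; tied cells are flagged. Returns a frame with columns
    ``cell_id, predicted_label, vote_fraction, tie``.
    """
    if ref.basis_labels != new.basis_labels:
        raise ValidationError("reference and new embeddings use different bases")
    if labels.cell_ids != ref.cell_ids:
        raise ValidationError("labels do not match the reference cells")
    n_ref = ref.scores.shape[1]
    if not 1 <= k <= n_ref:
        raise ValidationError(f"k must be in [1, {n_ref}], got {k}")

    nn = NearestNeighbors(n_neighbors=k).fit(ref.scores.T)
    dist, idx = nn.kneighbors(new.scores.T)
    lab = np.asarray(labels.labels, dtype=object)
    rows = []
    for j, cell in enumerate(new.cell_ids):
        votes: dict[str, list[float]] = {}
        for d, i in zip(dist[j], idx[j]):
            votes.setdefault(lab[i], []).append(float(d))
        best = max(votes)  # placeholder, replaced below
        top_count = max(len(v) for v in votes.values())
        tied = [lbl for lbl, v in votes.items() if len(v) == top_count]
        tie = len(tied) > 1
        if tie:
            # smaller mean distance wins, then lexicographic order
            tied.sort(key=lambda lbl: (float(np.mean(votes[lbl])), lbl))
        best = tied[0]
        rows.append(
            {"cell_id": cell, "predicted_label": best,
             "vote_fraction": top_count / k, "tie": tie}
        )
    return pd.DataFrame(rows)
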