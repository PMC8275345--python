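"""M-truncation: turning selected bases into a fixed-size gene panel.

A gene's relevance is its maximum weight across the selected bases — the
strongest contribution it makes to any retained gene program. Given a
panel size M, the cut value w_(M) is the M-th largest of these per-gene
maxima; all weights below w_(M) are zeroed and the M rows that remain
non-zero form the truncated weight matrix, ordered by descending maximum
(ties by original gene order). Entries exactly equal to w_(M) survive the
strict "< w_(M)" zeroing.

The panels are nested: the gene set at M is contained in the set at any
larger M (absent ties at the boundary). Ties straddling rank M are
resolved by input gene order and reported with a warning.
"""
from __future__ import annotations

import warnings

import numpy as np

from .containers import TruncatedWeights, WeightMatrix
from .errors import ValidationError

__all__ = ["m_truncate", "informative_genes"]


def m_truncate(W_S: WeightMatrix, M: int) -> TruncatedWeights:
    """Select the M most informative genes and zero sub-threshold weights."""
    maxima = W_S.weights.max(axis=1)
    n_nonzero = int(np.sum(maxima > 0))
    if not 1 <= M <= n_nonzero:
        raise ValidationError(
            f"M must be in [1, {n_nonzero}] (rows with a positive entry), got {M}"
        )
    order = np.argsort(-maxima, kind="stable")  # descending, ties by gene order
    w_M = float(maxima[order[M - 1]])
    tied = np.flatnonzero(maxima == w_M)
    if len(tied) > 1:
        # only warn when the tie actually straddles the cut
        in_panel = set(order[:M].tolist())
        if not set(tied.tolist()) <= in_panel:
            names = [W_S.gene_ids[i] for i in tied]
            warnings.warn(
                f"{len(tied)} genes tied at w_(M)={w_M:.6g}; kept the earliest "
                f"by input order among {names}",
                stacklevel=2,
            )
    keep = order[:M]
    truncated = W_S.weights[keep].copy()
    truncated[truncated < w_M] = 0.0
    return TruncatedWeights(
        truncated,
        [W_S.gene_ids[i] for i in keep],
        list(W_S.basis_labels),
        threshold_w=w_M,
        log_base=W_S.log_base,
    )


def informative_genes(W_S: WeightMatrix, M: int) -> list[str]:
    """The M panel genes in selection-rank order (same order as m_truncate rows)."""
    return list(m_truncate(W_S, M).gene_ids)
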