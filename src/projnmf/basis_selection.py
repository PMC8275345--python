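"""Selection of informative bases (step II of the workflow).

Three filters are applied in order and a basis is retained only if it
survives all of them:

1. *Annotation exclusion* (optional, knowledge-driven): drop bases named
   by the user, or bases whose top genes overlap a supplied housekeeping
   gene set by at least half.
2. *Library-size screen*: drop bases whose score row has |Pearson r| with
   the per-cell total log counts at or above a threshold (default 0.7);
   such bases track sequencing depth, not biology.
3. *Multimodality*: keep bases whose score distribution across cells is
   multimodal, judged by the excess-mass bootstrap test with
   Benjamini–Hochberg control of the FDR at 1% across the tested bases.
   A multimodal score row is what separates cell populations.

The screen uses |r| rather than signed r: a strongly anti-correlated
basis is equally depth-driven. Multimodality tests run on all bases not
excluded by annotation (including those failing the correlation screen),
and the BH family is exactly that tested set.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import (
    BasisReport,
    LibrarySizeVector,
    LogExpressionMatrix,
    ScoreMatrix,
    WeightMatrix,
)
from .errors import EmptySelectionError, ValidationError
from .modality import multimodality_test

__all__ = [
    "library_sizes",
    "correlation_screen",
    "bh_adjust",
    "top_weight_genes",
    "select_bases",
]

HOUSEKEEPING_OVERLAP = 0.5  # exclusion rule: >= half of a basis' top genes


def library_sizes(X: LogExpressionMatrix) -> LibrarySizeVector:
    """Per-cell totals of log-transformed counts (column sums of X)."""
    return LibrarySizeVector(X.values.sum(axis=0), X.cell_ids)


def correlation_screen(
    S: ScoreMatrix, lib: LibrarySizeVector, threshold: float = 0.7
) -> pd.DataFrame:
    """Pearson correlation of every score row with the library sizes.

    Returns a frame with columns ``basis_label, r, keep, degenerate``;
    ``keep`` is ``|r| < threshold``. A zero-variance score row has no
    defined correlation: it is recorded as r = 0 with the degenerate flag
    and left for the multimodality test to judge.
    """
    if S.cell_ids != lib.cell_ids:
        raise ValidationError("score matrix and library sizes refer to different cells")
    if S.n_cells < 3:
        raise ValidationError("correlation screen needs at least 3 cells")
    lv = lib.values - lib.values.mean()
    lib_sd = float(np.sqrt((lv**2).sum()))
    rows = []
    for k, label in enumerate(S.basis_labels):
        s = S.scores[k] - S.scores[k].mean()
        s_sd = float(np.sqrt((s**2).sum()))
        if s_sd == 0.0 or lib_sd == 0.0:
            rows.append({"basis_label": label, "r": 0.0, "keep": True, "degenerate": True})
            continue
        r = float((s @ lv) / (s_sd * lib_sd))
        rows.append(
            {"basis_label": label, "r": r, "keep": bool(abs(r) < threshold),
             "degenerate": False}
        )
    return pd.DataFrame(rows)


def bh_adjust(pvalues, fdr: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(adjusted_pvalues, reject_flags)``; a rejected (multimodal)
    basis is a retained basis.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adjusted, reject


def top_weight_genes(
    W: WeightMatrix, basis: int, fraction: float = 0.10
) -> list[str]:
    """The ⌈fraction·p⌉ genes with largest weight in one basis, descending.

    Ties are broken by input gene order (stable sort). These are the genes
    a functional-annotation service would be queried with.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    if not 0 <= basis < W.n_bases:
        raise ValidationError(f"basis index {basis} out of range")
    m = math.ceil(fraction * W.n_genes)
    order = np.argsort(-W.weights[:, basis], kind="stable")
    return [W.gene_ids[i] for i in order[:m]]


def _annotation_excluded(
    W: WeightMatrix,
    exclude_labels: list[str] | None,
    housekeeping_genes: list[str] | None,
    top_fraction: float,
) -> list[bool]:
    explicit = set(exclude_labels or [])
    unknown = explicit - set(W.basis_labels)
    if unknown:
        raise ValidationError(f"exclude labels not present: {sorted(unknown)}")
    hk = set(housekeeping_genes or [])
    flags = []
    for k, label in enumerate(W.basis_labels):
        flag = label in explicit
        if not flag and hk:
            top = top_weight_genes(W, k, top_fraction)
            flag = len(hk.intersection(top)) >= HOUSEKEEPING_OVERLAP * len(top)
        flags.append(flag)
    return flags


def select_bases(
    W: WeightMatrix,
    S: ScoreMatrix,
    X: LogExpressionMatrix,
    exclude_labels: list[str] | None = None,
    housekeeping_genes: list[str] | None = None,
    corr_threshold: float = 0.7,
    fdr: float = 0.01,
    B: int = 500,
    seed: int | None = None,
    top_fraction: float = 0.10,
    method: str = "excess_mass",
) -> tuple[WeightMatrix, list[BasisReport]]:
    """Apply all three filters and stack the surviving columns into W_S.

    Column order of the input is preserved. Raises
    :class:`EmptySelectionError` when nothing survives, naming the
    thresholds to revisit.
    """
    if W.basis_labels != S.basis_labels:
        raise ValidationError("weight and score matrices disagree on basis labels")
    if W.gene_ids != X.gene_ids or S.cell_ids != X.cell_ids:
        raise ValidationError("weight/score/expression matrices are inconsistent")

    excluded = _annotation_excluded(W, exclude_labels, housekeeping_genes, top_fraction)
    lib = library_sizes(X)
    corr = correlation_screen(S, lib, threshold=corr_threshold)

    rng = np.random.default_rng(seed)
    tested_idx = [k for k in range(W.n_bases) if not excluded[k]]
    pvals, degen = [], []
    for k in tested_idx:
        # each basis draws its own child stream: results do not depend on
        # which other bases happen to be excluded upstream of the test
        p, d = multimodality_test(S.scores[k], B=B, seed=rng.spawn(1)[0], method=method)
        pvals.append(p)
        degen.append(d)
    adjusted, reject = bh_adjust(pvals, fdr=fdr)

    p_of = {k: (pvals[i], adjusted[i], bool(reject[i]), degen[i])
            for i, k in enumerate(tested_idx)}
    reports: list[BasisReport] = []
    keep_cols: list[int] = []
    for k, label in enumerate(W.basis_labels):
        pv, ap, rej, dg = p_of.get(k, (1.0, 1.0, False, False))
        keep_corr = bool(corr.loc[k, "keep"])
        retained = (not excluded[k]) and keep_corr and rej
        if retained:
            keep_cols.append(k)
        reports.append(
            BasisReport(
                basis_label=label,
                libsize_correlation=float(corr.loc[k, "r"]),
                multimodality_pvalue=float(pv),
                adjusted_pvalue=float(ap),
                retained_by_correlation=keep_corr,
                retained_by_multimodality=rej,
                excluded_by_annotation=bool(excluded[k]),
                retained=retained,
                top_genes=top_weight_genes(W, k, top_fraction),
                correlation_degenerate=bool(corr.loc[k, "degenerate"]),
                pvalue_degenerate=bool(dg),
            )
        )
    if not keep_cols:
        raise EmptySelectionError(
            "no basis survived selection; consider raising corr_threshold "
            f"(currently {corr_threshold}) or fdr (currently {fdr})"
        )
    W_S = WeightMatrix(
        W.weights[:, keep_cols],
        W.gene_ids,
        [W.basis_labels[k] for k in keep_cols],
        log_base=W.log_base,
    )
    return W_S, reports


def report_frame(reports: list[BasisReport]) -> pd.DataFrame:
    """Tabular view of a BasisReport list (top genes joined by commas)."""
    return pd.DataFrame(
        [
            {
                "basis_label": r.basis_label,
                "libsize_correlation": r.libsize_correlation,
                "multimodality_pvalue": r.multimodality_pvalue,
                "adjusted_pvalue": r.adjusted_pvalue,
                "retained_by_correlation": r.retained_by_correlation,
                "retained_by_multimodality": r.retained_by_multimodality,
                "excluded_by_annotation": r.excluded_by_annotation,
                "retained": r.retained,
                "top_genes": ",".join(r.top_genes),
            }
            for r in reports
        ]
    )
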