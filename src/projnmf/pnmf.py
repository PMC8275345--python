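"""Projective non-negative matrix factorization (PNMF).

PNMF finds a non-negative weight matrix ``W`` (genes × K) minimizing

    ‖X − W Wᵀ X‖_F ,   W ≥ 0,

so that ``Wᵀ`` is simultaneously a projection map into a K-dimensional
space and a catalogue of sparse, largely mutually exclusive gene programs
(each column of ``W`` weights a small gene set). The solver is a
multiplicative update scheme started from the entrywise absolute value of
the PCA loading matrix, which biases the iteration toward nearly
orthogonal bases:

    W_ik ← W_ik · 2 (X Xᵀ W)_ik / [ (W Wᵀ X Xᵀ W)_ik + (X Xᵀ W Wᵀ W)_ik ]

followed by a rescaling of the whole matrix by 1/‖W‖₂. Multiplicative
updates preserve zeros exactly, so the support of ``W`` can only shrink.

The induced matrix 2-norm (largest singular value) is used for the
rescaling, which keeps ``WᵀW`` on the scale of the identity; the Frobenius
norm is available as an option. PCA initialization centers each gene by
default; both choices are exposed because neither is canonical.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FitDiagnostics, LogExpressionMatrix, ScoreMatrix, WeightMatrix
from .errors import DegenerateInputError, NumericalError, ValidationError

__all__ = [
    "initialize_weights",
    "pnmf_update_step",
    "fit_pnmf",
    "compute_scores",
    "orthogonality",
    "k_diagnostic",
    "zero_fraction",
]

#: multiplicative-update denominator guard; avoids 0/0 for all-zero genes
#: without perturbing converged values
EPS = 1e-10

#: entries below this are reported as zero when summarizing sparsity
#: (multiplicative updates reach zero only in the limit)
ZERO_TOL = 1e-8


def initialize_weights(
    X: LogExpressionMatrix, K: int, center: bool = True
) -> WeightMatrix:
    """Entrywise absolute value of the first K PCA loading vectors of X.

    Loadings are gene-wise (left singular vectors of the gene-centered
    matrix), each of unit Euclidean norm, so the result is deterministic:
    the sign ambiguity of PCA is erased by the absolute value.
    """
    p, n = X.values.shape
    if not 1 <= K <= min(p, n):
        raise ValidationError(f"K must be in [1, min(p, n)] = [1, {min(p, n)}], got {K}")
    A = X.values - X.values.mean(axis=1, keepdims=True) if center else X.values
    if not np.any(A):
        raise DegenerateInputError(
            "matrix has zero variance; PCA initialization is undefined"
        )
    # full SVD is affordable at the gene counts this package targets and is
    # deterministic, unlike randomized/Krylov alternatives
    U, _, _ = np.linalg.svd(A, full_matrices=False)
    W = np.abs(U[:, :K])
    labels = [f"basis{k + 1}" for k in range(K)]
    return WeightMatrix(W, X.gene_ids, labels, log_base=X.log_base)


def _spectral_norm(W: np.ndarray) -> float:
    return float(np.linalg.norm(W, 2))


def pnmf_update_step(
    W: np.ndarray, XXt: np.ndarray, eps: float = EPS, norm: str = "spectral"
) -> np.ndarray:
    """One multiplicative update followed by matrix rescaling.

    ``XXt`` is the precomputed ``p × p`` Gram matrix ``X Xᵀ`` (symmetric
    PSD). Entries that are exactly zero stay exactly zero.
    """
    if norm not in ("spectral", "frobenius"):
        raise ValidationError("norm must be 'spectral' or 'frobenius'")
    if not np.any(W):
        raise DegenerateInputError("all-zero weight matrix cannot be updated")
    XXtW = XXt @ W
    WtW = W.T @ W
    denom = W @ (W.T @ XXtW) + XXtW @ WtW
    Wnew = W * (2.0 * XXtW) / (denom + eps)
    s = _spectral_norm(Wnew) if norm == "spectral" else float(np.linalg.norm(Wnew))
    if s == 0.0:
        raise DegenerateInputError("update produced an all-zero weight matrix")
    return Wnew / s


def _objective(X: np.ndarray, W: np.ndarray) -> float:
    # ‖X − W WᵀX‖_F, evaluated without squaring
    return float(np.linalg.norm(X - W @ (W.T @ X)))


def fit_pnmf(
    X: LogExpressionMatrix,
    K: int = 20,
    tol: float = 1e-6,
    max_iter: int = 5000,
    seed: int | None = None,
    center_init: bool = True,
    norm: str = "spectral",
) -> tuple[WeightMatrix, ScoreMatrix, FitDiagnostics]:
    """Fit PNMF by multiplicative updates from the abs-PCA start.

    Iterates until the relative change of the objective over one iteration
    drops below ``tol`` or ``max_iter`` is reached. ``seed`` is accepted
    for interface uniformity; the algorithm is deterministic.

    Returns the weight matrix, the score matrix ``S = WᵀX`` and a
    diagnostics record whose objective trace includes the initial value.
    """
    del seed  # deterministic: abs-PCA start, no random restarts
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    W0 = initialize_weights(X, K, center=center_init)
    Xv = X.values
    XXt = Xv @ Xv.T
    W = W0.weights.copy()
    trace = [_objective(Xv, W)]
    converged = False
    for it in range(1, max_iter + 1):
        W = pnmf_update_step(W, XXt, norm=norm)
        obj = _objective(Xv, W)
        if not np.isfinite(obj) or not np.all(np.isfinite(W)):
            raise NumericalError(f"non-finite objective at iteration {it}")
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break
    Wm = WeightMatrix(W, X.gene_ids, W0.basis_labels, log_base=X.log_base)
    S = ScoreMatrix(W.T @ Xv, W0.basis_labels, X.cell_ids)
    diag = FitDiagnostics(
        objective_trace=np.asarray(trace),
        iterations_run=len(trace) - 1,
        converged=converged,
        orthogonality=orthogonality(Wm) if K >= 2 else float("nan"),
    )
    return Wm, S, diag


def compute_scores(W: WeightMatrix, X: LogExpressionMatrix) -> ScoreMatrix:
    """S = Wᵀ X. Gene identifiers must match in order (no silent reordering)."""
    if W.gene_ids != X.gene_ids:
        raise ValidationError(
            "gene_ids of weight matrix and expression matrix differ; "
            "use projection.align_genes for explicit reordering"
        )
    return ScoreMatrix(W.weights.T @ X.values, W.basis_labels, X.cell_ids)


def orthogonality(W: WeightMatrix) -> float:
    """Deviation of the basis set from orthogonality, in [0, 1]-ish scale.

    Columns are normalized to unit length (zero columns excluded), the Gram
    matrix ``G = W̃ᵀW̃`` is formed, and ``‖G − I‖_F / √(K(K−1))`` returned:
    0 for perfectly orthogonal bases, 1 when all columns coincide.
    """
    if W.n_bases < 2:
        raise ValidationError("orthogonality needs at least two bases")
    norms = np.linalg.norm(W.weights, axis=0)
    keep = norms > 0
    Wt = W.weights[:, keep] / norms[keep]
    K = Wt.shape[1]
    if K < 2:
        raise ValidationError("fewer than two non-zero columns")
    G = Wt.T @ Wt
    return float(np.linalg.norm(G - np.eye(K)) / np.sqrt(K * (K - 1)))


def zero_fraction(W: WeightMatrix, tol: float = ZERO_TOL) -> float:
    """Fraction of weight entries that are numerically zero (< tol)."""
    return float(np.mean(W.weights < tol))


def k_diagnostic(
    X: LogExpressionMatrix,
    K_grid: list[int],
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Fit PNMF over a grid of K and tabulate orthogonality + final objective.

    No automatic choice is made; K = 20 is the package default downstream.
    Duplicated grid entries are deduplicated with a warning; a failing K is
    recorded with NaN diagnostics and the grid continues.
    """
    if len(K_grid) == 0:
        raise ValidationError("K grid must not be empty")
    grid = list(dict.fromkeys(int(k) for k in K_grid))
    if len(grid) != len(K_grid):
        warnings.warn("duplicate K values in grid were removed", stacklevel=2)
    rows = []
    for K in grid:
        try:
            _, _, diag = fit_pnmf(X, K=K, tol=tol, max_iter=max_iter)
            rows.append(
                {"K": K, "orthogonality": diag.orthogonality,
                 "final_objective": diag.objective_trace[-1],
                 "converged": diag.converged, "error": ""}
            )
        except Exception as exc:  # keep scanning the grid
            warnings.warn(f"K={K} failed: {exc}", stacklevel=2)
            rows.append(
                {"K": K, "orthogonality": float("nan"),
                 "final_objective": float("nan"), "converged": False,
                 "error": str(exc)}
            )
    return pd.DataFrame(rows)
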