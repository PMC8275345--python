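"""In-memory containers for expression data, factorization output and reports.

Conventions
-----------
* Expression matrices are genes-by-cells (``p × n``); scores are
  bases-by-cells (``K × n``); weights are genes-by-bases (``p × K``).
* Identifiers are ordered, unique strings; order is meaningful everywhere.
* Values are dense ``float64`` arrays: the target scale (hundreds to a few
  thousand genes after panel design, tens of thousands of cells) does not
  warrant sparse linear algebra in the fit itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "LogExpressionMatrix",
    "WeightMatrix",
    "ScoreMatrix",
    "FitDiagnostics",
    "TruncatedWeights",
    "Embedding",
    "LibrarySizeVector",
    "BasisReport",
    "LabeledCells",
    "SimTruth",
]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class LogExpressionMatrix:
    """A log-transformed, non-negative gene-by-cell expression matrix.

    Parameters
    ----------
    values
        ``(p, n)`` array, all entries finite and >= 0.
    gene_ids, cell_ids
        Unique, ordered identifiers for rows and columns.
    log_base
        Tag recording which log transform produced the values
        (``"natural"``, ``"2"`` or ``"unknown"``). Used to validate that
        new data entering a projection matches the reference transform.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    log_base: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        p, n = self.values.shape
        if p < 1 or n < 1:
            raise ValidationError("matrix must have at least one gene and one cell")
        if len(self.gene_ids) != p or len(self.cell_ids) != n:
            raise ValidationError(
                f"id lengths ({len(self.gene_ids)}, {len(self.cell_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightMatrix:
    """Non-negative gene-by-basis weights W (each column is one basis)."""

    weights: np.ndarray
    gene_ids: list[str]
    basis_labels: list[str]
    log_base: str = "unknown"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValidationError("weights must be a 2-D array")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        self.basis_labels = _check_ids(self.basis_labels, "basis_labels")
        p, k = self.weights.shape
        if len(self.gene_ids) != p or len(self.basis_labels) != k:
            raise ValidationError("id lengths do not match weight shape")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights contain non-finite entries")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bases(self) -> int:
        return self.weights.shape[1]


@dataclass
class ScoreMatrix:
    """Basis-by-cell embedding S = Wᵀ X."""

    scores: np.ndarray
    basis_labels: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2-D array")
        self.basis_labels = _check_ids(self.basis_labels, "basis_labels")
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        if (len(self.basis_labels), len(self.cell_ids)) != self.scores.shape:
            raise ValidationError("id lengths do not match score shape")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores contain non-finite entries")

    @property
    def n_bases(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cells(self) -> int:
        return self.scores.shape[1]


@dataclass
class FitDiagnostics:
    """Convergence record of one factorization run.

    ``objective_trace`` holds ‖X − W WᵀX‖_F per iteration, including the
    value at initialization, so its length is ``iterations_run + 1``.
    ``orthogonality`` is ``nan`` for K = 1, where the measure is undefined.
    """

    objective_trace: np.ndarray
    iterations_run: int
    converged: bool
    orthogonality: float

    def __post_init__(self) -> None:
        self.objective_trace = np.asarray(self.objective_trace, dtype=np.float64)
        if len(self.objective_trace) != self.iterations_run + 1:
            raise ValidationError("objective_trace must include the initial value")


@dataclass
class TruncatedWeights:
    """M-truncated selected weights: exactly M rows, ranked by per-gene max weight."""

    weights: np.ndarray
    gene_ids: list[str]
    basis_labels: list[str]
    threshold_w: float
    log_base: str = "unknown"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        self.basis_labels = _check_ids(self.basis_labels, "basis_labels")
        if (len(self.gene_ids), len(self.basis_labels)) != self.weights.shape:
            raise ValidationError("id lengths do not match truncated weight shape")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")
        live = self.weights >= self.threshold_w
        if not np.all(live.any(axis=1)):
            raise ValidationError("every truncated row must keep one weight >= threshold")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


@dataclass
class Embedding:
    """Cells embedded in the selected low-dimensional space."""

    scores: np.ndarray
    basis_labels: list[str]
    cell_ids: list[str]
    source: str = "reference"  # {"reference", "new"}

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.basis_labels = _check_ids(self.basis_labels, "basis_labels")
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        if (len(self.basis_labels), len(self.cell_ids)) != self.scores.shape:
            raise ValidationError("id lengths do not match embedding shape")
        if self.source not in ("reference", "new"):
            raise ValidationError("source must be 'reference' or 'new'")


@dataclass
class LibrarySizeVector:
    """Per-cell totals of log-transformed counts (library-size proxy)."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        if self.values.ndim != 1 or len(self.values) != len(self.cell_ids):
            raise ValidationError("library sizes must be one value per cell")
        if np.any(self.values < 0):
            raise ValidationError("library sizes must be non-negative")


@dataclass
class BasisReport:
    """Per-basis diagnostics from the selection step."""

    basis_label: str
    libsize_correlation: float
    multimodality_pvalue: float
    adjusted_pvalue: float
    retained_by_correlation: bool
    retained_by_multimodality: bool
    excluded_by_annotation: bool
    retained: bool
    top_genes: list[str] = field(default_factory=list)
    correlation_degenerate: bool = False
    pvalue_degenerate: bool = False


@dataclass
class LabeledCells:
    """Cell-type labels for reference cells, one label per cell."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        self.labels = [str(v) for v in self.labels]
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError("exactly one label per cell is required")


@dataclass
class SimTruth:
    """Ground truth bundled with a simulated count matrix."""

    cluster_of_cell: list[str]
    marker_genes_by_cluster: dict[str, list[str]]
    housekeeping_genes: list[str]
    libsize_factor: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.libsize_factor = np.asarray(self.libsize_factor, dtype=np.float64)
        if np.any(self.libsize_factor <= 0):
            raise ValidationError("library size factors must be positive")
        marker_sets = [set(v) for v in self.marker_genes_by_cluster.values()]
        hk = set(self.housekeeping_genes)
        flat: set[str] = set()
        for s in marker_sets:
            if flat & s or hk & s:
                raise ValidationError("marker/housekeeping gene sets must be disjoint")
            flat |= s

    @property
    def all_marker_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.marker_genes_by_cluster.values():
            out.extend(genes)
        return out
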