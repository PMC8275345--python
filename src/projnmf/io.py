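"""Reading and writing expression matrices, weights, scores and gene lists.

On-disk formats are plain text: Matrix Market triplets with companion id
files (one id per line), or dense TSV/CSV with a header row of cell ids and
a first column of gene ids. Writers prepend ``#`` provenance comment lines;
readers skip them.

The on-disk layout (genes-by-cells vs cells-by-genes) is never guessed:
callers state it explicitly and the reader transposes to the in-memory
genes-by-cells convention.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import LogExpressionMatrix, ScoreMatrix, TruncatedWeights, WeightMatrix
from .errors import ParseError, ValidationError

__all__ = [
    "read_matrix",
    "log_transform",
    "write_expression_matrix",
    "write_weight_matrix",
    "read_weight_matrix",
    "write_score_matrix",
    "read_score_matrix",
    "write_gene_list",
    "read_gene_list",
    "write_mtx",
]

_FORMATS = ("mtx", "tsv", "csv")
_LAYOUTS = ("genes_by_cells", "cells_by_genes")


def _read_id_file(path: Path, what: str) -> list[str]:
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise ParseError(f"cannot read {what} file {path}: {exc}") from exc
    ids = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not ids:
        raise ParseError(f"{what} file {path} contains no identifiers")
    return ids


def read_matrix(
    path: str | Path,
    format: str = "tsv",
    layout: str = "genes_by_cells",
    gene_file: str | Path | None = None,
    cell_file: str | Path | None = None,
    log_base: str = "unknown",
) -> LogExpressionMatrix:
    """Read an expression matrix from disk into genes-by-cells orientation.

    For ``format="mtx"`` the companion row/column id files default to
    ``<stem>.genes.txt`` and ``<stem>.cells.txt`` next to the matrix file
    (named for the on-disk layout's rows and columns respectively being
    genes and cells when ``layout="genes_by_cells"``).
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValidationError(f"format must be one of {_FORMATS}, got {format!r}")
    if layout not in _LAYOUTS:
        raise ValidationError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
    if not path.exists():
        raise ParseError(f"input file not found: {path}")

    if format == "mtx":
        gene_file = Path(gene_file) if gene_file else path.with_suffix(".genes.txt")
        cell_file = Path(cell_file) if cell_file else path.with_suffix(".cells.txt")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError with line info
            raise ParseError(f"malformed MTX file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        row_ids = _read_id_file(gene_file, "gene id")
        col_ids = _read_id_file(cell_file, "cell id")
    else:
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                             float_precision="round_trip")
        except Exception as exc:
            raise ParseError(f"malformed {format.upper()} file {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
        if log_base == "unknown":
            # restore the transform tag written by write_expression_matrix
            log_base = _read_meta(path).get("log_base", "unknown")

    if len(row_ids) != values.shape[0] or len(col_ids) != values.shape[1]:
        raise ParseError(
            f"{path}: id counts ({len(row_ids)} rows, {len(col_ids)} cols) do not "
            f"match matrix shape {values.shape}"
        )
    if layout == "cells_by_genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return LogExpressionMatrix(values, row_ids, col_ids, log_base=log_base)


def log_transform(raw: LogExpressionMatrix, base: str = "natural") -> LogExpressionMatrix:
    """Apply ``x -> log(1 + x)`` entrywise in the chosen base.

    Zeros map to zero, so sparsity structure is preserved. Raw counts must
    be non-negative (enforced by the container).
    """
    if base not in ("natural", "2"):
        raise ValidationError("log base must be 'natural' or '2'")
    vals = np.log1p(raw.values)
    if base == "2":
        vals = vals / math.log(2.0)
    return LogExpressionMatrix(vals, raw.gene_ids, raw.cell_ids, log_base=base)


# ---------------------------------------------------------------------------
# TSV writers/readers with provenance comments

def _write_frame(df: pd.DataFrame, path: Path, header_lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        # %.17g is lossless for float64: write-then-read is the identity
        df.to_csv(fh, sep="\t", index_label="", float_format="%.17g")


def _read_frame(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0, comment="#",
                       float_precision="round_trip")


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
    return meta


def write_expression_matrix(
    X: LogExpressionMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_ids)
    lines = list(header_lines) + [f"log_base = {X.log_base}"]
    _write_frame(df, Path(path), lines)


def write_weight_matrix(
    W: WeightMatrix | TruncatedWeights, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write weights as TSV (gene rows, basis columns) at full float precision."""
    df = pd.DataFrame(W.weights, index=W.gene_ids, columns=W.basis_labels)
    lines = list(header_lines) + [f"log_base = {W.log_base}"]
    if isinstance(W, TruncatedWeights):
        lines.append(f"threshold_w = {W.threshold_w!r}")
    _write_frame(df, Path(path), lines)


def read_weight_matrix(path: str | Path) -> WeightMatrix | TruncatedWeights:
    """Read a weight TSV back; restores a TruncatedWeights if a threshold was stored."""
    df = _read_frame(Path(path))
    meta = _read_meta(Path(path))
    log_base = meta.get("log_base", "unknown")
    gene_ids = [str(i) for i in df.index]
    labels = [str(c) for c in df.columns]
    if "threshold_w" in meta:
        return TruncatedWeights(
            df.to_numpy(np.float64), gene_ids, labels,
            threshold_w=float(meta["threshold_w"]), log_base=log_base,
        )
    return WeightMatrix(df.to_numpy(np.float64), gene_ids, labels, log_base=log_base)


def write_score_matrix(
    S: ScoreMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    df = pd.DataFrame(S.scores, index=S.basis_labels, columns=S.cell_ids)
    _write_frame(df, Path(path), list(header_lines))


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    df = _read_frame(Path(path))
    return ScoreMatrix(
        df.to_numpy(np.float64), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_gene_list(gene_ids: Sequence[str], path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for g in gene_ids:
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    ids = _read_id_file(Path(path), "gene list")
    if len(set(ids)) != len(ids):
        raise ValidationError(f"gene list {path} contains duplicates")
    return ids


def write_mtx(
    X: LogExpressionMatrix, path: str | Path, comment: str = ""
) -> None:
    """Write a matrix as MTX triplets plus companion ``.genes.txt``/``.cells.txt``."""
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(X.values), comment=comment)
    path.with_suffix(".genes.txt").write_text("\n".join(X.gene_ids) + "\n")
    path.with_suffix(".cells.txt").write_text("\n".join(X.cell_ids) + "\n")
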