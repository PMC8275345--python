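"""Synthetic scRNA-seq-like counts with planted, recoverable structure.

The generator emulates the three data features the downstream pipeline
must react to:

* **Cell clusters with marker genes** — cells belong to one of
  ``n_clusters`` groups; each group up-regulates its own disjoint marker
  set by a log fold change, which is what makes some basis scores
  multimodal across cells.
* **Housekeeping-like genes** — a block of genes highly and uniformly
  expressed in every cluster; a basis dominated by them tracks sequencing
  depth rather than identity.
* **Library-size variation** — a per-cell log-normal factor multiplies
  every gene's mean *before* counts are drawn, so the depth confound is
  real and the correlation screen has a true positive to find.

Baseline per-gene means are log-normal across genes; counts are drawn
from a negative binomial (gamma–Poisson, default dispersion 0.2 — the
realistic overdispersed UMI regime) or plain Poisson for sharper oracle
tests. Everything is reproducible from a single integer seed through
numpy's PCG64 generator.

What this generator does *not* emulate: gene–gene correlation beyond the
cluster structure, batch effects, dropout beyond what the count model
implies, and continuous (trajectory-like) population structure.
"""
from __future__ import annotations

import numpy as np

from .containers import LogExpressionMatrix, SimTruth
from .errors import ValidationError
from .io import log_transform

__all__ = ["simulate_counts", "fixture_pipeline", "FIXTURE_PARAMS"]


def simulate_counts(
    n_cells: int = 600,
    n_genes: int = 300,
    n_clusters: int = 3,
    markers_per_cluster: int = 20,
    marker_log_fc: float = 2.0,
    housekeeping_fraction: float = 0.10,
    housekeeping_mean: float = 25.0,
    baseline_log_mean: float = 0.0,
    baseline_log_sd: float = 1.0,
    libsize_sd: float = 0.4,
    noise: str = "nb",
    nb_dispersion: float = 0.2,
    seed: int | None = None,
) -> tuple[LogExpressionMatrix, SimTruth]:
    """Draw a raw count matrix (genes × cells) plus its ground truth.

    Parameters mirror the planted structure: ``marker_log_fc`` is the
    natural-log fold change of a marker in its own cluster,
    ``housekeeping_mean`` the (high) mean of the housekeeping block in
    every cluster, ``libsize_sd`` the standard deviation of the per-cell
    log-normal depth factor. Returns raw counts; apply
    :func:`projnmf.io.log_transform` for the pipeline input.
    """
    if noise not in ("poisson", "nb"):
        raise ValidationError("noise must be 'poisson' or 'nb'")
    if n_cells < n_clusters or n_clusters < 1:
        raise ValidationError("need at least one cell per cluster")
    if marker_log_fc < 0 or libsize_sd < 0 or nb_dispersion <= 0:
        raise ValidationError("rates and spreads must be non-negative (dispersion > 0)")
    n_hk = int(round(housekeeping_fraction * n_genes))
    n_marker = markers_per_cluster * n_clusters
    if n_marker + n_hk > n_genes:
        raise ValidationError(
            f"gene budget infeasible: {n_marker} markers + {n_hk} housekeeping "
            f"> {n_genes} genes"
        )
    rng = np.random.default_rng(seed)

    gene_ids = [f"gene{i + 1}" for i in range(n_genes)]
    cell_ids = [f"cell{j + 1}" for j in range(n_cells)]
    clusters = [f"cluster{c + 1}" for c in range(n_clusters)]

    # gene roles: markers first, then housekeeping, then background
    marker_ids = {
        clusters[c]: gene_ids[c * markers_per_cluster:(c + 1) * markers_per_cluster]
        for c in range(n_clusters)
    }
    hk_ids = gene_ids[n_marker:n_marker + n_hk]

    # cells spread round-robin over clusters -> sizes differ by at most one
    cluster_of_cell = [clusters[j % n_clusters] for j in range(n_cells)]
    cluster_idx = np.array([j % n_clusters for j in range(n_cells)])

    base = rng.lognormal(mean=baseline_log_mean, sigma=baseline_log_sd, size=n_genes)
    mu = np.tile(base[:, None], (1, n_clusters))  # genes × clusters
    for c in range(n_clusters):
        rows = slice(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        mu[rows, c] *= np.exp(marker_log_fc)
    mu[n_marker:n_marker + n_hk, :] = housekeeping_mean

    libfac = rng.lognormal(mean=0.0, sigma=libsize_sd, size=n_cells)
    lam = mu[:, cluster_idx] * libfac[None, :]  # genes × cells

    if noise == "poisson":
        counts = rng.poisson(lam)
    else:
        shape = 1.0 / nb_dispersion
        counts = rng.poisson(rng.gamma(shape, lam / shape))

    X = LogExpressionMatrix(counts.astype(np.float64), gene_ids, cell_ids,
                            log_base="unknown")
    truth = SimTruth(
        cluster_of_cell=cluster_of_cell,
        marker_genes_by_cluster=marker_ids,
        housekeeping_genes=list(hk_ids),
        libsize_factor=libfac,
        seed=-1 if seed is None else int(seed),
    )
    return X, truth


#: the standard small end-to-end fixture: three clusters, one housekeeping
#: block, moderate depth variation
FIXTURE_PARAMS = dict(
    n_cells=600,
    n_genes=300,
    n_clusters=3,
    markers_per_cluster=20,
    marker_log_fc=2.0,
    housekeeping_fraction=0.10,
    libsize_sd=0.4,
    noise="nb",
    nb_dispersion=0.2,
)


def fixture_pipeline(seed: int = 0) -> dict:
    """Generate the standard fixture and the qualitative outcomes it must show.

    Returns a dict with the log1p-transformed matrix (``"X"``), the truth
    (``"truth"``) and a manifest of expected behavior for the full
    pipeline run on this data: at least one basis removed by the
    library-size screen, at least two bases retained as multimodal, and at
    least 90% of the planted markers recovered when the panel size equals
    the number of planted markers.
    """
    raw, truth = simulate_counts(seed=seed, **FIXTURE_PARAMS)
    X = log_transform(raw, base="natural")
    n_markers = sum(len(v) for v in truth.marker_genes_by_cluster.values())
    manifest = {
        "min_bases_removed_by_correlation": 1,
        "min_multimodal_bases": 2,
        "min_marker_recovery": 0.90,
        "panel_size": n_markers,
    }
    return {"X": X, "raw": raw, "truth": truth, "manifest": manifest}
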