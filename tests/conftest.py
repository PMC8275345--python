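"""Shared fixtures: the pinned synthetic data bundle and its pipeline products.

The expensive pieces (PNMF fit, basis selection with bootstrap tests) are
computed once per session and shared; individual tests assert different
facets of the same run.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import projnmf as pj

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: the pinned generator seed for the standard end-to-end fixture
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_bundle():
    """Standard 600-cell, 300-gene, 3-cluster bundle at the pinned seed."""
    return pj.fixture_pipeline(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_fit(fixture_bundle):
    """PNMF fit at K=20 on the standard bundle."""
    X = fixture_bundle["X"]
    W, S, diag = pj.fit_pnmf(X, K=20)
    return {"X": X, "W": W, "S": S, "diag": diag}


@pytest.fixture(scope="session")
def fixture_selection(fixture_bundle, fixture_fit):
    """Basis selection on the standard fit (B=500, seed 3)."""
    W_S, reports = pj.select_bases(
        fixture_fit["W"], fixture_fit["S"], fixture_fit["X"], B=500, seed=3
    )
    return {"W_S": W_S, "reports": reports, "truth": fixture_bundle["truth"]}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_expression(values, gene_ids=None, cell_ids=None, log_base="unknown"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(p)]
    cell_ids = cell_ids or [f"c{j+1}" for j in range(n)]
    return pj.LogExpressionMatrix(values, gene_ids, cell_ids, log_base=log_base)
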