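"""Library-size screen, BH adjustment, top genes, and the combined selection."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import pearsonr

import projnmf as pj
from projnmf.basis_selection import bh_adjust, correlation_screen, top_weight_genes
from projnmf.errors import EmptySelectionError, ValidationError

from conftest import make_expression


def bh_bruteforce(p, fdr):
    """Independent step-up oracle: largest i with p_(i) <= fdr*i/m rejects 1..i."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    cutoff = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= fdr * rank / m:
            cutoff = rank
    if cutoff > 0:
        reject[order[:cutoff]] = True
    # adjusted p: cumulative-min construction from the top
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj, reject


class TestLibrarySizes:
    def test_column_sums(self):
        X = make_expression([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(pj.library_sizes(X).values, [4.0, 6.0])

    def test_all_zero(self):
        X = make_expression(np.zeros((3, 4)))
        np.testing.assert_array_equal(pj.library_sizes(X).values, np.zeros(4))

    def test_single_gene(self):
        X = make_expression([[2.0, 5.0, 1.0]])
        np.testing.assert_array_equal(pj.library_sizes(X).values, [2.0, 5.0, 1.0])


class TestCorrelationScreen:
    def _screen(self, score_rows, lib):
        S = pj.ScoreMatrix(np.asarray(score_rows, float),
                           [f"b{i}" for i in range(len(score_rows))],
                           [f"c{j}" for j in range(len(lib))])
        L = pj.LibrarySizeVector(np.asarray(lib, float), S.cell_ids)
        return correlation_screen(S, L)

    def test_self_correlation_removed(self):
        out = self._screen([[1.0, 2.0, 3.0, 4.0]], [1.0, 2.0, 3.0, 4.0])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert not out.loc[0, "keep"]

    @pytest.mark.parametrize(
        "scores,expect_keep",
        [([1.0, -1.0, 1.0, -1.0], True), ([1.1, 1.9, 3.2, 3.8], False)],
    )
    def test_against_scipy_oracle(self, scores, expect_keep):
        lib = [1.0, 2.0, 3.0, 4.0]
        out = self._screen([scores], lib)
        # negative scores cannot occur in practice but Pearson r is unaffected
        assert out.loc[0, "r"] == pytest.approx(pearsonr(scores, lib).statistic)
        assert out.loc[0, "keep"] == expect_keep

    def test_anticorrelated_basis_also_removed(self):
        lib = [1.0, 2.0, 3.0, 4.0]
        out = self._screen([[4.0, 3.0, 2.0, 1.0]], lib)
        assert out.loc[0, "r"] == pytest.approx(-1.0)
        assert not out.loc[0, "keep"]  # screen uses |r|

    def test_zero_variance_row_degenerate_but_kept(self):
        out = self._screen([[2.0, 2.0, 2.0]], [1.0, 2.0, 3.0])
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "keep"]
        assert out.loc[0, "r"] == 0.0

    @given(
        a=st.floats(0.1, 10.0), b=st.floats(0.0, 5.0),
        c=st.floats(0.1, 10.0), d=st.floats(0.0, 5.0),
    )
    def test_affine_invariance(self, a, b, c, d):
        # positive scale + nonnegative shift keeps both vectors valid
        rng = np.random.default_rng(99)
        s = rng.uniform(0, 5, size=30)
        lib = rng.uniform(1, 10, size=30)
        base = self._screen([s], lib).loc[0, "r"]
        S2 = pj.ScoreMatrix((a * s + b)[None, :], ["b0"],
                            [f"c{j}" for j in range(30)])
        L2 = pj.LibrarySizeVector(c * lib + d, S2.cell_ids)
        again = correlation_screen(S2, L2).loc[0, "r"]
        assert again == pytest.approx(base, abs=1e-9)

    def test_too_few_cells(self):
        with pytest.raises(ValidationError):
            self._screen([[1.0, 2.0]], [1.0, 2.0])


class TestBHAdjust:
    def test_worked_example(self):
        adjusted, reject = bh_adjust([0.001, 0.02, 0.8], fdr=0.01)
        np.testing.assert_array_equal(reject, [True, False, False])

    def test_all_ones_none_rejected(self):
        _, reject = bh_adjust([1.0] * 5, fdr=0.01)
        assert not reject.any()

    def test_all_zero_all_rejected(self):
        _, reject = bh_adjust([0.0] * 5, fdr=0.01)
        assert reject.all()

    def test_empty(self):
        adjusted, reject = bh_adjust([], fdr=0.01)
        assert adjusted.size == 0 and reject.size == 0

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=40)
        adjusted, _ = bh_adjust(p, fdr=0.05)
        assert np.all(adjusted >= p - 1e-15)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = int(rng.integers(1, 25))
            p = np.round(rng.uniform(size=m), 3)  # rounding makes ties common
            fdr = float(rng.choice([0.01, 0.05, 0.1]))
            adj, rej = bh_adjust(p, fdr)
            adj_o, rej_o = bh_bruteforce(p, fdr)
            np.testing.assert_allclose(adj, adj_o, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_o)

    def test_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestTopWeightGenes:
    def _W(self, column):
        col = np.asarray(column, float)[:, None]
        return pj.WeightMatrix(col, [f"gene{i+1}" for i in range(len(col))], ["b1"])

    def test_worked_example(self):
        W = self._W([0.9, 0.1, 0.5, 0.0, 0.2])
        assert top_weight_genes(W, 0, fraction=0.4) == ["gene1", "gene3"]

    def test_fraction_one_sorts_all(self):
        W = self._W([0.2, 0.9, 0.5])
        assert top_weight_genes(W, 0, fraction=1.0) == ["gene2", "gene3", "gene1"]

    def test_ties_broken_by_gene_order(self):
        W = self._W([0.0, 0.0, 0.0, 0.0])
        assert top_weight_genes(W, 0, fraction=0.5) == ["gene1", "gene2"]

    def test_bad_fraction(self):
        with pytest.raises(ValidationError):
            top_weight_genes(self._W([1.0]), 0, fraction=0.0)


class TestSelectBases:
    def test_fixture_selection_semantics(self, fixture_selection):
        reports = fixture_selection["reports"]
        # every input basis appears in exactly one report row
        assert sorted(r.basis_label for r in reports) == sorted(
            f"basis{k+1}" for k in range(20)
        )
        for r in reports:
            assert r.retained == (
                not r.excluded_by_annotation
                and r.retained_by_correlation
                and r.retained_by_multimodality
            )
            assert r.adjusted_pvalue >= r.multimodality_pvalue - 1e-15

    def test_fixture_removes_depth_basis_keeps_cluster_bases(self, fixture_selection):
        reports = fixture_selection["reports"]
        removed_by_corr = [r for r in reports if not r.retained_by_correlation]
        assert len(removed_by_corr) >= 1
        retained = [r for r in reports if r.retained]
        assert len(retained) >= 2
        # the most depth-correlated basis is housekeeping-dominated
        top_corr = max(reports, key=lambda r: abs(r.libsize_correlation))
        hk = set(fixture_selection["truth"].housekeeping_genes)
        overlap = len(hk.intersection(top_corr.top_genes)) / len(top_corr.top_genes)
        assert overlap > 0.5
        assert not top_corr.retained_by_correlation

    def test_selected_weight_columns_preserve_order(self, fixture_selection, fixture_fit):
        W_S = fixture_selection["W_S"]
        retained = [r.basis_label for r in fixture_selection["reports"] if r.retained]
        assert W_S.basis_labels == retained
        full = fixture_fit["W"]
        for label in retained:
            k_full = full.basis_labels.index(label)
            k_sel = W_S.basis_labels.index(label)
            np.testing.assert_array_equal(
                W_S.weights[:, k_sel], full.weights[:, k_full]
            )

    def test_explicit_exclusion(self, fixture_fit):
        W, S, X = fixture_fit["W"], fixture_fit["S"], fixture_fit["X"]
        label = W.basis_labels[1]  # a basis known to be retained at this seed
        W_S, reports = pj.select_bases(W, S, X, exclude_labels=[label], B=60, seed=3)
        row = next(r for r in reports if r.basis_label == label)
        assert row.excluded_by_annotation and not row.retained
        assert label not in W_S.basis_labels

    def test_housekeeping_overlap_exclusion(self, fixture_fit, fixture_bundle):
        W, S, X = fixture_fit["W"], fixture_fit["S"], fixture_fit["X"]
        hk = fixture_bundle["truth"].housekeeping_genes
        _, reports = pj.select_bases(W, S, X, housekeeping_genes=hk, B=60, seed=3)
        assert any(r.excluded_by_annotation for r in reports)

    def test_empty_selection_raises(self, fixture_fit):
        W, S, X = fixture_fit["W"], fixture_fit["S"], fixture_fit["X"]
        with pytest.raises(EmptySelectionError, match="corr_threshold"):
            pj.select_bases(W, S, X, corr_threshold=1e-9, B=40, seed=0)

    def test_unknown_exclude_label_rejected(self, fixture_fit):
        W, S, X = fixture_fit["W"], fixture_fit["S"], fixture_fit["X"]
        with pytest.raises(ValidationError):
            pj.select_bases(W, S, X, exclude_labels=["nope"], B=40, seed=0)
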