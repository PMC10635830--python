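"""Barcode-rank inflection, ambient estimation, Monte-Carlo cell calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import gammaln

from pipflow import (AmbientProfile, BarcodeRankCurve, CountMatrix,
                     FeatureTable, call_cells, empty_drops_pvalues,
                     estimate_ambient, find_inflection)


def matrix_from_rows(rows: np.ndarray, n_genes: int = None) -> CountMatrix:
    n_genes = rows.shape[1] if n_genes is None else n_genes
    features = FeatureTable([{"feature_id": f"g{j}"} for j in range(n_genes)])
    return CountMatrix(sp.csr_matrix(rows),
                       [f"bc{i:05d}" for i in range(rows.shape[0])], features)


class TestFindInflection:
    def test_two_plateau_fixture(self):
        rng = np.random.default_rng(0)
        high = rng.poisson(1000, size=500)
        low = rng.poisson(10, size=5000) + 1
        totals = np.concatenate([high, low]).astype(float)
        curve = BarcodeRankCurve(
            barcodes=[f"b{i}" for i in range(len(totals))],
            totals=np.sort(totals)[::-1])
        thr = find_inflection(curve)
        assert 10 < thr < 1000
        assert (np.sort(high)[::-1] > thr).all()

    def test_unsorted_input_is_sorted_internally(self):
        rng = np.random.default_rng(1)
        totals = np.concatenate([rng.poisson(800, 300) + 1,
                                 rng.poisson(8, 3000) + 1]).astype(float)
        rng.shuffle(totals)
        curve = BarcodeRankCurve(
            barcodes=[f"b{i}" for i in range(len(totals))], totals=totals)
        find_inflection(curve)
        assert (np.diff(curve.totals) <= 0).all()

    def test_flat_curve_uses_fallback(self):
        curve = BarcodeRankCurve(barcodes=[f"b{i}" for i in range(500)],
                                 totals=np.full(500, 50.0))
        with pytest.warns(UserWarning, match="falling back"):
            thr = find_inflection(curve)
        assert curve.fallback_used
        assert thr == 50.0

    def test_too_few_barcodes_rejected(self):
        curve = BarcodeRankCurve(barcodes=["b"] * 50,
                                 totals=np.full(50, 10.0))
        with pytest.raises(ValueError):
            find_inflection(curve)


class TestEstimateAmbient:
    def test_direct_proportions(self):
        rows = np.array([[10, 30], [500, 100]])
        cm = matrix_from_rows(rows)
        amb = estimate_ambient(cm, lower_threshold=40)
        np.testing.assert_allclose(amb.proportions, [0.25, 0.75])
        assert amb.n_ambient_barcodes == 1

    def test_unseen_gene_gets_zero_without_pseudocount(self):
        rows = np.array([[10, 0], [500, 100]])
        amb = estimate_ambient(matrix_from_rows(rows), lower_threshold=40)
        assert amb.proportions[1] == 0.0

    def test_profile_sums_to_one(self):
        rng = np.random.default_rng(2)
        rows = rng.poisson(3, size=(50, 20))
        amb = estimate_ambient(matrix_from_rows(rows), lower_threshold=1000)
        assert abs(amb.proportions.sum() - 1) < 1e-12

    def test_empty_pool_is_an_error(self):
        rows = np.array([[100, 100], [200, 200]])
        with pytest.raises(ValueError):
            estimate_ambient(matrix_from_rows(rows), lower_threshold=5)


def enumerate_pvalue_2gene(counts: tuple[int, int], p: tuple[float, float]
                           ) -> float:
    """Exact p = P(LL(X) <= LL(obs)) by enumeration over all (k, T-k)."""
    T = sum(counts)

    def ll(k):
        with np.errstate(divide="ignore"):
            lp = np.log(p)
        terms = 0.0
        for c, logp in zip((k, T - k), lp):
            if c > 0 and np.isneginf(logp):
                return -np.inf
            terms += c * (logp if c else 0.0)
        return (gammaln(T + 1) - gammaln(k + 1) - gammaln(T - k + 1) + terms)

    obs = ll(counts[0])
    total = 0.0
    for k in range(T + 1):
        if ll(k) <= obs + 1e-12:
            total += np.exp(ll(k)) if np.isfinite(ll(k)) else 0.0
    return total


class TestEmptyDropsPvalues:
    def test_matches_enumeration_oracle(self):
        """Monte-Carlo p agrees with the exhaustive 2-gene oracle within
        3 MC standard errors, over all totals <= 8 under a skewed null."""
        ambient = AmbientProfile(np.array([0.3, 0.7]), ["g0", "g1"], 0.0,
                                 0.0, 1)
        cases = [(a, b) for a, b in itertools.product(range(9), repeat=2)
                 if 0 < a + b <= 8]
        rows = np.array(cases)
        cm = matrix_from_rows(rows)
        n_iter = 100_000
        table = empty_drops_pvalues(cm, ambient, cm.barcodes,
                                    n_iterations=n_iter, seed=0)
        for (a, b), mc_p in zip(cases, table["pvalue"]):
            exact = enumerate_pvalue_2gene((a, b), (0.3, 0.7))
            se = np.sqrt(exact * (1 - exact) / n_iter)
            assert abs(mc_p - exact) <= 3 * se + 1e-4, (a, b)

    def test_estimator_bounds(self):
        ambient = AmbientProfile(np.array([0.5, 0.5]), ["g0", "g1"], 0.0,
                                 0.0, 1)
        cm = matrix_from_rows(np.array([[8, 0], [4, 4]]))
        table = empty_drops_pvalues(cm, ambient, cm.barcodes,
                                    n_iterations=500, seed=1)
        assert ((table["pvalue"] >= 1 / 501)
                & (table["pvalue"] <= 1)).all()

    def test_zero_probability_feature_flagged_minimum_p(self):
        ambient = AmbientProfile(np.array([1.0, 0.0]), ["g0", "g1"], 0.0,
                                 0.0, 1)
        cm = matrix_from_rows(np.array([[5, 3]]))
        table = empty_drops_pvalues(cm, ambient, cm.barcodes,
                                    n_iterations=200, seed=2)
        assert table["zero_ambient_feature"].iloc[0]
        assert table["pvalue"].iloc[0] == pytest.approx(1 / 201)

    def test_ambient_like_barcode_is_unremarkable(self):
        """Counts proportional to the ambient profile sit near the top of
        the null p-value range."""
        ambient = AmbientProfile(np.array([0.5, 0.5]), ["g0", "g1"], 0.0,
                                 0.0, 1)
        cm = matrix_from_rows(np.array([[4, 4], [8, 0]]))
        table = empty_drops_pvalues(cm, ambient, cm.barcodes,
                                    n_iterations=20_000, seed=3)
        balanced, extreme = table["pvalue"].tolist()
        assert balanced > 0.5 > extreme


class TestCallCells:
    def test_bh_computation(self):
        pv = pd.DataFrame({
            "barcode": [f"b{i}" for i in range(100)],
            "total": 100,
            "pvalue": [1e-5] * 5 + [0.9] * 95,
        })
        calls = call_cells(pv, alpha=0.001)
        assert calls.n_cells == 5
        assert (calls.table["p_adjusted"] >= calls.table["pvalue"]).all()

    def test_all_null_pvalues_give_no_cells(self):
        pv = pd.DataFrame({"barcode": ["a", "b"], "total": [5, 6],
                           "pvalue": [1.0, 1.0]})
        assert call_cells(pv, alpha=0.001).n_cells == 0

    def test_force_n_top_totals_with_lexicographic_ties(self):
        totals = pd.Series({"z": 50, "a": 50, "m": 50, "b": 10, "c": 9,
                            **{f"x{i}": 100 for i in range(8)}})
        calls = call_cells(force_n=10, totals=totals)
        assert calls.n_cells == 10
        cells = set(calls.cells)
        assert {f"x{i}" for i in range(8)} <= cells
        # two of the three tied at 50 enter, lexicographically first
        assert {"a", "m"} <= cells and "z" not in cells
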