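"""Downsampling laws, QC metrics, normalization, pseudobulk correlation."""

import numpy as np
import pytest
import scipy.sparse as sp

from pipflow import (CountMatrix, FeatureTable, UmiRecord,
                     downsample_cells_and_reads, downsample_umis,
                     normalize_log, pseudobulk, pseudobulk_correlate,
                     qc_metrics)
from pipflow.quant import collapse_umis


@pytest.fixture()
def small_matrix():
    features = FeatureTable(
        [{"feature_id": "gA", "species": "human"},
         {"feature_id": "gB", "species": "human"},
         {"feature_id": "MT-g", "species": "human", "mito": True}])
    arr = np.array([[2, 0, 1],
                    [5, 5, 0],
                    [0, 0, 0],
                    [100, 250, 50]])
    return CountMatrix(sp.csr_matrix(arr), ["b1", "b2", "b3", "b4"], features)


class TestDownsampleUmis:
    def test_fraction_one_is_identity(self, small_matrix):
        out = downsample_umis(small_matrix, fraction=1.0, seed=0)
        assert (out.matrix != small_matrix.matrix).nnz == 0

    def test_exact_target_totals(self, small_matrix):
        out = downsample_umis(small_matrix, target_per_cell=4, seed=0)
        totals = out.barcode_totals()
        # cells above the target land exactly on it; smaller cells unchanged
        assert totals.tolist() == [3, 4, 0, 4]

    def test_never_increases_any_entry(self, small_matrix):
        out = downsample_umis(small_matrix, fraction=0.3, seed=1)
        assert ((small_matrix.matrix - out.matrix).toarray() >= 0).all()

    def test_deterministic_under_seed(self, small_matrix):
        a = downsample_umis(small_matrix, fraction=0.5, seed=9)
        b = downsample_umis(small_matrix, fraction=0.5, seed=9)
        assert (a.matrix != b.matrix).nnz == 0

    def test_bad_fraction_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            downsample_umis(small_matrix, fraction=0.0)

    def test_expectation_scales_with_fraction(self, small_matrix):
        """Mean of each downsampled entry ~ fraction * entry (within 3 SE
        over 200 replicates; hypergeometric sampling)."""
        frac = 0.4
        reps = np.stack([
            downsample_umis(small_matrix, fraction=frac, seed=s)
            .matrix.toarray() for s in range(200)])
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        target = frac * small_matrix.matrix.toarray()
        # rounding the per-cell target makes tiny cells off by < 1 count
        assert (np.abs(mean - target) <= 3 * se + 0.5).all()


class TestDownsampleCellsAndReads:
    @staticmethod
    def records(rng, n=500):
        return [UmiRecord(f"bc{rng.integers(5)}", f"U{i}",
                          f"G{rng.integers(4)}", int(rng.integers(1, 6)))
                for i in range(n)]

    def test_all_cells_keeps_barcode_set(self):
        rng = np.random.default_rng(0)
        recs = self.records(rng)
        out = downsample_cells_and_reads(recs, n_cells=5, seed=1)
        assert {r.barcode for r in out} == {r.barcode for r in recs}

    def test_too_many_cells_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            downsample_cells_and_reads(self.records(rng), n_cells=99)

    def test_binomial_thinning_within_3_se(self):
        rng = np.random.default_rng(1)
        recs = [UmiRecord("bc", f"U{i}", "G", 10) for i in range(10_000)]
        total = sum(r.multiplicity for r in recs)
        p = 0.3
        out = downsample_cells_and_reads(recs, thinning=p, seed=2)
        kept = sum(r.multiplicity for r in out)
        se = np.sqrt(total * p * (1 - p))
        assert abs(kept - total * p) <= 3 * se

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        recs = self.records(rng)
        a = downsample_cells_and_reads(recs, n_cells=3, thinning=0.5, seed=7)
        b = downsample_cells_and_reads(recs, n_cells=3, thinning=0.5, seed=7)
        assert a == b


class TestQCMetrics:
    def test_direct_computation(self, small_matrix):
        m = qc_metrics(small_matrix)
        row = m.per_barcode.set_index("barcode").loc["b1"]
        assert row["total_umis"] == 3
        assert row["genes_detected"] == 2
        assert row["mito_fraction"] == pytest.approx(1 / 3)

    def test_zero_total_flagged(self, small_matrix):
        m = qc_metrics(small_matrix)
        row = m.per_barcode.set_index("barcode").loc["b3"]
        assert row["total_umis"] == 0 and row["mito_fraction"] == 0
        assert bool(row["zero_total"])

    def test_median_definition(self):
        features = FeatureTable([{"feature_id": "g"}])
        cm = CountMatrix(sp.csr_matrix(np.array([[1], [2], [3]])),
                         ["a", "b", "c"], features)
        assert qc_metrics(cm).median_umis == 2

    def test_saturation_monotonic_in_depth(self):
        """Median genes per cell never decreases with read depth on a
        saturation series (thinning the same read pool to rising targets)."""
        rng = np.random.default_rng(4)
        features = FeatureTable([{"feature_id": f"G{i}"} for i in range(40)])
        recs = [UmiRecord(f"bc{c}", f"U{i}", f"G{rng.integers(40)}", 6)
                for c in range(20) for i in range(150)]
        medians = []
        for depth in (30, 100, 300, 900):
            thinned = downsample_cells_and_reads(recs, reads_per_cell=depth,
                                                 seed=5)
            counts = collapse_umis(thinned)
            cm = CountMatrix.from_counts(counts, features)
            medians.append(qc_metrics(cm).median_genes)
        assert medians == sorted(medians)


class TestNormalizeLog:
    def test_direct_formula(self):
        features = FeatureTable([{"feature_id": "a"}, {"feature_id": "b"}])
        cm = CountMatrix(sp.csr_matrix(np.array([[1, 3]])), ["c"], features)
        out = normalize_log(cm).toarray()
        assert out[0, 0] == pytest.approx(np.log1p(2500))
        assert out[0, 1] == pytest.approx(np.log1p(7500))

    def test_zero_cell_stays_zero(self, small_matrix):
        out = normalize_log(small_matrix)
        assert out.toarray()[2].sum() == 0

    def test_pre_log_values_sum_to_scale(self, small_matrix):
        mat = small_matrix.matrix.toarray().astype(float)
        totals = mat.sum(axis=1, keepdims=True)
        scaled = np.where(totals > 0, mat / np.where(totals > 0, totals, 1)
                          * 1e4, 0)
        assert np.allclose(scaled.sum(axis=1)[totals.ravel() > 0], 1e4)
        # and the module output is exactly log1p of those values
        assert np.allclose(normalize_log(small_matrix).toarray(),
                           np.log1p(scaled))

    def test_monotone_within_cell(self, small_matrix):
        out = normalize_log(small_matrix).toarray()
        raw = small_matrix.matrix.toarray()
        for i in range(raw.shape[0]):
            order = np.argsort(raw[i])
            assert (np.diff(out[i][order]) >= -1e-12).all()


class TestPseudobulk:
    def test_sums_equal_column_sums(self, small_matrix):
        groups = {"b1": "x", "b2": "x", "b3": "y", "b4": "y"}
        pb = pseudobulk(small_matrix, groups)
        np.testing.assert_array_equal(
            pb["x"].to_numpy(),
            np.asarray(small_matrix.subset_barcodes(["b1", "b2"])
                       .matrix.sum(axis=0)).ravel())

    def test_identical_groups_give_r1_slope1(self, small_matrix):
        groups = {"b1": "x", "b2": "x", "b3": "y", "b4": "y"}
        pb = pseudobulk(small_matrix, groups)
        pb["z"] = pb["x"]
        r, slope = pseudobulk_correlate(pb, "x", "z")
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_tpm_scale_invariance(self, small_matrix):
        groups = {"b1": "x", "b2": "x", "b3": "y", "b4": "y"}
        pb = pseudobulk(small_matrix, groups)
        pb["double"] = 2 * pb["x"]
        r, slope = pseudobulk_correlate(pb, "x", "double")
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_constant_vector_is_an_error(self, small_matrix):
        groups = {"b1": "x", "b2": "x", "b3": "y", "b4": "y"}
        pb = pseudobulk(small_matrix, groups)
        pb["const"] = 1
        with pytest.raises(ValueError):
            pseudobulk_correlate(pb, "x", "const")
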