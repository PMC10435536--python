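"""Low-count filtering, collapsing, quantile normalization, TMM, log-CPM."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import osteosig as og
from osteosig.preprocess import FilterParams


def _em(values, scale="counts", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return og.ExpressionMatrix(genes, samples, values, scale)


def _brute_filter(values, params, groups=None):
    """Literal evaluation of the keep rule, independent of the implementation."""
    lib = values.sum(axis=0)
    n_min = values.shape[1] if groups is None else min(
        list(pd.Series(groups).value_counts())
    )
    if n_min > params.large_n:
        n_min = params.large_n + (n_min - params.large_n) * params.min_prop
    cutoff = params.min_count / np.median(lib) * 1e6
    keep = []
    for g in range(values.shape[0]):
        cpm = values[g] / lib * 1e6
        ok_cpm = sum(c >= cutoff - 1e-14 for c in cpm) >= n_min - 1e-14
        ok_tot = values[g].sum() >= params.min_total_count - 1e-14
        keep.append(ok_cpm and ok_tot)
    return np.array(keep)


class TestFilterLowCounts:
    def test_matches_direct_rule_on_planted_matrix(self):
        rng = np.random.default_rng(2)
        values = rng.integers(50, 500, size=(50, 6)).astype(float)
        values[:10] = rng.integers(0, 3, size=(10, 6))  # planted below cutoff
        em = _em(values)
        out = og.filter_low_counts(em)
        expected = _brute_filter(values, FilterParams())
        assert out.n_genes == int(expected.sum()) == 40
        assert out.gene_ids == [g for g, k in zip(em.gene_ids, expected) if k]

    def test_group_sizes_shrink_through_large_n(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 300, size=(80, 12)).astype(float)
        groups = ["A"] * 8 + ["B"] * 4
        out = og.filter_low_counts(_em(values), groups=groups)
        expected = _brute_filter(values, FilterParams(), groups)
        assert out.n_genes == int(expected.sum())

    def test_all_zero_gene_always_removed(self):
        values = np.vstack([np.zeros(4), np.full((5, 4), 100.0)])
        out = og.filter_low_counts(_em(values))
        assert "G0" not in out.gene_ids

    def test_idempotent_and_subset_of_input(self):
        rng = np.random.default_rng(4)
        em = _em(rng.integers(0, 200, size=(60, 8)).astype(float))
        once = og.filter_low_counts(em)
        twice = og.filter_low_counts(once)
        assert set(once.gene_ids) <= set(em.gene_ids)
        assert twice.gene_ids == once.gene_ids
        np.testing.assert_array_equal(twice.values, once.values)

    def test_errors(self):
        with pytest.raises(ValueError, match="counts-scale"):
            og.filter_low_counts(_em(np.ones((3, 3)), scale="tpm"))
        with pytest.raises(ValueError, match="retained 0"):
            og.filter_low_counts(_em(np.ones((3, 3))))


class TestCollapseDuplicates:
    def test_duplicate_rows_averaged(self):
        em = _em([[2, 4], [4, 6]], genes=["GAPDH", "GAPDH"])
        out = og.collapse_duplicate_genes(em)
        assert out.gene_ids == ["GAPDH"]
        np.testing.assert_array_equal(out.values, [[3, 5]])

    def test_unique_symbols_unchanged(self):
        em = _em([[1, 2], [3, 4]], genes=["A", "B"])
        out = og.collapse_duplicate_genes(em)
        np.testing.assert_array_equal(out.values, em.values)
        assert out.gene_ids == ["A", "B"]

    def test_ambiguous_symbols_dropped(self):
        em = _em([[1, 1], [2, 2], [3, 3]], genes=["A", "NA", ""])
        out = og.collapse_duplicate_genes(em)
        assert out.gene_ids == ["A"]


class TestQuantileNormalize:
    def test_three_by_three_toy_rank_mean(self):
        em = _em(np.array([[1, 4, 7], [2, 5, 8], [3, 6, 9]]), scale="tpm")
        out = og.quantile_normalize(em)
        for j in range(3):
            np.testing.assert_allclose(np.sort(out.values[:, j]), [4, 5, 6])

    def test_identical_columns_fixed_point_and_idempotence(self):
        col = np.array([3.0, 1.0, 7.0, 5.0])
        em = _em(np.column_stack([col, col, col]), scale="tpm")
        out = og.quantile_normalize(em)
        np.testing.assert_allclose(out.values, em.values)
        rng = np.random.default_rng(6)
        em2 = _em(rng.random((30, 5)), scale="tpm")
        once = og.quantile_normalize(em2)
        twice = og.quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_columns_share_distribution_and_means(self):
        rng = np.random.default_rng(7)
        out = og.quantile_normalize(_em(rng.random((100, 6)) * 50, scale="tpm"))
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-12)
        assert np.ptp(out.values.mean(axis=0)) < 1e-9

    def test_ties_get_mean_of_reference_values(self):
        # column 1 has a tie at ranks 1-2; reference = mean of sorted columns
        em = _em(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]), scale="tpm")
        out = og.quantile_normalize(em)
        ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])
        tied = (ref[0] + ref[1]) / 2
        np.testing.assert_allclose(out.values[:, 0], [tied, tied, ref[2]])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            og.quantile_normalize(_em(np.ones((3, 1)), scale="tpm"))

    def test_agrees_with_limma_on_tie_free_matrix(self, tmp_path):
        rng = np.random.default_rng(8)
        values = np.abs(rng.normal(10, 3, size=(100, 5)))
        og.quantile_normalize(_em(values, scale="tpm"))
        np.savetxt(tmp_path / "x.tsv", values, delimiter="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(limma)); x <- as.matrix(read.table("{tmp_path}/x.tsv"));'
             f'write.table(normalizeQuantiles(x), "{tmp_path}/q.tsv", sep="\\t", '
             f'col.names=FALSE, row.names=FALSE)'],
            capture_output=True, text=True,
        )
        assert r.returncode == 0, r.stderr
        expected = np.loadtxt(tmp_path / "q.tsv")
        out = og.quantile_normalize(_em(values, scale="tpm"))
        np.testing.assert_allclose(out.values, expected, atol=1e-10)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 51, dtype=float)
        f = og.tmm_factors(_em(np.column_stack([col, col])))
        np.testing.assert_allclose(f.factors.to_numpy(), [1, 1], atol=1e-12)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(9)
        col = rng.integers(1, 500, size=100).astype(float)
        f = og.tmm_factors(_em(np.column_stack([col, 2 * col])))
        np.testing.assert_allclose(f.factors.to_numpy(), [1, 1], atol=1e-9)

    def test_contaminated_sample_factor_below_one(self):
        rng = np.random.default_rng(10)
        values = rng.integers(20, 200, size=(200, 4)).astype(float)
        values[:10, 0] *= 50  # 5% high-count contaminants in sample 1
        f = og.tmm_factors(_em(values))
        assert f.factors.iloc[0] < 1

    def test_gene_order_permutation_invariant(self, rng):
        values = rng.integers(1, 400, size=(80, 5)).astype(float)
        f1 = og.tmm_factors(_em(values))
        perm = rng.permutation(80)
        f2 = og.tmm_factors(_em(values[perm]))
        np.testing.assert_allclose(f1.factors.to_numpy(), f2.factors.to_numpy(), atol=1e-12)

    def test_geometric_mean_one(self, rng):
        values = rng.integers(0, 300, size=(150, 6)).astype(float)
        f = og.tmm_factors(_em(values))
        assert abs(np.exp(np.mean(np.log(f.factors))) - 1) < 1e-9

    def test_zero_total_count_sample_rejected(self):
        values = np.column_stack([np.zeros(5), np.ones(5)])
        with pytest.raises(ValueError, match="zero total"):
            og.tmm_factors(_em(values))

    def test_agrees_with_edger(self, tmp_path):
        rng = np.random.default_rng(11)
        values = rng.negative_binomial(5, 0.02, size=(200, 6)).astype(float)
        values[:20, 0] *= 8
        f = og.tmm_factors(_em(values))
        np.savetxt(tmp_path / "x.tsv", values, delimiter="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR)); x <- as.matrix(read.table("{tmp_path}/x.tsv"));'
             'cat(calcNormFactors(x, method="TMM"), sep="\\n")'],
            capture_output=True, text=True,
        )
        assert r.returncode == 0, r.stderr
        expected = np.array([float(v) for v in r.stdout.split()])
        np.testing.assert_allclose(f.factors.to_numpy(), expected, atol=1e-5)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        values = np.zeros((2, 1))
        values[1, 0] = 1e6 - 1  # library size ~1e6
        em = _em(values)
        out = og.logcpm(em, None, prior=0.5)
        expected = np.log2(0.5 / (1e6 - 1 + 1) * 1e6)
        assert abs(out.values[0, 0] - expected) < 1e-12
        assert abs(out.values[0, 0] + 1.0) < 1e-4

    def test_monotone_in_count(self):
        em = _em(np.array([[10.0], [20.0], [1e6]]))
        out = og.logcpm(em)
        assert out.values[0, 0] < out.values[1, 0] < out.values[2, 0]

    def test_depth_doubling_near_invariance(self, rng):
        # prior distortion scales as prior/(2 * count * ln 2): needs counts
        # well above the prior for near-invariance
        values = rng.integers(500, 5000, size=(500, 3)).astype(float)
        values[0] = 1e6  # push library sizes over 1e6
        a = og.logcpm(_em(values))
        b = og.logcpm(_em(2 * values))
        assert np.max(np.abs(a.values - b.values)) < 1e-3

    def test_negative_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            og.logcpm(_em(np.ones((2, 2))), prior=-0.5)

    def test_scale_tag(self):
        out = og.logcpm(_em(np.ones((3, 2)) * 10))
        assert out.scale == "logcpm"
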