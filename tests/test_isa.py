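"""Seeded consensus ISA: normalization, iteration, seeding, consensus rule."""

import numpy as np
import pytest

import osteosig as og
from osteosig.isa import (
    IsaParams,
    consensus_from_instances,
    isa_consensus,
    isa_iterate,
    isa_normalize,
    make_seeds,
)


def _planted_matrix(rng, n_genes=500, n_samples=150, blocks=None, shift=2.0):
    X = rng.normal(size=(n_genes, n_samples))
    if blocks is None:
        blocks = [
            (range(0, 30), range(0, 40)),
            (range(30, 60), range(40, 80)),
            (range(60, 90), range(80, 110)),
            (range(90, 120), range(110, 150)),
        ]
    for gs, ss in blocks:
        X[np.ix_(list(gs), list(ss))] += shift
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    return X, genes, samples, blocks


def _jaccard(a, b):
    a, b = frozenset(a), frozenset(b)
    return len(a & b) / len(a | b)


class TestNormalize:
    def test_row_means_zero_unit_sd(self, rng):
        X = rng.normal(3, 2, size=(20, 15))
        row_std, col_std = isa_normalize(X)
        assert np.max(np.abs(row_std.mean(axis=1))) < 1e-12
        np.testing.assert_allclose(row_std.std(axis=1), 1.0)
        assert np.max(np.abs(col_std.mean(axis=0))) < 1e-12

    def test_pre_standardized_input_is_fixed_point(self, rng):
        X = rng.normal(size=(10, 8))
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        row_std, _ = isa_normalize(X)
        np.testing.assert_allclose(row_std, X, atol=1e-12)

    def test_hand_matrix_matches_direct_computation(self):
        X = np.array([[1.0, 2, 3, 4], [2, 2, 4, 4], [0, 1, 0, 1], [5, 1, 5, 1]])
        row_std, col_std = isa_normalize(X)
        for i in range(4):
            expected = (X[i] - X[i].mean()) / X[i].std()
            np.testing.assert_allclose(row_std[i], expected, atol=1e-12)
        for j in range(4):
            expected = (X[:, j] - X[:, j].mean()) / X[:, j].std()
            np.testing.assert_allclose(col_std[:, j], expected, atol=1e-12)

    def test_constant_rows_warned_and_too_few_rejected(self, rng):
        X = rng.normal(size=(5, 6))
        X[0] = 7.0
        with pytest.warns(UserWarning, match="constant rows"):
            isa_normalize(X)
        bad = np.ones((3, 4))
        bad[0] = np.arange(4)
        with pytest.raises(ValueError, match="non-constant rows"):
            isa_normalize(bad)


class TestIterate:
    def test_planted_block_recovered_from_inside_seed(self, rng):
        X, genes, samples, blocks = _planted_matrix(rng, blocks=[(range(30), range(40))])
        row_std, col_std = isa_normalize(X)
        bc = isa_iterate(row_std, col_std, genes, samples,
                         gene_seed=[0, 5, 10], params=IsaParams())
        assert bc is not None and bc.converged
        assert _jaccard(bc.gene_set, [f"G{i}" for i in range(30)]) >= 0.9
        # sample membership is the noisier dimension (threshold on 150 z-scores)
        assert _jaccard(bc.sample_set, [f"S{j}" for j in range(40)]) >= 0.7

    def test_pure_noise_mostly_empty_or_nonconverged(self):
        rng = np.random.default_rng(55)
        X = rng.normal(size=(200, 80))
        row_std, col_std = isa_normalize(X)
        outcomes = []
        for _ in range(20):
            seed = rng.choice(200, size=3, replace=False)
            bc = isa_iterate(row_std, col_std,
                             [f"G{i}" for i in range(200)], [f"S{j}" for j in range(80)],
                             gene_seed=seed, params=IsaParams())
            outcomes.append(bc is None or not bc.converged)
        assert np.mean(outcomes) >= 0.8

    def test_converged_bicluster_is_a_fixed_point(self, rng):
        X, genes, samples, _ = _planted_matrix(rng, blocks=[(range(30), range(40))])
        row_std, col_std = isa_normalize(X)
        bc = isa_iterate(row_std, col_std, genes, samples,
                         gene_seed=list(range(0, 30, 3)), params=IsaParams())
        assert bc.converged
        again = isa_iterate(
            row_std, col_std, genes, samples,
            gene_seed=[genes.index(g) for g in bc.gene_set], params=IsaParams(),
        )
        assert again.gene_set == bc.gene_set and again.sample_set == bc.sample_set

    def test_seed_argument_contract(self, rng):
        X, genes, samples, _ = _planted_matrix(rng, n_genes=50, n_samples=30, blocks=[])
        row_std, col_std = isa_normalize(X)
        with pytest.raises(ValueError, match="exactly one"):
            isa_iterate(row_std, col_std, genes, samples)
        with pytest.raises(ValueError, match="empty seed"):
            isa_iterate(row_std, col_std, genes, samples, gene_seed=[])


class TestMakeSeeds:
    def test_ten_gene_plus_seven_sample_clusters_give_17_seeds(self, rng):
        gene_part = np.repeat(np.arange(10), 12)
        sample_part = np.repeat(np.arange(7), 9)
        seeds = make_seeds(gene_part, sample_part, rng=rng)
        assert len(seeds) == 17
        assert sum(kind == "gene" for kind, _ in seeds) == 10
        assert all(len(idx) == 3 for _, idx in seeds)

    def test_small_cluster_clamped_with_warning(self, rng):
        gene_part = np.array([0, 0, 1, 1, 1])
        sample_part = np.array([0, 0, 0])
        with pytest.warns(UserWarning, match="using all"):
            seeds = make_seeds(gene_part, sample_part, seeds_per_cluster=3, rng=rng)
        sizes = {tuple(idx) for kind, idx in seeds if kind == "gene"}
        assert (0, 1) in sizes

    def test_same_rng_seed_identical_seed_lists(self):
        gene_part = np.repeat(np.arange(4), 10)
        sample_part = np.repeat(np.arange(3), 10)
        s1 = make_seeds(gene_part, sample_part, rng=np.random.default_rng(3))
        s2 = make_seeds(gene_part, sample_part, rng=np.random.default_rng(3))
        for (k1, i1), (k2, i2) in zip(s1, s2):
            assert k1 == k2 and np.array_equal(i1, i2)

    def test_empty_partition_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            make_seeds([], [0, 1], rng=rng)


class TestConsensus:
    def test_four_planted_blocks_recovered(self):
        rng = np.random.default_rng(42)
        X, genes, samples, blocks = _planted_matrix(rng)
        result = isa_consensus(X, genes, samples, IsaParams(rng_seed=7))
        assert len(result) == 4
        for bc in result:
            best = max(
                _jaccard(bc.gene_set, [f"G{i}" for i in gs]) for gs, _ in blocks
            )
            assert best >= 0.9
            assert bc.support > 0.75

    def test_subthreshold_block_absent(self):
        rng = np.random.default_rng(43)
        X, genes, samples, _ = _planted_matrix(
            rng, blocks=[(range(30), range(40))], shift=0.2
        )
        result = isa_consensus(X, genes, samples, IsaParams(rng_seed=7))
        planted = [f"G{i}" for i in range(30)]
        assert all(_jaccard(bc.gene_set, planted) < 0.5 for bc in result)

    def test_consensus_threshold_is_strict_majority(self):
        genes = frozenset({"G1", "G2", "G3"})
        samples = frozenset({"S1", "S2"})
        params = IsaParams(n_runs=25)
        at_18 = [(r, genes, samples) for r in range(18)]
        at_19 = [(r, genes, samples) for r in range(19)]
        assert consensus_from_instances(at_18, 25, params) == []
        out = consensus_from_instances(at_19, 25, params)
        assert len(out) == 1 and out[0].gene_set == genes
        assert out[0].support == pytest.approx(19 / 25)

    def test_raising_gene_threshold_never_grows_gene_sets(self):
        rng = np.random.default_rng(44)
        X, genes, samples, _ = _planted_matrix(rng, blocks=[(range(40), range(50))])
        loose = isa_consensus(X, genes, samples, IsaParams(t_gene=2.0, rng_seed=5))
        tight = isa_consensus(X, genes, samples, IsaParams(t_gene=2.5, rng_seed=5))
        assert max((len(b.gene_set) for b in tight), default=0) <= max(
            (len(b.gene_set) for b in loose), default=0
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(45)
        X, genes, samples, _ = _planted_matrix(rng, n_genes=200, n_samples=80,
                                               blocks=[(range(25), range(30))])
        res = isa_consensus(X, genes, samples, IsaParams(rng_seed=11))
        perm_g = rng.permutation(200)
        perm_s = rng.permutation(80)
        res_p = isa_consensus(
            X[np.ix_(perm_g, perm_s)],
            [genes[i] for i in perm_g],
            [samples[j] for j in perm_s],
            IsaParams(rng_seed=11),
        )
        assert {b.gene_set for b in res} == {b.gene_set for b in res_p}
        assert {b.sample_set for b in res} == {b.sample_set for b in res_p}

    def test_identical_seed_byte_identical_output(self):
        rng = np.random.default_rng(46)
        X, genes, samples, _ = _planted_matrix(rng, n_genes=200, n_samples=80,
                                               blocks=[(range(25), range(30))])
        r1 = isa_consensus(X, genes, samples, IsaParams(rng_seed=3))
        r2 = isa_consensus(X, genes, samples, IsaParams(rng_seed=3))
        assert [(b.gene_set, b.sample_set, b.support) for b in r1] == [
            (b.gene_set, b.sample_set, b.support) for b in r2
        ]

    def test_noise_matrix_yields_empty_list(self):
        rng = np.random.default_rng(47)
        X = rng.normal(size=(150, 60))
        result = isa_consensus(X, [f"G{i}" for i in range(150)],
                               [f"S{j}" for j in range(60)], IsaParams(rng_seed=1))
        assert result == []
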