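"""Consensus clustering: oracle equivalence, CDF/delta-area, tree cuts."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

import immusub as im
from immusub.consensus import ConsensusResult, _resample_indices


def two_clouds(n_per=10, sep=100.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, 3))
    b = rng.normal(0, 1, (n_per, 3)) + sep
    return np.vstack([a, b])


def test_consensus_diagonal_is_one_and_symmetric():
    X = two_clouds()
    res = im.consensus_matrix(X, 2, im.ResamplingScheme(20, 0.8, seed=1))
    assert np.allclose(np.diag(res.consensus), 1.0)
    assert np.allclose(res.consensus, res.consensus.T)
    assert res.consensus.min() >= 0 and res.consensus.max() <= 1


def test_perfectly_separated_clouds_give_binary_consensus():
    X = two_clouds(sep=100.0)
    res = im.consensus_matrix(X, 2, im.ResamplingScheme(50, 0.8, seed=2))
    within = res.consensus[:10, :10][np.triu_indices(10, 1)]
    between = res.consensus[:10, 10:]
    assert np.all(within == 1.0)
    assert np.all(between == 0.0)


def test_full_fraction_equals_single_comembership_matrix():
    """With fraction=1 every resample clusters all items identically, so the
    consensus must be exactly the one co-membership indicator matrix."""
    X = two_clouds(n_per=6, sep=10.0, seed=3)
    scheme = im.ResamplingScheme(10, 1.0, seed=4)
    res = im.consensus_matrix(X, 2, scheme)
    lab = fcluster(linkage(X, method="average", metric="euclidean"), 2, "maxclust")
    comember = (lab[:, None] == lab[None, :]).astype(float)
    assert np.array_equal(res.consensus, comember)
    assert set(np.unique(res.consensus)) <= {0.0, 1.0}


def test_small_run_matches_brute_force_average_of_resamples():
    """6 items, B=3: the consensus equals an independently recomputed ratio of
    co-membership to co-draw counts over the same three resamples."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 4))
    scheme = im.ResamplingScheme(3, 1.0, seed=6)
    res = im.consensus_matrix(X, 2, scheme)

    conn = np.zeros((6, 6))
    cnt = np.zeros((6, 6))
    for idx in _resample_indices(6, scheme):
        uniq = np.unique(idx)
        lab = fcluster(
            linkage(X[uniq], method="average", metric="euclidean"), 2, "maxclust"
        )
        same = (lab[:, None] == lab[None, :]).astype(float)
        conn[np.ix_(uniq, uniq)] += same
        cnt[np.ix_(uniq, uniq)] += 1
    expected = np.where(cnt > 0, conn / np.maximum(cnt, 1), 0.0)
    np.fill_diagonal(expected, 1.0)
    assert np.allclose(res.consensus, expected)


def test_sweep_identical_to_per_k_calls():
    X = two_clouds(n_per=8, sep=3.0, seed=7)
    scheme = im.ResamplingScheme(15, 0.8, seed=8)
    sweep = im.consensus_sweep(X, [2, 3, 4], scheme)
    for k in (2, 3, 4):
        single = im.consensus_matrix(X, k, scheme)
        assert np.array_equal(sweep[k].consensus, single.consensus)


def test_co_sample_counts_match_subsampling_expectation():
    n, B, f = 30, 200, 0.8
    X = np.random.default_rng(9).normal(size=(n, 2))
    res = im.consensus_matrix(X, 2, im.ResamplingScheme(B, f, seed=10))
    m = int(np.ceil(f * n))
    p = (m / n) * ((m - 1) / (n - 1))  # P(both items drawn), without replacement
    mean = B * p
    sd = np.sqrt(B * p * (1 - p))
    off = res.co_sample_counts[np.triu_indices(n, 1)]
    assert np.all(np.abs(off - mean) <= 4 * sd + 1)


def test_invalid_k_rejected():
    X = np.zeros((4, 2))
    with pytest.raises(ValueError):
        im.consensus_matrix(X, 1, im.ResamplingScheme(5, 1.0, 0))
    with pytest.raises(ValueError):
        im.consensus_matrix(X, 5, im.ResamplingScheme(5, 1.0, 0))


class TestCDF:
    def make_result(self, values):
        n = values.shape[0]
        return ConsensusResult(
            k=2,
            item_ids=pd.RangeIndex(n),
            consensus=values,
            co_cluster_counts=np.zeros((n, n)),
            co_sample_counts=np.ones((n, n)),
        )

    def test_two_point_distribution_area_is_zero_fraction(self):
        C = np.ones((6, 6))
        C[:3, 3:] = 0.0
        C[3:, :3] = 0.0
        res = self.make_result(C)
        _, area = im.consensus_cdf(res)
        p_zero = (C[np.triu_indices(6, 1)] == 0).mean()
        assert abs(area - p_zero) <= 0.011  # grid resolution

    def test_all_half_gives_area_half(self):
        C = np.full((5, 5), 0.5)
        np.fill_diagonal(C, 1.0)
        _, area = im.consensus_cdf(self.make_result(C))
        assert abs(area - 0.5) <= 0.011

    def test_matches_independent_numeric_integration(self):
        rng = np.random.default_rng(11)
        C = rng.uniform(size=(8, 8))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        res = self.make_result(C)
        grid, area = im.consensus_cdf(res)
        vals = C[np.triu_indices(8, 1)]
        g = np.linspace(0, 1, 101)
        cdf = np.array([(vals <= x).mean() for x in g])
        area_oracle = np.sum((cdf[1:] + cdf[:-1]) / 2 * np.diff(g))
        assert abs(area - area_oracle) < 1e-12


class TestSelectK:
    def fake_results(self, areas):
        out = {}
        for k, a in areas.items():
            r = ConsensusResult(
                k=k,
                item_ids=pd.RangeIndex(3),
                consensus=np.eye(3),
                co_cluster_counts=np.zeros((3, 3)),
                co_sample_counts=np.ones((3, 3)),
            )
            r.area_under_cdf = a
            out[k] = r
        return out

    def test_flat_area_curve_returns_k_min(self):
        sel = im.select_k(self.fake_results({2: 0.4, 3: 0.4, 4: 0.4}))
        assert sel.k == 2

    def test_dominant_jump_selected(self):
        sel = im.select_k(self.fake_results({2: 0.10, 3: 0.11, 4: 0.30, 5: 0.305}))
        assert sel.k == 4

    def test_requires_consecutive_ks(self):
        with pytest.raises(ValueError):
            im.select_k(self.fake_results({2: 0.1, 4: 0.2}))


class TestCutConsensus:
    def block_result(self):
        C = np.zeros((6, 6))
        C[:4, :4] = 1.0
        C[4:, 4:] = 1.0
        return ConsensusResult(
            k=2,
            item_ids=pd.Index([f"i{j}" for j in range(6)]),
            consensus=C,
            co_cluster_counts=np.zeros((6, 6)),
            co_sample_counts=np.ones((6, 6)),
        )

    def test_perfect_blocks_recovered_and_numbered_by_size(self):
        labels = im.cut_consensus(self.block_result(), 2)
        assert list(labels) == [1, 1, 1, 1, 2, 2]  # largest block gets label 1

    def test_labels_invariant_to_item_order(self):
        rng = np.random.default_rng(12)
        X = two_clouds(n_per=7, sep=5.0, seed=13)
        scheme = im.ResamplingScheme(30, 0.8, seed=14)
        res = im.consensus_matrix(X, 2, scheme)
        lab = im.cut_consensus(res, 2)
        perm = rng.permutation(14)
        res_p = im.consensus_matrix(X[perm], 2, scheme)
        lab_p = im.cut_consensus(res_p, 2)
        assert adjusted_rand_score(lab.to_numpy()[perm], lab_p.to_numpy()) == 1.0

    def test_k_above_item_count_rejected(self):
        with pytest.raises(ValueError):
            im.cut_consensus(self.block_result(), 7)


class TestDiscover:
    def test_zero_noise_recovery_is_perfect(self):
        cfg = im.SimulationConfig(
            genes_per_module=6,
            n_noise_genes=0,
            subtype_sizes=(10, 10, 10, 10, 10),
            noise_sd=1e-6,
            seed=15,
        )
        expr, _, truth = im.generate_cohort(cfg, "c1")
        std = im.standardize_genes(expr)
        modules, subtypes, _, _ = im.discover(
            std, 4, 5, im.ResamplingScheme(20, 0.8, seed=16)
        )
        assert adjusted_rand_score(truth.module_of_gene, modules.module_of_gene) == 1.0
        assert (
            adjusted_rand_score(truth.subtype_of_sample, subtypes.subtype_of_sample)
            == 1.0
        )

    def test_deterministic_under_fixed_seed(self, study):
        scheme = im.ResamplingScheme(10, 0.8, seed=17)
        m1, s1, _, _ = im.discover(study.standardized, 4, 5, scheme)
        m2, s2, _, _ = im.discover(study.standardized, 4, 5, scheme)
        assert m1.module_of_gene.equals(m2.module_of_gene)
        assert s1.subtype_of_sample.equals(s2.subtype_of_sample)

    def test_default_study_recovery(self, study):
        mask = study.truth_a.module_of_gene.notna()
        g_ari = adjusted_rand_score(
            study.truth_a.module_of_gene[mask],
            study.modules.module_of_gene[mask],
        )
        s_ari = adjusted_rand_score(
            study.true_subtypes.reindex(study.subtypes.subtype_of_sample.index),
            study.subtypes.subtype_of_sample,
        )
        assert g_ari >= 0.9
        assert s_ari >= 0.8

    def test_noise_degrades_recovery_monotonically(self):
        """Median subtype ARI over seeds does not increase with noise."""
        aris = []
        for sd in (0.3, 1.0, 2.5):
            vals = []
            for seed in range(7):
                cfg = im.SimulationConfig(
                    genes_per_module=8,
                    n_noise_genes=20,
                    subtype_sizes=(12,) * 5,
                    noise_sd=sd,
                    seed=20 + seed,
                )
                expr, _, truth = im.generate_cohort(cfg, "c1")
                std = im.standardize_genes(expr)
                _, subtypes, _, _ = im.discover(
                    std, 4, 5, im.ResamplingScheme(15, 0.8, seed=30 + seed)
                )
                vals.append(
                    adjusted_rand_score(
                        truth.subtype_of_sample, subtypes.subtype_of_sample
                    )
                )
            aris.append(np.median(vals))
        # non-strict degradation; 0.02 covers ARI sampling noise at the floor
        assert aris[0] >= aris[1] - 0.02 and aris[1] >= aris[2] - 0.02
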