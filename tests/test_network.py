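"""Pairwise mixture clustering, cluster Spearman, edge extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.mixture import GaussianMixture

from csgcn.gem import GEM
from csgcn.network import (EdgeCluster, Network, cluster_spearman,
                           extract_network, pairwise_clusters, read_edge_list,
                           similarity_scan, write_edge_list)


def _toy_gem(mat, genes=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i:02d}" for i in range(mat.shape[0])]
    samples = [f"s{j:03d}" for j in range(mat.shape[1])]
    return GEM(values=pd.DataFrame(mat, index=genes, columns=samples))


class TestPairwiseClusters:
    def test_two_separated_clouds_recovered(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(2, 1, 100), r.normal(8, 1, 60)])
            y = np.concatenate([r.normal(2, 1, 100), r.normal(8, 1, 60)])
            truth = np.array([0] * 100 + [1] * 60)
            out = pairwise_clusters(x, y, seed=seed)
            if len(out) != 2:
                continue
            lab = np.full(160, -1)
            for ec in out:
                lab[ec.in_cluster()] = ec.cluster_index
            agree = max((lab == truth).mean(), (lab == 1 - truth).mean())
            hits += agree >= 0.95
        assert hits >= 8

    def test_single_cloud_selects_one_component(self):
        ones = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            x, y = r.normal(5, 1, 150), r.normal(5, 1, 150)
            out = pairwise_clusters(x, y, seed=seed)
            ones += len(out) == 1 and out[0].n_clusters == 1
        assert ones >= 9

    def test_below_min_cluster_yields_no_eligible_cluster(self):
        r = np.random.default_rng(0)
        x, y = r.normal(5, 1, 29), r.normal(5, 1, 29)
        assert pairwise_clusters(x, y) == []

    def test_negative_and_missing_marked_excluded(self):
        r = np.random.default_rng(1)
        x, y = r.normal(5, 1, 100), r.normal(5, 1, 100)
        x[0] = -0.5
        y[1] = np.nan
        out = pairwise_clusters(x, y, seed=0)
        for ec in out:
            assert ec.sample_mask[0] == "9"
            assert ec.sample_mask[1] == "9"
            counts = {c: ec.sample_mask.count(c) for c in "109"}
            assert sum(counts.values()) == 100

    def test_matches_sklearn_mixture_on_separated_clouds(self):
        # independent cross-check of the compiled EM against sklearn
        # clouds kept positive: values < 0 are masked by the expression rule
        r = np.random.default_rng(3)
        x = np.concatenate([r.normal(5, 1, 80), r.normal(12, 1, 80)])
        y = np.concatenate([r.normal(5, 1, 80), r.normal(12, 1, 80)])
        ours = pairwise_clusters(x, y, seed=0)
        gm = GaussianMixture(n_components=2, n_init=5, random_state=0)
        ref = gm.fit_predict(np.column_stack([x, y]))
        assert len(ours) == 2
        lab = np.full(160, -1)
        for ec in ours:
            lab[ec.in_cluster()] = ec.cluster_index
        agree = max((lab == ref).mean(), (lab == 1 - ref).mean())
        assert agree >= 0.98


class TestClusterSpearman:
    def test_monotone_transform_gives_one(self):
        r = np.random.default_rng(0)
        x = r.normal(0, 1, 40)
        assert cluster_spearman(x, np.exp(x), "1" * 40) == pytest.approx(1.0)
        assert cluster_spearman(x, -x, "1" * 40) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        r = np.random.default_rng(5)
        x = np.round(r.normal(0, 1, 30), 1)  # ties
        y = np.round(r.normal(0, 1, 30), 1)
        rho = cluster_spearman(x, y, "1" * 30)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_cluster_dropped(self):
        x = np.ones(30)
        y = np.arange(30.0)
        assert cluster_spearman(x, y, "1" * 30) is None

    def test_mask_too_small_rejected(self):
        with pytest.raises(ValueError):
            cluster_spearman(np.ones(40), np.ones(40), "1" * 10 + "0" * 30)


class TestSimilarityScan:
    def test_visits_every_unordered_pair(self, rng):
        gem = _toy_gem(rng.normal(5, 1, (10, 40)))
        out = similarity_scan(gem, min_cluster=10, seed=0)
        pairs = {(e.gene_a, e.gene_b) for e in out}
        assert len(pairs) == 45

    def test_gene_order_permutation_invariant(self, rng):
        mat = rng.normal(5, 1, (6, 60))
        gem = _toy_gem(mat)
        perm = [3, 0, 5, 1, 4, 2]
        gem_p = _toy_gem(mat[perm], genes=[f"g{i:02d}" for i in perm])
        a = {(e.gene_a, e.gene_b, e.cluster_index): e.rho
             for e in similarity_scan(gem, min_cluster=10, seed=4)}
        b = {(e.gene_a, e.gene_b, e.cluster_index): e.rho
             for e in similarity_scan(gem_p, min_cluster=10, seed=4)}
        assert a == b

    def test_mask_conservation(self, rng):
        gem = _toy_gem(rng.normal(5, 1, (5, 50)))
        for ec in similarity_scan(gem, min_cluster=10, seed=0):
            m = ec.sample_mask
            assert m.count("1") + m.count("0") + m.count("9") == len(m) == 50

    def test_chunked_execution_reassembles_the_full_scan(self, rng):
        gem = _toy_gem(rng.normal(5, 1, (8, 40)))
        full = similarity_scan(gem, min_cluster=10, seed=2)
        parts = []
        for i in range(3):
            parts.extend(similarity_scan(gem, min_cluster=10, seed=2,
                                         chunk=(i, 3)))
        assert {(e.key, e.sample_mask, e.rho) for e in parts} == \
            {(e.key, e.sample_mask, e.rho) for e in full}

    def test_single_global_cluster_matches_plain_spearman(self, rng):
        # forcing one component reduces the scan to the all-sample
        # Spearman network (oracle equivalence)
        mat = rng.normal(5, 1, (6, 80))
        gem = _toy_gem(mat)
        out = similarity_scan(gem, max_components=1, seed=0)
        for ec in out:
            i = int(ec.gene_a[1:])
            j = int(ec.gene_b[1:])
            ref = stats.spearmanr(mat[i], mat[j]).statistic
            assert ec.rho == pytest.approx(ref, abs=1e-12)


class TestExtractNetwork:
    def _ec(self, a, b, rho, idx=0):
        return EdgeCluster(gene_a=a, gene_b=b, cluster_index=idx, n_clusters=1,
                           sample_mask="1" * 30, cluster_size=30, rho=rho)

    def test_strict_inequality_at_tau(self):
        edges = [self._ec("a", "b", 0.8), self._ec("a", "c", 0.800001)]
        net = extract_network(edges, 0.8)
        assert [(e.gene_a, e.gene_b) for e in net.edges] == [("a", "c")]

    def test_empty_input_gives_empty_network(self):
        assert extract_network([], 0.5).edges == []

    def test_triangle_degrees(self):
        edges = [self._ec("a", "b", 0.9), self._ec("a", "c", 0.9),
                 self._ec("b", "c", 0.9)]
        net = extract_network(edges, 0.5)
        assert net.degrees == {"a": 2, "b": 2, "c": 2}

    def test_negative_rho_counts_by_magnitude(self):
        net = extract_network([self._ec("a", "b", -0.95)], 0.9)
        assert len(net.edges) == 1

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Network(edges=[self._ec("a", "b", 0.9), self._ec("a", "b", 0.8)],
                    n_samples=30)


def test_edge_list_round_trip(tmp_path, rng):
    gem = _toy_gem(rng.normal(5, 1, (5, 50)))
    out = similarity_scan(gem, min_cluster=10, seed=0)
    path = tmp_path / "edges.tsv"
    write_edge_list(out, path)
    back = read_edge_list(path)
    assert len(back) == len(out)
    for e1, e2 in zip(out, back):
        assert e1.key == e2.key
        assert e1.sample_mask == e2.sample_mask
        if e1.rho is None:
            assert e2.rho is None
        else:
            assert e2.rho == pytest.approx(e1.rho, abs=1e-10)
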