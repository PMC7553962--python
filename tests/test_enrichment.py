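"""Fisher/Hochberg label enrichment, region sets, anatomical merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csgcn import example_merge_map
from csgcn.enrichment import (EnrichmentRecord, edge_label_enrichment,
                              enrich_edges, fisher_enrichment_p,
                              hochberg_adjust, merge_anatomical,
                              module_label_enrichment, node_expression_stats,
                              select_region_sets, threshold_sweep)
from csgcn.gem import GEM
from csgcn.network import EdgeCluster

import pandas as pd


def _edge(mask, a="gA", b="gB", idx=0):
    return EdgeCluster(gene_a=a, gene_b=b, cluster_index=idx,
                       n_clusters=1, sample_mask=mask,
                       cluster_size=mask.count("1"), rho=0.95)


def _labels(n, region_sizes):
    labels = {}
    i = 0
    for r, size in region_sizes.items():
        for _ in range(size):
            labels[f"s{i:03d}"] = r
            i += 1
    assert i == n
    return labels


def brute_force_fisher_upper_tail(a, b, c, d):
    """Hypergeometric upper tail by direct summation (independent oracle)."""
    N, K, n = a + b + c + d, a + c, a + b
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


class TestFisher:
    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(500):
            a, b, c, d = rng.integers(0, 40, 4)
            if a + b == 0 or a + c == 0:
                continue
            p = fisher_enrichment_p(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(
                brute_force_fisher_upper_tail(int(a), int(b), int(c), int(d)),
                abs=1e-12)

    def test_exact_region_cluster_gives_one_over_binomial(self):
        # cluster == exactly the 30 samples of region r out of 100
        labels = _labels(100, {"r": 30, "other": 70})
        edge = _edge("1" * 30 + "0" * 70)
        recs = edge_label_enrichment(edge, labels, sorted(labels))
        p_r = next(r.p_raw for r in recs if r.label == "r")
        assert p_r == pytest.approx(1 / math.comb(100, 30), rel=1e-9)

    def test_all_samples_cluster_is_uninformative(self):
        labels = _labels(60, {"r": 20, "q": 40})
        recs = edge_label_enrichment(_edge("1" * 60), labels, sorted(labels))
        assert all(r.p_raw == pytest.approx(1.0) for r in recs)

    def test_excluded_samples_leave_the_table(self):
        labels = _labels(50, {"r": 25, "q": 25})
        recs = edge_label_enrichment(_edge("1" * 20 + "9" * 10 + "0" * 20),
                                     labels, sorted(labels))
        for r in recs:
            assert sum(r.table) == 40


class TestHochberg:
    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        recs = [EnrichmentRecord(target="t", label=str(i), table=(1, 1, 1, 1),
                                 p_raw=float(p))
                for i, p in enumerate(rng.uniform(0, 1, 25))]
        hochberg_adjust(recs)
        for r in recs:
            assert r.p_raw <= r.p_adj <= 1.0
        order_raw = np.argsort([r.p_raw for r in recs])
        adj = np.array([r.p_adj for r in recs])
        assert (np.diff(adj[order_raw]) >= -1e-15).all()

    def test_single_test_family_unchanged(self):
        recs = [EnrichmentRecord(target="t", label="l", table=(1, 1, 1, 1),
                                 p_raw=0.037)]
        hochberg_adjust(recs, family="per_target")
        assert recs[0].p_adj == pytest.approx(0.037)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_matches_stepup_definition(self, ps):
        recs = [EnrichmentRecord(target="t", label=str(i),
                                 table=(1, 1, 1, 1), p_raw=p)
                for i, p in enumerate(ps)]
        hochberg_adjust(recs)
        # independent step-up computation
        m = len(ps)
        order = np.argsort(ps)[::-1]  # largest first
        expected = np.empty(m)
        running = np.inf
        for rank, i in enumerate(order):
            running = min(running, (rank + 1) * ps[i])
            expected[i] = min(running, 1.0)
        for r, e in zip(recs, expected):
            assert r.p_adj == pytest.approx(e, abs=1e-12)


class TestModuleEnrichment:
    def test_single_edge_module_equals_edge_record(self):
        labels = _labels(80, {"r": 30, "q": 50})
        edge = _edge("1" * 25 + "0" * 55)
        e_recs = edge_label_enrichment(edge, labels, sorted(labels))
        m_recs = module_label_enrichment([edge], labels, sorted(labels), "M1")
        for er, mr in zip(e_recs, m_recs):
            assert mr.p_raw == pytest.approx(er.p_raw)
            assert mr.table == er.table

    def test_union_covering_all_samples_uninformative(self):
        labels = _labels(40, {"r": 20, "q": 20})
        edges = [_edge("1" * 20 + "0" * 20), _edge("0" * 20 + "1" * 20, idx=1)]
        recs = module_label_enrichment(edges, labels, sorted(labels), "M1")
        assert all(r.p_raw == pytest.approx(1.0) for r in recs)

    def test_union_matches_hypergeometric_oracle(self):
        labels = _labels(100, {"r": 40, "q": 60})
        # two edges with complementary halves of region r
        edges = [_edge("1" * 20 + "0" * 80),
                 _edge("0" * 20 + "1" * 20 + "0" * 60, idx=1)]
        recs = module_label_enrichment(edges, labels, sorted(labels), "M1")
        p_r = next(r.p_raw for r in recs if r.label == "r")
        assert p_r == pytest.approx(
            brute_force_fisher_upper_tail(40, 0, 0, 60), abs=1e-12)

    def test_intersection_mode(self):
        labels = _labels(40, {"r": 20, "q": 20})
        edges = [_edge("1" * 30 + "0" * 10), _edge("1" * 10 + "0" * 30, idx=1)]
        recs = module_label_enrichment(edges, labels, sorted(labels), "M1",
                                       combine="intersection")
        assert recs[0].table[0] + recs[0].table[1] == 10


class TestRegionSets:
    def _records(self):
        labels = _labels(120, {"r1": 40, "r2": 40, "r3": 40})
        edges = [
            _edge("1" * 40 + "0" * 80, a="a", b="b"),          # r1 only
            _edge("0" * 40 + "1" * 40 + "0" * 40, a="a", b="c"),  # r2 only
            _edge("1" * 80 + "0" * 40, a="b", b="c"),          # r1 and r2
            _edge("1" * 8 + "0" * 112, a="c", b="d"),          # weak: none
        ]
        return enrich_edges(edges, labels, sorted(labels)), edges

    def test_unique_and_histogram_bookkeeping(self):
        recs, _ = self._records()
        sets = select_region_sets(recs, edge_alpha=1e-6)
        assert sorted(sets.unique_edges) == ["r1", "r2"]
        assert [k[:2] for k in sets.unique_edges["r1"]] == [("a", "b")]
        assert sets.histogram[0] == 1   # the weak edge
        assert sets.histogram[2] == 1   # the two-region edge
        assert sets.region_count[("c", "d", 0)] == 0
        for lab, keys in sets.region_edges.items():
            assert set(sets.unique_edges.get(lab, [])) <= set(keys)

    def test_boundary_is_strictly_less(self):
        recs = [EnrichmentRecord(target="a|b|0", label="r", table=(1, 0, 0, 1),
                                 p_raw=1e-10, p_adj=1e-10)]
        sets = select_region_sets(recs, edge_alpha=1e-10)
        assert sets.region_edges == {}

    def test_alpha_one_marks_everything(self):
        recs, edges = self._records()
        sets = select_region_sets(recs, edge_alpha=1.0000001)
        assert all(c == 3 for c in sets.region_count.values())

    def test_threshold_sweep_monotone(self):
        recs, _ = self._records()
        df = threshold_sweep(recs, alphas=(1e-3, 1e-10))
        total = df.groupby("alpha")["edges"].sum()
        assert total.loc[1e-10] <= total.loc[1e-3]


class TestMerge:
    def _sets(self):
        recs = TestRegionSets()._records()[0]
        return select_region_sets(recs, edge_alpha=1e-10)

    def test_identity_map_is_identity(self):
        sets = self._sets()
        merged = merge_anatomical(sets, {"r1": "r1", "r2": "r2"},
                                  min_group_edges=1)
        assert merged.region_edges == sets.unique_edges

    def test_disjoint_regions_sum(self):
        sets = self._sets()
        merged = merge_anatomical(sets, {"r1": "g", "r2": "g"},
                                  min_group_edges=1)
        assert len(merged.region_edges["g"]) == 2

    def test_small_groups_flagged(self):
        sets = self._sets()
        merged = merge_anatomical(sets, {"r1": "g1", "r2": "g2"},
                                  min_group_edges=2)
        assert sorted(merged.flagged_small) == ["g1", "g2"]

    def test_uncovered_label_rejected(self):
        with pytest.raises(ValueError, match="merge map"):
            merge_anatomical(self._sets(), {"r1": "g"})

    def test_packaged_example_map_covers_13_regions(self):
        mm = example_merge_map()
        assert len(mm) == 13
        groups = set(mm.values())
        for g in ("basal_ganglia", "cerebellum", "cortex", "hypothalamus",
                  "spinal_cord", "substantia_nigra"):
            assert g in groups
        assert sum(1 for v in mm.values() if v == "basal_ganglia") == 3
        assert sum(1 for v in mm.values() if v == "cortex") == 3


def test_node_expression_stats_hand_case():
    vals = pd.DataFrame([[1.0, 3.0], [5.0, 7.0], [2.0, 2.0]],
                        index=["a", "b", "c"], columns=["s1", "s2"])
    gem = GEM(values=vals)
    mu_s, sd_s, mu_a, sd_a = node_expression_stats(gem, ["a", "b"])
    assert mu_s == pytest.approx(4.0)
    assert sd_s == pytest.approx(np.std([1, 3, 5, 7]))
    assert mu_a == pytest.approx(np.mean(vals.to_numpy()))
    mu_all_set = node_expression_stats(gem, ["a", "b", "c"])
    assert mu_all_set[0] == pytest.approx(mu_all_set[2])
    with pytest.raises(ValueError):
        node_expression_stats(gem, [])


def test_label_shuffled_null_rarely_significant(rng):
    # under label shuffling, almost no edge may reach p_adj < 1e-3
    n = 120
    labels_true = _labels(n, {"r1": 40, "r2": 40, "r3": 40})
    sample_ids = sorted(labels_true)
    edges = []
    for i in range(40):
        mask = np.array(["0"] * n)
        mask[rng.choice(n, 40, replace=False)] = "1"
        edges.append(_edge("".join(mask), a=f"g{i}", b=f"h{i}"))
    hits = 0
    total = 0
    for shuffle in range(50):
        perm = rng.permutation(sample_ids)
        labels = {s: labels_true[p] for s, p in zip(sample_ids, perm)}
        recs = enrich_edges(edges, labels, sample_ids)
        hits += sum(1 for r in recs if r.p_adj < 1e-3)
        total += len(edges)
    assert hits / total <= 0.002
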