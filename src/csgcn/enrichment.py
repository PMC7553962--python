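"""Sample-label enrichment of edges and modules; region set extraction.

Each edge's supporting sample cluster (the '1' characters of its mask)
is tested for over-representation of every region label with a
one-sided Fisher exact test; a Hochberg step-up correction is applied
over the whole edge x label family by default (``family="global"``) or
per edge (``family="per_target"``).  Modules are tested the same way on
the union of their member edges' sample sets.

Region-specific sub-networks come from edges with adjusted p below
``edge_alpha`` (default 1e-10, strict <); edges enriched in exactly one
region are that region's *unique* edges, and anatomical groups merge
the unique edge lists of their member regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gem import GEM
from .network import EdgeCluster

__all__ = ["EnrichmentRecord", "RegionSets", "fisher_enrichment_p",
           "edge_label_enrichment", "module_label_enrichment",
           "enrich_edges", "enrich_modules", "select_region_sets",
           "merge_anatomical", "node_expression_stats", "threshold_sweep"]

EdgeKey = tuple[str, str, int]


@dataclass
class EnrichmentRecord:
    target: str          # edge key string "a|b|cluster" or module id
    label: str
    table: tuple[int, int, int, int]  # a, b, c, d
    p_raw: float
    p_adj: float = float("nan")


@dataclass
class RegionSets:
    region_edges: dict[str, list[EdgeKey]] = field(default_factory=dict)
    region_nodes: dict[str, list[str]] = field(default_factory=dict)
    unique_edges: dict[str, list[EdgeKey]] = field(default_factory=dict)
    unique_nodes: dict[str, list[str]] = field(default_factory=dict)
    region_count: dict[EdgeKey, int] = field(default_factory=dict)
    histogram: dict[int, int] = field(default_factory=dict)
    flagged_small: list[str] = field(default_factory=list)


def edge_key_str(e: EdgeCluster) -> str:
    return f"{e.gene_a}|{e.gene_b}|{e.cluster_index}"


def parse_edge_key(s: str) -> EdgeKey:
    a, b, c = s.split("|")
    return (a, b, int(c))


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Equals the upper hypergeometric tail P(X >= a) with population
    a+b+c+d, a+c labeled successes, and a+b draws.
    """
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def _label_tables(in_mask: np.ndarray, excl_mask: np.ndarray,
                  label_arr: np.ndarray, labels: list[str]
                  ) -> list[tuple[str, tuple[int, int, int, int]]]:
    use = ~excl_mask
    out = []
    for lab in labels:
        has = label_arr == lab
        a = int((in_mask & has & use).sum())
        b = int((in_mask & ~has & use).sum())
        c = int((~in_mask & has & use).sum())
        d = int((~in_mask & ~has & use).sum())
        out.append((lab, (a, b, c, d)))
    return out


def _mask_arrays(mask: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(mask.encode(), dtype=np.uint8)
    return arr == ord("1"), arr == ord("9")


def edge_label_enrichment(edge: EdgeCluster, labels: dict[str, str],
                          sample_ids: list[str]) -> list[EnrichmentRecord]:
    """Raw (unadjusted) Fisher records for one edge against every label."""
    label_arr = np.asarray([labels[s] for s in sample_ids])
    uniq = sorted(set(label_arr))
    in_mask, excl = _mask_arrays(edge.sample_mask)
    recs = []
    for lab, tab in _label_tables(in_mask, excl, label_arr, uniq):
        recs.append(EnrichmentRecord(target=edge_key_str(edge), label=lab,
                                     table=tab, p_raw=fisher_enrichment_p(*tab)))
    return recs


def module_label_enrichment(module_edges: list[EdgeCluster],
                            labels: dict[str, str], sample_ids: list[str],
                            module_id: str, combine: str = "union"
                            ) -> list[EnrichmentRecord]:
    """Fisher records for a module's combined sample set.

    ``combine="union"`` (default) takes the union of member edges' '1'
    samples; ``"intersection"`` the intersection.  Samples excluded
    ('9') in every member edge are left out of the table.
    """
    if not module_edges:
        raise ValueError("module has no edges")
    label_arr = np.asarray([labels[s] for s in sample_ids])
    uniq = sorted(set(label_arr))
    ins, excls = zip(*(_mask_arrays(e.sample_mask) for e in module_edges))
    if combine == "union":
        in_mask = np.logical_or.reduce(ins)
    elif combine == "intersection":
        in_mask = np.logical_and.reduce(ins)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    excl = np.logical_and.reduce(excls) & ~in_mask
    recs = []
    for lab, tab in _label_tables(in_mask, excl, label_arr, uniq):
        recs.append(EnrichmentRecord(target=module_id, label=lab, table=tab,
                                     p_raw=fisher_enrichment_p(*tab)))
    return recs


def hochberg_adjust(records: list[EnrichmentRecord],
                    family: str = "global") -> list[EnrichmentRecord]:
    """Hochberg step-up adjustment, in place, over the chosen family."""
    if not records:
        return records
    if family == "global":
        groups = {None: records}
    elif family == "per_target":
        groups = {}
        for r in records:
            groups.setdefault(r.target, []).append(r)
    else:
        raise ValueError(f"unknown family scope {family!r}")
    for recs in groups.values():
        praw = np.array([r.p_raw for r in recs])
        padj = multipletests(praw, method="simes-hochberg")[1]
        for r, p in zip(recs, padj):
            r.p_adj = float(p)
    return records


def enrich_edges(edges: list[EdgeCluster], labels: dict[str, str],
                 sample_ids: list[str], family: str = "global"
                 ) -> list[EnrichmentRecord]:
    recs: list[EnrichmentRecord] = []
    for e in edges:
        recs.extend(edge_label_enrichment(e, labels, sample_ids))
    return hochberg_adjust(recs, family=family)


def enrich_modules(modules: dict[str, list[EdgeCluster]],
                   labels: dict[str, str], sample_ids: list[str],
                   family: str = "global", combine: str = "union"
                   ) -> list[EnrichmentRecord]:
    recs: list[EnrichmentRecord] = []
    for mid, medges in modules.items():
        recs.extend(module_label_enrichment(medges, labels, sample_ids, mid,
                                            combine=combine))
    return hochberg_adjust(recs, family=family)


def select_region_sets(records: list[EnrichmentRecord],
                       edge_alpha: float = 1e-10) -> RegionSets:
    """Per-region enriched/unique edge lists and the region-count histogram.

    An edge counts for a region iff its adjusted p is strictly below
    ``edge_alpha``; unique edges are enriched in exactly one region.
    """
    out = RegionSets()
    per_edge: dict[EdgeKey, list[str]] = {}
    seen: set[EdgeKey] = set()
    for r in records:
        key = parse_edge_key(r.target)
        seen.add(key)
        if r.p_adj < edge_alpha:
            per_edge.setdefault(key, []).append(r.label)
    for key in seen:
        regions = per_edge.get(key, [])
        out.region_count[key] = len(regions)
        out.histogram[len(regions)] = out.histogram.get(len(regions), 0) + 1
        for lab in regions:
            out.region_edges.setdefault(lab, []).append(key)
            if len(regions) == 1:
                out.unique_edges.setdefault(lab, []).append(key)
    for d_edges, d_nodes in ((out.region_edges, out.region_nodes),
                             (out.unique_edges, out.unique_nodes)):
        for lab, keys in d_edges.items():
            keys.sort()
            d_nodes[lab] = sorted({g for k in keys for g in k[:2]})
    return out


def merge_anatomical(region_sets: RegionSets, merge_map: dict[str, str],
                     basis: str = "unique", min_group_edges: int = 3
                     ) -> RegionSets:
    """Merge per-region edge lists into anatomical groups.

    ``basis`` selects whether the groups union the regions' unique edge
    lists (default: the mini-network construction) or all
    enriched edges.  Groups with fewer than ``min_group_edges`` edges
    are flagged (too small to form a sub-network) but still returned.
    """
    src = region_sets.unique_edges if basis == "unique" else region_sets.region_edges
    present = set(src)
    uncovered = present.difference(merge_map)
    if uncovered:
        raise ValueError(f"merge map does not cover label(s) {sorted(uncovered)}")
    merged = RegionSets(region_count=dict(region_sets.region_count),
                        histogram=dict(region_sets.histogram))
    for lab, keys in src.items():
        group = merge_map[lab]
        merged.region_edges.setdefault(group, [])
        merged.region_edges[group] = sorted(set(merged.region_edges[group]) | set(keys))
    for group, keys in merged.region_edges.items():
        merged.region_nodes[group] = sorted({g for k in keys for g in k[:2]})
        if len(keys) < min_group_edges:
            merged.flagged_small.append(group)
    merged.flagged_small.sort()
    return merged


def node_expression_stats(gem: GEM, node_set: list[str]
                          ) -> tuple[float, float, float, float]:
    """(mean, sd) of log2 expression over the node subset and over all genes."""
    if not node_set:
        raise ValueError("empty node set")
    missing = set(node_set) - set(gem.gene_ids)
    if missing:
        raise ValueError(f"node(s) not in GEM: {sorted(missing)[:3]}")
    all_vals = gem.matrix()
    sub = gem.values.loc[list(node_set)].to_numpy(dtype=float)
    return (float(np.nanmean(sub)), float(np.nanstd(sub)),
            float(np.nanmean(all_vals)), float(np.nanstd(all_vals)))


def threshold_sweep(records: list[EnrichmentRecord],
                    alphas: tuple[float, ...] = (1e-3, 1e-5, 1e-10, 1e-15, 1e-20)
                    ) -> pd.DataFrame:
    """Edges and nodes per region at a sweep of significance cutoffs."""
    rows = []
    for alpha in alphas:
        sets = select_region_sets(records, edge_alpha=alpha)
        for lab, keys in sorted(sets.region_edges.items()):
            rows.append({"alpha": alpha, "region": lab, "edges": len(keys),
                         "nodes": len(sets.region_nodes[lab])})
    return pd.DataFrame(rows, columns=["alpha", "region", "edges", "nodes"])
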