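"""Condition-specific co-expression network construction.

For every unordered gene pair the sample scatter (x, y) is deconvolved
with a 2-D Gaussian mixture (BIC-selected component count); each
mixture cluster with at least ``min_cluster`` samples gets a Spearman
correlation computed over its members only.  A cluster therefore
captures a *condition-specific* correlation — e.g. one supported only
by the samples of a single brain region — that an all-sample
correlation would dilute.

Sample masks use one character per sample: '1' in the cluster, '0' in
another cluster, '9' excluded (missing, or a normalized log2 value
below 0 in either gene).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._gmm import fit_best_gmm
from .gem import GEM

__all__ = ["EdgeCluster", "Network", "pairwise_clusters", "cluster_spearman",
           "similarity_scan", "extract_network", "read_edge_list",
           "write_edge_list"]

MIN_CLUSTER = 30  # smallest sample cluster that gets a correlation


@dataclass
class EdgeCluster:
    """One gene pair's sample cluster: the atomic network record."""

    gene_a: str
    gene_b: str
    cluster_index: int
    n_clusters: int
    sample_mask: str          # over {'1','0','9'}, length n_samples
    cluster_size: int
    rho: float | None = None  # Spearman over the '1' samples, None if ineligible

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("edge endpoints must satisfy gene_a < gene_b")
        if self.sample_mask.count("1") != self.cluster_size:
            raise ValueError("cluster_size inconsistent with sample_mask")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.gene_a, self.gene_b, self.cluster_index)

    def in_cluster(self) -> np.ndarray:
        return np.frombuffer(self.sample_mask.encode(), dtype=np.uint8) == ord("1")


@dataclass
class Network:
    """Thresholded edge list with node degrees."""

    edges: list[EdgeCluster]
    n_samples: int
    tau: float | None = None
    degrees: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (gene_a, gene_b, cluster_index) edge keys")
        deg: dict[str, int] = {}
        for e in self.edges:
            deg[e.gene_a] = deg.get(e.gene_a, 0) + 1
            deg[e.gene_b] = deg.get(e.gene_b, 0) + 1
        self.degrees = deg

    @property
    def nodes(self) -> list[str]:
        return sorted(self.degrees)


def _pair_seed(base_seed: int, gene_a: str, gene_b: str) -> int:
    # stable under gene-order permutation: derived from the canonical pair key
    return zlib.crc32(f"{base_seed}:{gene_a}|{gene_b}".encode()) & 0x7FFFFFFF


def pairwise_clusters(x: np.ndarray, y: np.ndarray, *,
                      gene_a: str = "a", gene_b: str = "b",
                      min_cluster: int = MIN_CLUSTER, max_components: int = 5,
                      restarts: int = 2, max_iter: int = 150, tol: float = 1e-6,
                      seed: int = 0) -> list[EdgeCluster]:
    """Mixture-deconvolve one gene pair's sample scatter.

    Samples where either value is missing or below 0 are marked '9' and
    excluded before clustering.  Returns one EdgeCluster per mixture
    component; only clusters with >= ``min_cluster`` members are
    eligible for a correlation downstream (``rho`` is left unset here).
    Fewer than ``min_cluster`` usable samples yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned to the same samples")
    usable = np.isfinite(x) & np.isfinite(y) & (x >= 0) & (y >= 0)
    n = x.size
    if int(usable.sum()) < min_cluster:
        return []
    pts = np.column_stack([x[usable], y[usable]])
    labels, k, _bic = fit_best_gmm(pts, max_components, restarts, max_iter,
                                   tol, 1e-6, seed)
    out: list[EdgeCluster] = []
    full = np.full(n, -1, dtype=int)
    full[usable] = labels
    for c in range(k):
        mask = np.where(full == c, "1", np.where(full == -1, "9", "0"))
        out.append(EdgeCluster(
            gene_a=gene_a, gene_b=gene_b, cluster_index=c, n_clusters=k,
            sample_mask="".join(mask), cluster_size=int((full == c).sum())))
    return out


def cluster_spearman(x: np.ndarray, y: np.ndarray, mask: str,
                     min_cluster: int = MIN_CLUSTER) -> float | None:
    """Spearman rho over the mask's '1' samples (average-rank ties).

    Returns None when either vector has zero rank variance (rho
    undefined; the cluster is dropped downstream).
    """
    sel = np.frombuffer(mask.encode(), dtype=np.uint8) == ord("1")
    if int(sel.sum()) < min_cluster:
        raise ValueError(f"mask selects fewer than {min_cluster} samples")
    xs, ys = np.asarray(x, float)[sel], np.asarray(y, float)[sel]
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        return None
    rho = stats.spearmanr(xs, ys).statistic
    return None if np.isnan(rho) else float(rho)


def similarity_scan(gem: GEM, *, min_cluster: int = MIN_CLUSTER,
                    max_components: int = 5, restarts: int = 2,
                    seed: int = 0, genes: list[str] | None = None,
                    chunk: tuple[int, int] | None = None
                    ) -> list[EdgeCluster]:
    """Run mixture clustering + Spearman over every unordered gene pair.

    Deterministic given seed (per-pair seeds derive from the canonical
    gene-pair key, so the edge set is invariant to gene order).
    ``chunk=(i, n_chunks)`` restricts to the i-th of n contiguous pair
    blocks for resumable execution.
    """
    names = genes if genes is not None else gem.gene_ids
    mat = gem.values.loc[names].to_numpy(dtype=float)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    if chunk is not None:
        ci, nc = chunk
        size = -(-len(pairs) // nc)
        pairs = pairs[ci * size:(ci + 1) * size]
    out: list[EdgeCluster] = []
    for i, j in pairs:
        a, b = names[i], names[j]
        if a > b:
            a, b = b, a
            xi, yi = mat[j], mat[i]
        else:
            xi, yi = mat[i], mat[j]
        try:
            clusters = pairwise_clusters(
                xi, yi, gene_a=a, gene_b=b, min_cluster=min_cluster,
                max_components=max_components, restarts=restarts,
                seed=_pair_seed(seed, a, b))
        except Exception:
            continue  # per-pair failures are skipped, not fatal
        for ec in clusters:
            if ec.cluster_size >= min_cluster:
                rho = cluster_spearman(xi, yi, ec.sample_mask,
                                       min_cluster=min_cluster)
                if rho is not None:
                    ec = replace(ec, rho=rho)
            out.append(ec)
    return out


def extract_network(edge_clusters: list[EdgeCluster], tau: float,
                    n_samples: int | None = None) -> Network:
    """Keep clusters with |rho| strictly greater than tau as edges."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    edges = [e for e in edge_clusters if e.rho is not None and abs(e.rho) > tau]
    if n_samples is None:
        n_samples = len(edge_clusters[0].sample_mask) if edge_clusters else 0
    return Network(edges=edges, n_samples=n_samples, tau=tau)


# -- edge-list TSV exchange format --------------------------------------

_COLS = ["gene_a", "gene_b", "rho", "cluster_index", "n_clusters",
         "cluster_size", "sample_mask"]


def write_edge_list(edge_clusters: list[EdgeCluster], path: str | Path) -> None:
    rows = [(e.gene_a, e.gene_b,
             "" if e.rho is None else f"{e.rho:.12g}",
             e.cluster_index, e.n_clusters, e.cluster_size, e.sample_mask)
            for e in edge_clusters]
    pd.DataFrame(rows, columns=_COLS).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[EdgeCluster]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_mask": str})
    out = []
    for r in df.itertuples(index=False):
        rho = None if pd.isna(r.rho) else float(r.rho)
        out.append(EdgeCluster(
            gene_a=str(r.gene_a), gene_b=str(r.gene_b), rho=rho,
            cluster_index=int(r.cluster_index), n_clusters=int(r.n_clusters),
            cluster_size=int(r.cluster_size), sample_mask=str(r.sample_mask)))
    return out
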