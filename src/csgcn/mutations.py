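"""Tumor-mutation count statistics and empirical enrichment for gene sets.

For a gene set and tumor type, three statistics are summed over the
cohort: the number of set genes mutated in at least one tumor, the
number of tumors with at least one mutation in the set, and the total
mutation count in the set.  Each observed statistic is compared with
100 size-controlled random gene sets (length-matched, same matcher as
the classifier nulls); the empirical p-value uses the add-one form
(1 + #{random >= observed}) / (n_rand + 1), with the plain r/n form
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import RandomSetSpec, random_size_controlled_sets

__all__ = ["MutationEnrichmentResult", "read_mutations", "count_stats",
           "empirical_enrichment"]

REQUIRED_COLUMNS = ("tumor_id", "tumor_type", "gene")
STAT_NAMES = ("mutated_genes", "mutated_tumors", "total_mutations")


@dataclass
class MutationEnrichmentResult:
    gene_set: list[str]
    tumor_type: str
    observed: dict[str, int]
    random_means: dict[str, float]
    p_value: dict[str, float]        # add-one empirical p, drives the flag
    p_value_plain: dict[str, float]  # r / n form
    significant: dict[str, bool] = field(default_factory=dict)
    n_randomizations: int = 100
    alpha: float = 0.01


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a simplified MAF TSV; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mutation table is missing column {col!r}")
    df = df[list(REQUIRED_COLUMNS)].dropna()
    return df.reset_index(drop=True)


def count_stats(mutations: pd.DataFrame, gene_set: list[str],
                tumor_type: str) -> tuple[int, int, int]:
    """(mutated_genes, mutated_tumors, total_mutations) for one cohort."""
    if not gene_set:
        raise ValueError("empty gene set")
    if tumor_type not in set(mutations["tumor_type"]):
        raise ValueError(f"unknown tumor type {tumor_type!r}")
    sub = mutations[(mutations["tumor_type"] == tumor_type)
                    & mutations["gene"].isin(set(gene_set))]
    return (int(sub["gene"].nunique()), int(sub["tumor_id"].nunique()),
            int(len(sub)))


def _gene_index(sub: pd.DataFrame) -> dict[str, tuple[set[str], int]]:
    """gene -> (tumor ids carrying it, total row count) for one cohort."""
    idx: dict[str, tuple[set[str], int]] = {}
    for tid, g in zip(sub["tumor_id"].to_numpy(), sub["gene"].to_numpy()):
        if g in idx:
            idx[g][0].add(tid)
            idx[g] = (idx[g][0], idx[g][1] + 1)
        else:
            idx[g] = ({tid}, 1)
    return idx


def _stat_vector(idx: dict[str, tuple[set[str], int]],
                 gene_set: list[str]) -> np.ndarray:
    tumors: set[str] = set()
    n_genes = 0
    total = 0
    for g in gene_set:
        hit = idx.get(g)
        if hit is not None:
            n_genes += 1
            tumors |= hit[0]
            total += hit[1]
    return np.array([n_genes, len(tumors), total], dtype=float)


def empirical_enrichment(mutations: pd.DataFrame, gene_set: list[str],
                         tumor_type: str, universe: list[str],
                         gene_lengths: dict[str, int], n_rand: int = 100,
                         seed: int = 0, alpha: float = 0.01,
                         size_tolerance: float = 0.10
                         ) -> MutationEnrichmentResult:
    """Empirical mutation enrichment of a gene set vs size-matched nulls."""
    obs = count_stats(mutations, gene_set, tumor_type)
    sub = mutations[mutations["tumor_type"] == tumor_type]
    # per-tumor-type seed offset keeps draws reproducible per cohort
    type_seed = (seed * 104729 + hash(tumor_type) % 10007) % (2 ** 31)
    rand_sets = random_size_controlled_sets(
        gene_set, universe, gene_lengths,
        spec=RandomSetSpec(n_sets=n_rand, size_tolerance=size_tolerance),
        seed=type_seed)
    idx = _gene_index(sub)
    rand = np.vstack([_stat_vector(idx, rs) for rs in rand_sets])
    obs_v = np.asarray(obs, dtype=float)
    ge = (rand >= obs_v[None, :]).sum(axis=0)
    p_add1 = (1.0 + ge) / (n_rand + 1.0)
    p_plain = ge / n_rand
    return MutationEnrichmentResult(
        gene_set=list(gene_set), tumor_type=tumor_type,
        observed=dict(zip(STAT_NAMES, map(int, obs))),
        random_means=dict(zip(STAT_NAMES, rand.mean(axis=0).tolist())),
        p_value=dict(zip(STAT_NAMES, p_add1.tolist())),
        p_value_plain=dict(zip(STAT_NAMES, p_plain.tolist())),
        significant={k: bool(v < alpha)
                     for k, v in zip(STAT_NAMES, p_add1.tolist())},
        n_randomizations=n_rand, alpha=alpha)
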