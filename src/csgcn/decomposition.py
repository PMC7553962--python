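"""Phase-II combinatorial decomposition of a significant gene set.

The set is decomposed by iterating over subset sizes k = 1..n-1: all
C(n, k) subsets are scored for k up to ``exhaustive_max`` (default 3),
after which each of the best ``beam_width`` subsets of the previous
iteration is extended by every absent gene (beam search).  Each subset
is scored by cross-validated classification accuracy.  A gene's
per-iteration frequency is the fraction of counted subsets containing
it — over *all* subsets while exhaustive (hence uniform early rows),
over the retained top-B subsets afterwards.  Candidates are the genes
whose aggregate frequency is at least one-half standard deviation
above the mean aggregate frequency (sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .gem import GEM
from .screening import (RandomSetSpec, ScreenReport, _features,
                        _make_classifier, random_size_controlled_sets,
                        rf_classify, train_eval)

__all__ = ["DecompositionResult", "phase2_combinatorial", "candidate_rule",
           "rf_candidates", "validate_decomposition"]


@dataclass
class DecompositionResult:
    gene_set: list[str]
    frequency: pd.DataFrame          # iterations (subset size) x genes, in [0,1]
    aggregate: pd.Series
    threshold: float
    candidates: list[str]
    non_candidates: list[str]
    beam_width: int
    exhaustive_max: int
    best_subsets: dict[int, list[tuple[float, tuple[str, ...]]]] = field(
        default_factory=dict)


def candidate_rule(aggregate: pd.Series) -> tuple[float, list[str], list[str]]:
    """mean + 0.5 * sample SD split of aggregate frequencies."""
    thr = float(aggregate.mean() + 0.5 * aggregate.std(ddof=1))
    cand = sorted(aggregate.index[aggregate >= thr])
    non = sorted(aggregate.index[aggregate < thr])
    return thr, cand, non


def _score_subset(X: np.ndarray, y: np.ndarray,
                  fold_idx: list[tuple[np.ndarray, np.ndarray]],
                  cols: list[int], scorer: str, rf_trees: int,
                  seed: int) -> float:
    Xs = X[:, cols]
    accs = []
    for tr, te in fold_idx:
        if scorer == "tree":
            clf = DecisionTreeClassifier(min_impurity_decrease=1e-7,
                                         random_state=seed)
        elif scorer == "rf":
            clf = RandomForestClassifier(n_estimators=rf_trees,
                                         min_impurity_decrease=1e-7,
                                         random_state=seed)
        else:
            clf = _make_classifier(scorer, len(cols), seed)
        clf.fit(Xs[tr], y[tr])
        accs.append(float(np.mean(clf.predict(Xs[te]) == y[te])))
    return float(np.mean(accs))


def phase2_combinatorial(gem: GEM, labels: dict[str, str],
                         gene_set: list[str], exhaustive_max: int = 3,
                         beam_width: int = 32, seed: int = 0,
                         scorer: str = "tree", scorer_folds: int = 3,
                         rf_trees: int = 30) -> DecompositionResult:
    """Beam-search decomposition into candidate vs non-candidate genes."""
    n = len(gene_set)
    if n < 4:
        raise ValueError("gene set must have >= 4 genes")
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    genes = list(gene_set)
    X = _features(gem, genes)
    y = np.asarray([labels[s] for s in gem.sample_ids])
    skf = StratifiedKFold(n_splits=scorer_folds, shuffle=True,
                          random_state=seed)
    fold_idx = [(tr, te) for tr, te in skf.split(X, y)]
    all_idx = tuple(range(n))

    freq_rows: list[np.ndarray] = []
    retained: list[tuple[int, ...]] = []
    best_subsets: dict[int, list[tuple[float, tuple[str, ...]]]] = {}
    for k in range(1, n):
        if k <= exhaustive_max:
            cands = list(combinations(all_idx, k))
            counted = cands
        else:
            seen: set[tuple[int, ...]] = set()
            for sub in retained:
                present = set(sub)
                for g in all_idx:
                    if g not in present:
                        seen.add(tuple(sorted(sub + (g,))))
            cands = sorted(seen)
            counted = None  # counted over the retained top-B below
        scored = [(_score_subset(X, y, fold_idx, list(c), scorer, rf_trees,
                                 seed * 100003 + k * 1009 + i), c)
                  for i, c in enumerate(cands)]
        # ties broken lexicographically for determinism
        scored.sort(key=lambda t: (-t[0], t[1]))
        retained = [c for _, c in scored[:beam_width]]
        best_subsets[k] = [(s, tuple(genes[i] for i in c))
                           for s, c in scored[:beam_width]]
        pool = counted if counted is not None else retained
        counts = np.zeros(n)
        for c in pool:
            counts[list(c)] += 1
        freq_rows.append(counts / len(pool))

    freq = pd.DataFrame(freq_rows, index=range(1, n), columns=genes)
    aggregate = freq.sum(axis=0)
    thr, cand, non = candidate_rule(aggregate)
    return DecompositionResult(gene_set=genes, frequency=freq,
                               aggregate=aggregate, threshold=thr,
                               candidates=cand, non_candidates=non,
                               beam_width=beam_width,
                               exhaustive_max=exhaustive_max,
                               best_subsets=best_subsets)


def rf_candidates(importances: dict[str, float], k: int) -> list[str]:
    """Top-k genes by Random-Forest importance (ties by name)."""
    if k > len(importances):
        raise ValueError("k exceeds the gene set size")
    order = sorted(importances.items(), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in order[:k]]


def validate_decomposition(gem: GEM, labels: dict[str, str],
                           candidates: list[str], non_candidates: list[str],
                           spec: RandomSetSpec | None = None, seed: int = 0,
                           folds: int = 10, classifier: str = "rf"
                           ) -> dict[str, ScreenReport]:
    """Accuracy-vs-random comparison of full / candidate / non-candidate sets."""
    if set(candidates) & set(non_candidates):
        raise ValueError("candidate and non-candidate sets overlap")
    spec = spec or RandomSetSpec()
    if gem.gene_lengths is None:
        raise ValueError("GEM carries no gene lengths")
    sets = {"full": sorted(set(candidates) | set(non_candidates)),
            "candidates": list(candidates)}
    if non_candidates:
        sets["non_candidates"] = list(non_candidates)
    out: dict[str, ScreenReport] = {}
    for i, (name, genes) in enumerate(sets.items()):
        rep = train_eval(gem, labels, genes, folds=folds, seed=seed,
                         classifier=classifier, name=name)
        rand_sets = random_size_controlled_sets(
            genes, gem.gene_ids, gem.gene_lengths, spec=spec,
            seed=seed * 131 + i)
        for ri, rs in enumerate(rand_sets):
            r = train_eval(gem, labels, rs, folds=folds,
                           seed=seed * 131 + i * 1000 + ri,
                           classifier=classifier, name=f"{name}_rand{ri}")
            rep.random_means.append(r.mean_accuracy)
        rep.random_mean = float(np.mean(rep.random_means))
        out[name] = rep
    return out
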