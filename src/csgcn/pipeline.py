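"""Config-driven end-to-end orchestration.

Runs the stages simulate -> preprocess -> network -> communities &
enrichment -> embedding -> screen -> decompose -> mutations on a YAML
config, writing every artifact plus a manifest (file hashes, params,
seeds) under the output directory.  Reruns with the same config
reproduce all deterministic outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import communities, decomposition, embedding, enrichment, mutations
from . import network as net
from . import preprocess as prep
from . import rmt, screening, simulate
from .gem import write_gem, write_gene_lengths, write_labels

log = logging.getLogger("csgcn.pipeline")

STAGES = ["simulate", "preprocess", "network", "enrich", "embed",
          "screen", "decompose", "mutations"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # stage parameter blocks (defaults mirror the module defaults)
    sim: dict = field(default_factory=dict)
    ks_threshold: float = 0.15
    min_cluster: int = 30
    max_components: int = 5
    tau_override: float | None = None
    edge_alpha: float = 1e-10
    module_alpha: float = 1e-3
    module_min_edges: int = 3
    perplexity: float = 30
    pca_dims: int = 50
    n_random: int = 50
    size_tolerance: float = 0.10
    screen_classifier: str = "mlp"
    screen_folds: int = 10
    beam_width: int = 32
    exhaustive_max: int = 3
    decompose_set_size: int = 10
    n_rand_mutation: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        for f in out.iterdir():
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = _sha256(f)

    sim_kwargs = dict(config.sim)
    cfg = simulate.default_config(seed=config.seed, **sim_kwargs)
    gem = labels = truth = None
    edge_clusters = None
    network = None
    region_sets = merged = None

    for stage in config.stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            gem, labels, lengths, truth = simulate.simulate_gem(cfg)
            write_gem(gem, out / "gem_tpm.tsv")
            write_labels(labels, out / "labels.tsv")
            write_gene_lengths(lengths, out / "gene_lengths.tsv")
            muts, _ = simulate.simulate_mutations(cfg)
            muts.to_csv(out / "mutations.tsv", sep="\t", index=False)
            record(stage, seed=cfg.seed, n_genes=cfg.n_genes,
                   n_samples=gem.n_samples)
        elif stage == "preprocess":
            gem, report = prep.preprocess_pipeline(
                gem, ks_threshold=config.ks_threshold)
            write_gem(gem, out / "gem_normalized.tsv")
            report.to_frame().to_csv(out / "ks_report.tsv", sep="\t",
                                     index=False)
            record(stage, removed=report.removed_samples,
                   steps=report.steps_applied)
        elif stage == "network":
            edge_clusters = net.similarity_scan(
                gem, min_cluster=config.min_cluster,
                max_components=config.max_components, seed=config.seed)
            net.write_edge_list(edge_clusters, out / "edge_clusters.tsv")
            thr = rmt.rmt_threshold(edge_clusters,
                                    override_tau=config.tau_override)
            if thr.tau is None:
                raise RuntimeError(f"network stage: {thr.message}")
            network = net.extract_network(edge_clusters, thr.tau,
                                          n_samples=gem.n_samples)
            net.write_edge_list(network.edges, out / "network_edges.tsv")
            pd.DataFrame(thr.scan_trace,
                         columns=["threshold", "n_edges", "nnsd_chi2"]
                         ).to_csv(out / "rmt_trace.tsv", sep="\t", index=False)
            record(stage, tau=thr.tau, method=thr.method,
                   n_edges=len(network.edges))
        elif stage == "enrich":
            if not network.edges:
                record(stage, skipped="empty network")
                continue
            lc = communities.link_communities(
                network, min_edges=config.module_min_edges)
            pd.DataFrame([(m, "|".join(map(str, k))) for m, keys in
                          lc.modules.items() for k in keys],
                         columns=["module_id", "edge_key"]
                         ).to_csv(out / "modules.tsv", sep="\t", index=False)
            erecs = enrichment.enrich_edges(network.edges, labels,
                                            gem.sample_ids)
            mrecs = enrichment.enrich_modules(lc.module_edges, labels,
                                              gem.sample_ids)
            rows = [(r.target, r.label, *r.table, r.p_raw, r.p_adj)
                    for r in erecs + mrecs]
            pd.DataFrame(rows, columns=["target", "label", "a", "b", "c", "d",
                                        "p_raw", "p_adj"]
                         ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            region_sets = enrichment.select_region_sets(
                erecs, edge_alpha=config.edge_alpha)
            merge_map = {r: r for r in sorted({l for l in labels.values()})}
            merged = enrichment.merge_anatomical(region_sets, merge_map)
            rows = [(lab, f"{k[0]}|{k[1]}|{k[2]}")
                    for lab, keys in sorted(region_sets.region_edges.items())
                    for k in keys]
            pd.DataFrame(rows, columns=["region", "edge_key"]
                         ).to_csv(out / "region_edges.tsv", sep="\t",
                                  index=False)
            record(stage, n_modules=len(lc.modules),
                   regions={k: len(v) for k, v in
                            region_sets.region_edges.items()})
        elif stage == "embed":
            for name, genes in _gene_sets(merged, gem):
                if gem.n_samples <= 3 * config.perplexity:
                    break
                emb = embedding.project(gem, genes,
                                        perplexity=config.perplexity,
                                        pca_dims=config.pca_dims,
                                        seed=config.seed)
                df = emb.coords.copy()
                df["label"] = [labels[s] for s in df.index]
                df.to_csv(out / f"embedding_{name}.tsv", sep="\t",
                          index_label="sample_id")
            record(stage, perplexity=config.perplexity)
        elif stage == "screen":
            sets = dict(_gene_sets(merged, gem))
            reports = screening.phase1_screen(
                gem, labels, sets,
                spec=screening.RandomSetSpec(n_sets=config.n_random,
                                             size_tolerance=config.size_tolerance),
                folds=config.screen_folds, seed=config.seed,
                classifier=config.screen_classifier)
            rows = [(r.name, len(r.genes), r.mean_accuracy, r.random_mean,
                     r.t_p, r.significant) for r in reports]
            pd.DataFrame(rows, columns=["set", "n_genes", "accuracy",
                                        "random_mean", "t_p", "significant"]
                         ).to_csv(out / "screen.tsv", sep="\t", index=False)
            manifest["screen"] = rows
            record(stage, n_sets=len(sets))
        elif stage == "decompose":
            sets = dict(_gene_sets(merged, gem))
            if not sets:
                record(stage, skipped="no gene sets")
                continue
            name, genes = min(sets.items(), key=lambda t: (len(t[1]), t[0]))
            genes = genes[:config.decompose_set_size]
            if len(genes) < 4:
                record(stage, skipped=f"set {name} too small")
                continue
            res = decomposition.phase2_combinatorial(
                gem, labels, genes, exhaustive_max=config.exhaustive_max,
                beam_width=config.beam_width, seed=config.seed)
            res.frequency.to_csv(out / "decomposition_frequency.tsv", sep="\t")
            (out / "candidates.txt").write_text("\n".join(res.candidates) + "\n")
            (out / "non_candidates.txt").write_text(
                "\n".join(res.non_candidates) + "\n")
            record(stage, set=name, candidates=res.candidates)
        elif stage == "mutations":
            muts = mutations.read_mutations(out / "mutations.tsv")
            rows = []
            for tt in sorted(set(muts["tumor_type"])):
                for name, genes in _gene_sets(merged, gem):
                    res = mutations.empirical_enrichment(
                        muts, genes, tt, gem.gene_ids, gem.gene_lengths,
                        n_rand=config.n_rand_mutation, seed=config.seed)
                    for stat in mutations.STAT_NAMES:
                        rows.append((name, tt, stat, res.observed[stat],
                                     res.random_means[stat],
                                     res.p_value[stat],
                                     res.significant[stat]))
            pd.DataFrame(rows, columns=["set", "tumor_type", "statistic",
                                        "observed", "random_mean", "p",
                                        "significant"]
                         ).to_csv(out / "mutation_enrichment.tsv", sep="\t",
                                  index=False)
            record(stage, n_rows=len(rows))
        else:
            raise ValueError(f"unknown stage {stage!r}")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def _gene_sets(merged, gem) -> list[tuple[str, list[str]]]:
    if merged is None:
        return []
    return [(lab, nodes) for lab, nodes in sorted(merged.region_nodes.items())
            if len(nodes) >= 4]
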