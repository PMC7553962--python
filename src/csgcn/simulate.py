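"""Synthetic study generator: GEMs with planted region-specific
co-expression, sample labels, gene lengths, and somatic-mutation tables
with planted elevated-rate gene sets.

The expression model is a single latent factor per planted module per
region: for a sample of region r and a gene of a module planted in r,
the log2-scale value is

    x = b_g + noise_sd * (lambda * f_s + sqrt(1 - lambda^2) * eps)

with a per-sample factor f_s ~ N(factor_mean, 1) shared by the
module's genes, so within the planted region those genes are
correlated (Pearson lambda^2 on the log2 scale) while in every other
region — and for all background genes everywhere — values are
independent noise around the gene baseline b_g.  The nonzero factor
mean makes a planted module region-*activated* as well as
region-coexpressed: its genes run higher in the planted region, the
way condition-specific modules behave in real tissue panels.  (With a
zero-mean factor the in-region cluster would coincide in location with
the background cloud and no mixture model — this package's or any
other — could deconvolve it; lambda = 0 still removes both the
correlation and the shift.)  The emitted matrix is on the TPM-like
scale (2**x), with zeros injected at a configurable rate to exercise
the downstream "values < 0 ignored" rule.

Mutations: per tumor and gene, presence ~ Bernoulli(rate), with rate
multiplied for genes of an enriched set, and multiplicity
1 + Poisson(0.3) given presence; one output row per mutation event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gem import GEM

__all__ = ["PlantedModule", "MutationConfig", "SimConfig", "SimTruth",
           "simulate_gem", "simulate_mutations", "default_config"]


@dataclass
class PlantedModule:
    region_id: str
    gene_ids: list[str]
    factor_loading: float  # lambda in [0, 1)


@dataclass
class MutationConfig:
    tumor_types: list[str] = field(default_factory=lambda: ["TT1", "TT2"])
    tumors_per_type: int = 100
    background_rate: float = 0.01
    enriched_sets: list[tuple[list[str], float]] = field(default_factory=list)
    multiplicity_mean: float = 0.3  # Poisson mean of extra mutations given presence


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a modest multi-region bulk RNA-seq study: log2-TPM
    baselines around 4 (sd 1.5) so nearly all values are positive and
    expressed, unit per-sample noise on the log2 scale, a 1% dropout
    (exact zero) rate, and gene lengths log-uniform between 500 bp and
    100 kb.
    """

    n_regions: int = 6
    samples_per_region: int = 60
    n_genes: int = 300
    planted_modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 1.0
    factor_mean: float = 3.0
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    zero_prob: float = 0.01
    gene_length_range: tuple[int, int] = (500, 100_000)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    seed: int = 0

    # -- id helpers ------------------------------------------------------
    @property
    def region_ids(self) -> list[str]:
        return [f"R{i}" for i in range(self.n_regions)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if min(self.n_regions, self.samples_per_region, self.n_genes) < 1:
            raise ValueError("all counts must be >= 1")
        seen: set[str] = set()
        for m in self.planted_modules:
            if not 0.0 <= m.factor_loading < 1.0:
                raise ValueError(
                    f"factor loading must be in [0, 1): {m.factor_loading}")
            if m.region_id not in self.region_ids:
                raise ValueError(f"unknown region {m.region_id}")
            overlap = seen.intersection(m.gene_ids)
            if overlap:
                raise ValueError(
                    f"planted modules overlap on gene(s) {sorted(overlap)[:3]}")
            seen.update(m.gene_ids)
        unknown = seen.difference(self.gene_ids)
        if unknown:
            raise ValueError(f"planted gene(s) not in GEM: {sorted(unknown)[:3]}")
        max_mult = max((m for _, m in self.mutation.enriched_sets), default=1.0)
        if self.mutation.background_rate * max_mult > 1.0:
            raise ValueError("background_rate * multiplier exceeds 1")


@dataclass
class SimTruth:
    planted_edges: set[tuple[str, str, str]] = field(default_factory=set)
    informative_genes: dict[str, list[str]] = field(default_factory=dict)
    enriched_mutation_sets: list[tuple[list[str], float]] = field(default_factory=list)


def default_config(n_modules: int | None = None,
                   genes_per_module: int = 10,
                   factor_loading: float = 0.95,
                   **kwargs) -> SimConfig:
    """SimConfig with one planted module per region (the study default)."""
    cfg = SimConfig(**kwargs)
    if n_modules is None:
        n_modules = cfg.n_regions
    genes = cfg.gene_ids
    mods = []
    for i in range(n_modules):
        mods.append(PlantedModule(
            region_id=cfg.region_ids[i % cfg.n_regions],
            gene_ids=genes[i * genes_per_module:(i + 1) * genes_per_module],
            factor_loading=factor_loading))
    cfg.planted_modules = mods
    cfg.validate()
    return cfg


def simulate_gem(config: SimConfig
                 ) -> tuple[GEM, dict[str, str], dict[str, int], SimTruth]:
    """Draw a TPM-scale GEM with planted region-specific co-expression.

    Returns (gem, labels, gene_lengths, truth); the GEM also carries the
    labels and lengths.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    n_s = config.n_regions * config.samples_per_region
    sample_ids = [f"S{i:05d}" for i in range(n_s)]
    region_of = np.repeat(config.region_ids, config.samples_per_region)
    labels = dict(zip(sample_ids, region_of))

    gidx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                      size=config.n_genes)
    x = base[:, None] + config.noise_sd * rng.standard_normal(
        (config.n_genes, n_s))

    truth = SimTruth()
    for m in config.planted_modules:
        lam = m.factor_loading
        smask = region_of == m.region_id
        rows = [gidx[g] for g in m.gene_ids]
        f = config.factor_mean + rng.standard_normal(int(smask.sum()))
        eps = rng.standard_normal((len(rows), int(smask.sum())))
        signal = lam * f[None, :] + np.sqrt(1.0 - lam * lam) * eps
        x[np.ix_(rows, smask)] = base[rows][:, None] + config.noise_sd * signal
        truth.informative_genes.setdefault(m.region_id, []).extend(m.gene_ids)
        gs = sorted(m.gene_ids)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                truth.planted_edges.add((gs[i], gs[j], m.region_id))

    tpm = np.power(2.0, x)
    if config.zero_prob > 0:
        tpm[rng.random(tpm.shape) < config.zero_prob] = 0.0

    lo, hi = config.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    gene_lengths = {g: int(round(l)) for g, l in zip(genes, lengths)}

    df = pd.DataFrame(tpm, index=genes, columns=sample_ids)
    gem = GEM(values=df, labels=labels, gene_lengths=gene_lengths,
              log=[f"simulate_gem(seed={config.seed})"])
    truth.enriched_mutation_sets = list(config.mutation.enriched_sets)
    return gem, labels, gene_lengths, truth


def simulate_mutations(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a simplified MAF table (tumor_id, tumor_type, gene).

    Deterministic given ``config.seed``; uses a seed stream independent
    of the expression draw so the two tables can be generated in either
    order.
    """
    config.validate()
    mc = config.mutation
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = config.gene_ids
    rate = np.full(config.n_genes, mc.background_rate)
    gidx = {g: i for i, g in enumerate(genes)}
    for gene_ids, mult in mc.enriched_sets:
        for g in gene_ids:
            rate[gidx[g]] = mc.background_rate * mult
    if np.any(rate > 1.0):
        raise ValueError("per-gene presence probability exceeds 1")

    rows: list[tuple[str, str, str]] = []
    for tt in mc.tumor_types:
        for t in range(mc.tumors_per_type):
            tumor_id = f"{tt}-T{t:04d}"
            present = rng.random(config.n_genes) < rate
            idx = np.flatnonzero(present)
            counts = 1 + rng.poisson(mc.multiplicity_mean, size=idx.size)
            for i, c in zip(idx, counts):
                rows.extend([(tumor_id, tt, genes[i])] * int(c))
    table = pd.DataFrame(rows, columns=["tumor_id", "tumor_type", "gene"])
    truth = SimTruth(enriched_mutation_sets=list(mc.enriched_sets))
    return table, truth


def write_mutations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
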