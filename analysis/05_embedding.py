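#!/usr/bin/env python
"""Embed samples over each region gene set (PCA + t-SNE, perplexity 30)
and quantify region separation with the silhouette score against
label-shuffled baselines.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from csgcn.embedding import project, silhouette_margin
from csgcn.gem import read_gem

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 1


def main() -> None:
    gem = read_gem(OUT / "gem_log2.tsv", labels=OUT / "labels.tsv")
    gene_sets = sorted(OUT.glob("geneset_*.txt"))
    all_nodes = sorted({g for p in gene_sets for g in p.read_text().split()})
    gene_sets.append(None)  # the union set
    for path in gene_sets:
        name = path.stem.removeprefix("geneset_") if path else "all_regions"
        genes = path.read_text().split() if path else all_nodes
        if len(genes) < 2:
            print(f"  {name}: too few genes, skipped")
            continue
        emb = project(gem, genes, perplexity=30, seed=SEED)
        df = emb.coords.copy()
        df["label"] = [gem.labels[s] for s in df.index]
        df.to_csv(OUT / f"embedding_{name}.tsv", sep="\t",
                  index_label="sample_id")
        true, shuffled = silhouette_margin(emb, gem.labels, seed=SEED)
        print(f"  {name} ({len(genes)} genes): silhouette {true:.3f} "
              f"vs shuffled {shuffled:.3f}")


if __name__ == "__main__":
    main()
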