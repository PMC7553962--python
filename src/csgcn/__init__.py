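"""csgcn: condition-specific gene co-expression networks and gene-set
biomarker screening.

Pipeline stages (each its own module):

* :mod:`csgcn.simulate` — synthetic GEMs with planted region-specific
  co-expression and mutation tables with planted elevated-rate sets;
* :mod:`csgcn.preprocess` — log2 transform, KS outlier screen,
  quantile normalization;
* :mod:`csgcn.network` / :mod:`csgcn.rmt` — per-pair Gaussian-mixture
  sample clustering, per-cluster Spearman correlation, random-matrix
  thresholding, edge extraction;
* :mod:`csgcn.communities` / :mod:`csgcn.enrichment` — link-community
  modules, Fisher/Hochberg sample-label enrichment, region sub-network
  and unique-edge selection, anatomical merging;
* :mod:`csgcn.embedding` — PCA + t-SNE sample embedding per gene set;
* :mod:`csgcn.screening` / :mod:`csgcn.decomposition` — feedforward
  classifier screening against size-controlled random gene sets, and
  combinatorial decomposition into candidate genes;
* :mod:`csgcn.mutations` — mutation count statistics and empirical
  enrichment against size-controlled random sets.
"""

from importlib import resources

import yaml

from .gem import GEM, read_gem, write_gem

__version__ = "0.1.0"
__all__ = ["GEM", "read_gem", "write_gem", "example_merge_map"]


def example_merge_map() -> dict[str, str]:
    """The packaged 13-region -> anatomical-group example merge map."""
    text = resources.files("csgcn.data").joinpath(
        "brain_region_merge.yaml").read_text()
    return yaml.safe_load(text)
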