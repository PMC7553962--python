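"""GEM preprocessing: log2 transform, KS outlier screen, quantile normalization.

The fixed pipeline order is log2 -> KS outlier screen -> quantile
normalization.  Each step is recorded in the report so a run can be
audited afterwards.

Notes on conventions
--------------------
* ``log2_transform`` maps 0 to missing (log of zero is undefined);
  positive values below 1 become negative log2 values and are retained —
  the network stage ignores values < 0 when pairing samples.
* The KS screen compares each sample's empirical distribution of
  non-missing values against the pool of all *other* samples, flagging
  samples with Dval strictly greater than the threshold (default 0.15).
* Quantile normalization forces every sample's sorted value vector to
  the across-sample mean of sorted vectors; ties receive the mean of
  their target quantiles, and missing entries stay missing (ranks are
  taken over the non-missing entries of each sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gem import GEM

__all__ = ["PreprocessReport", "log2_transform", "ks_outlier_flags",
           "quantile_normalize", "preprocess_pipeline"]


@dataclass
class PreprocessReport:
    dvals: dict[str, float] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)
    steps_applied: list[str] = field(default_factory=list)
    threshold: float = 0.15

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": list(self.dvals),
            "Dval": list(self.dvals.values()),
            "flagged": [s in self.removed_samples for s in self.dvals],
        })


def log2_transform(gem: GEM) -> GEM:
    """log2 each positive value; zeros become missing; negatives are an error."""
    vals = gem.matrix()
    if np.nanmin(vals) < 0:
        raise ValueError("log2_transform expects nonnegative (linear-scale) values")
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    df = pd.DataFrame(out, index=gem.values.index, columns=gem.values.columns)
    return gem.copy_with(df, step="log2")


def ks_outlier_flags(gem: GEM, dval_threshold: float = 0.15) -> PreprocessReport:
    """Two-sample KS screen of each sample against the pool of all others.

    A sample is flagged iff its KS statistic (Dval) is strictly greater
    than ``dval_threshold``.
    """
    report = PreprocessReport(threshold=dval_threshold)
    cols = gem.sample_ids
    mat = gem.matrix()
    col_vals = [mat[:, j][~np.isnan(mat[:, j])] for j in range(len(cols))]
    for v, s in zip(col_vals, cols):
        if v.size < 2:
            raise ValueError(f"sample {s} has fewer than 2 non-missing values")
    for j, s in enumerate(cols):
        pooled = np.concatenate([col_vals[i] for i in range(len(cols)) if i != j])
        d = stats.ks_2samp(col_vals[j], pooled, method="asymp").statistic
        report.dvals[s] = float(d)
        if d > dval_threshold:
            report.removed_samples.append(s)
    report.steps_applied.append(f"ks_screen(threshold={dval_threshold})")
    return report


def quantile_normalize(gem: GEM) -> GEM:
    """Quantile-normalize samples so all share the mean sorted profile.

    Missing entries are excluded from ranking and remain missing; ties
    get the mean of their target quantiles.  With no missing data every
    per-sample sorted vector equals the across-sample mean of sorted
    vectors exactly.
    """
    mat = gem.matrix()
    n_genes, n_samples = mat.shape
    if n_genes == 0 or n_samples == 0:
        raise ValueError("empty GEM")
    for j in range(n_samples):
        if np.all(np.isnan(mat[:, j])):
            raise ValueError(f"sample {gem.sample_ids[j]} is fully missing")

    # reference profile: mean of per-column sorted values, interpolated
    # onto a common grid of n_genes quantile positions
    grid = (np.arange(n_genes) + 0.5) / n_genes
    ref = np.zeros(n_genes)
    for j in range(n_samples):
        col = mat[:, j]
        obs = np.sort(col[~np.isnan(col)])
        m = obs.size
        q = (np.arange(m) + 0.5) / m
        ref += np.interp(grid, q, obs)
    ref /= n_samples

    out = np.full_like(mat, np.nan)
    for j in range(n_samples):
        col = mat[:, j]
        ok = ~np.isnan(col)
        m = int(ok.sum())
        # average ranks (ties averaged), mapped to reference quantiles
        r = stats.rankdata(col[ok], method="average")
        q = (r - 0.5) / m
        out[ok, j] = np.interp(q, grid, ref)
    df = pd.DataFrame(out, index=gem.values.index, columns=gem.values.columns)
    return gem.copy_with(df, step="quantile_normalize")


def preprocess_pipeline(gem: GEM, ks_threshold: float = 0.15
                        ) -> tuple[GEM, PreprocessReport]:
    """log2 -> KS outlier removal -> quantile normalization."""
    g = log2_transform(gem)
    report = ks_outlier_flags(g, dval_threshold=ks_threshold)
    report.steps_applied.insert(0, "log2")
    if report.removed_samples:
        keep = [s for s in g.sample_ids if s not in report.removed_samples]
        labels = None
        if g.labels is not None:
            labels = {s: g.labels[s] for s in keep}
        g = GEM(values=g.values[keep], labels=labels,
                gene_lengths=g.gene_lengths, log=list(g.log))
    g = quantile_normalize(g)
    report.steps_applied.append("quantile_normalize")
    return g, report
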