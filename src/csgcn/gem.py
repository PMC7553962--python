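"""Gene expression matrix (GEM) container and TSV I/O.

A GEM is a genes x samples matrix of expression values (TPM-like on the
linear scale, or log2 after transformation), with optional per-sample
region labels and per-gene lengths.  It is the universal input of the
pipeline: every downstream stage consumes a GEM or something derived
from one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GEM", "read_gem", "write_gem", "read_labels", "write_labels",
           "read_gene_lengths", "write_gene_lengths"]


@dataclass
class GEM:
    """Genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  NaN
        marks a missing measurement.
    labels
        Optional map sample id -> region label.  When present it must
        cover every sample.
    gene_lengths
        Optional map gene id -> length in bp, used for size-controlled
        random gene-set matching.
    """

    values: pd.DataFrame
    labels: dict[str, str] | None = None
    gene_lengths: dict[str, int] | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if self.labels is not None:
            missing = [s for s in cols if s not in self.labels]
            if missing:
                raise ValueError(
                    f"labels do not cover {len(missing)} sample(s), "
                    f"e.g. {missing[:3]}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("GEM carries no sample labels")
        return np.asarray([self.labels[s] for s in self.sample_ids])

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy_with(self, values: pd.DataFrame, step: str | None = None) -> "GEM":
        log = list(self.log) + ([step] if step else [])
        return GEM(values=values, labels=self.labels,
                   gene_lengths=self.gene_lengths, log=log)


def read_gem(path: str | Path, labels: str | Path | None = None,
             gene_lengths: str | Path | None = None) -> GEM:
    """Read a GEM TSV (first column gene id, header row sample ids).

    Empty cells are read as missing.  Duplicate gene or sample ids and
    non-numeric body cells raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in GEM {path}: {exc}") from exc
    lab = read_labels(labels) if labels is not None else None
    gl = read_gene_lengths(gene_lengths) if gene_lengths is not None else None
    return GEM(values=df, labels=lab, gene_lengths=gl)


def write_gem(gem: GEM, path: str | Path) -> None:
    gem.values.to_csv(path, sep="\t", index_label="gene_id",
                      float_format="%.10g")


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs >= 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(labels), "region": list(labels.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def write_gene_lengths(lengths: dict[str, int], path: str | Path) -> None:
    pd.DataFrame({"gene_id": list(lengths),
                  "length_bp": list(lengths.values())}
                 ).to_csv(path, sep="\t", index=False)
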