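"""Core in-memory containers shared by all pipeline stages.

A :class:`CountMatrix` holds raw integer read counts (genes x samples)
together with per-sample metadata (developmental stage, dissected region,
replicate id, whole-embryo flag) and per-gene metadata (ortholog name,
homeolog suffix, transcript length, chromosome arm).  A
:class:`ExpressionMatrix` holds TMM-normalized log2-CPM values derived from
it.  Both are thin wrappers around aligned pandas objects with validation
and plain-text (TSV) round-trip I/O, so every stage of the pipeline can be
re-run from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_META_COLUMNS = ("stage", "region", "replicate", "is_whole_embryo")
GENE_META_COLUMNS = ("ortholog", "suffix", "length", "arm")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dup[:5]}")


@dataclass
class CountMatrix:
    """Integer read counts with sample and gene annotations.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers.
    sample_meta
        Indexed by sample id; columns ``stage``, ``region``, ``replicate``,
        ``is_whole_embryo``.
    gene_meta
        Indexed by gene id; columns ``ortholog``, ``suffix`` (``l``/``s`` or
        empty), ``length`` (nt), ``arm`` (``L``/``S``/``unknown``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        if not self.counts.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        if not self.counts.index.equals(self.gene_meta.index):
            self.gene_meta = self.gene_meta.loc[self.counts.index]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes],
                           self.sample_meta,
                           self.gene_meta.loc[genes])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)],
                           self.sample_meta.loc[list(samples)],
                           self.gene_meta)

    def dissected(self) -> "CountMatrix":
        """Samples from microdissected regions (whole embryos excluded)."""
        keep = self.sample_meta.index[~self.sample_meta["is_whole_embryo"]]
        return self.subset_samples(keep)

    # ------------------------------------------------------------------ I/O
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(path / "counts.tsv", sep="\t", index_label="gene")
        self.sample_meta.to_csv(path / "samples.tsv", sep="\t",
                                index_label="sample")
        self.gene_meta.to_csv(path / "genes.tsv", sep="\t",
                              index_label="gene")

    @classmethod
    def from_dir(cls, path) -> "CountMatrix":
        path = Path(path)
        counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col="gene")
        smeta = pd.read_csv(path / "samples.tsv", sep="\t",
                            index_col="sample")
        gmeta = pd.read_csv(path / "genes.tsv", sep="\t", index_col="gene",
                            keep_default_na=False,
                            na_values=[""])
        smeta["is_whole_embryo"] = smeta["is_whole_embryo"].astype(bool)
        return cls(counts, smeta, gmeta)


@dataclass
class ExpressionMatrix:
    """TMM-normalized log2-CPM values, with provenance of the scaling.

    ``values[g, s] = log2((count + prior) / (libsize_s * factor_s) * 1e6)``.
    """

    values: pd.DataFrame
    scaling_factors: pd.Series
    prior_count: float
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if (self.scaling_factors <= 0).any():
            raise ValueError("scaling factors must be positive")
        gm = np.exp(np.mean(np.log(self.scaling_factors.to_numpy())))
        if abs(gm - 1.0) > 1e-6:
            raise ValueError("scaling factors must have geometric mean 1, "
                             f"got {gm!r}")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def linear(self) -> pd.DataFrame:
        """Back-transform to linear-scale CPM (2**log2-CPM)."""
        return 2.0 ** self.values

    def subset_genes(self, genes) -> "ExpressionMatrix":
        # bypasses re-validation: factor geometric mean is a whole-dataset
        # invariant that gene/sample subsets need not preserve
        sub = ExpressionMatrix.__new__(ExpressionMatrix)
        sub.values = self.values.loc[genes]
        sub.scaling_factors = self.scaling_factors
        sub.prior_count = self.prior_count
        sub.sample_meta = self.sample_meta
        sub.gene_meta = self.gene_meta.loc[genes] \
            if len(self.gene_meta.columns) else self.gene_meta.reindex(genes)
        return sub

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        sub = ExpressionMatrix.__new__(ExpressionMatrix)
        sub.values = self.values[samples]
        sub.scaling_factors = self.scaling_factors.loc[samples]
        sub.prior_count = self.prior_count
        sub.sample_meta = self.sample_meta.loc[samples]
        sub.gene_meta = self.gene_meta
        return sub

    def dissected(self) -> "ExpressionMatrix":
        keep = self.sample_meta.index[~self.sample_meta["is_whole_embryo"]]
        return self.subset_samples(keep)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(path / "log2cpm.tsv", sep="\t", index_label="gene")
        prov = self.scaling_factors.to_frame("tmm_factor")
        prov["prior_count"] = self.prior_count
        prov.to_csv(path / "scaling.tsv", sep="\t", index_label="sample")
        self.sample_meta.to_csv(path / "samples.tsv", sep="\t",
                                index_label="sample")

    @classmethod
    def from_dir(cls, path) -> "ExpressionMatrix":
        path = Path(path)
        values = pd.read_csv(path / "log2cpm.tsv", sep="\t", index_col="gene")
        prov = pd.read_csv(path / "scaling.tsv", sep="\t", index_col="sample")
        smeta = pd.read_csv(path / "samples.tsv", sep="\t",
                            index_col="sample")
        smeta["is_whole_embryo"] = smeta["is_whole_embryo"].astype(bool)
        return cls(values, prov["tmm_factor"],
                   float(prov["prior_count"].iloc[0]), smeta)
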