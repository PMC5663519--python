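"""Tissue-specificity scoring and signature extraction.

A gene's concentration across the K NMF-tissues is measured by the
population Gini index, G = sum_ij |x_i - x_j| / (2 K^2 mean(x)), which is 0
for uniform expression and (K-1)/K for expression confined to a single
tissue (0.8 for K = 5, the scale the signature cutoff 0.7-0.8 refers to).
Ectoderm enrichment is the ratio of a gene's mean expression in a dissected
region to its mean whole-embryo (WE) expression at the matching stage,
converted to a 0-100 percentile score among all genes in that region.  The
signature of a tissue collects the genes assigned to it (argmax of the
extended component matrix) with near-maximal Gini and non-negative ectoderm
enrichment (highest dissected-region median log2 expression at least the WE
median).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def gini_index(tissue_levels) -> float:
    """Population Gini index of a non-negative expression vector.

    Maximum (K-1)/K is attained by single-tissue expression; 0 by perfect
    equality.  All-zero input is undefined and returns NaN with a warning.
    """
    x = np.asarray(tissue_levels, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if (x < 0).any():
        raise ValueError("tissue levels must be non-negative")
    if x.sum() == 0:
        warnings.warn("all-zero expression: Gini undefined")
        return float("nan")
    k = len(x)
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff / (2.0 * k * k * x.mean()))


def gini_table(W_full: pd.DataFrame) -> pd.Series:
    """Gini index of every gene's row of the extended component matrix."""
    x = W_full.to_numpy(dtype=float)
    k = x.shape[1]
    total = x.sum(axis=1)
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = diff / (2.0 * k * total)
    return pd.Series(g, index=W_full.index, name="gini")


def ectoderm_enrichment(expr, stage: str, pseudo_cpm: float = 0.5):
    """Region/WE expression ratio and percentile score per gene.

    Ratios are computed on linear CPM with a pseudo-count; the score is the
    percentile rank (average ranks for ties, 0-100) of the ratio among all
    genes within that region.

    Returns
    -------
    (ratios, scores)
        Two genes x regions DataFrames.
    """
    meta = expr.sample_meta
    stage_mask = meta["stage"] == stage
    we_cols = expr.samples[(meta["is_whole_embryo"] & stage_mask).to_numpy()]
    if len(we_cols) == 0:
        raise ValueError(f"no whole-embryo sample at stage {stage!r}")
    lin = expr.linear()
    we_mean = lin[we_cols].mean(axis=1) + pseudo_cpm
    diss = meta.index[(~meta["is_whole_embryo"] & stage_mask).to_numpy()]
    ratios, scores = {}, {}
    for region, cols in meta.loc[diss].groupby("region").groups.items():
        ratio = (lin[list(cols)].mean(axis=1) + pseudo_cpm) / we_mean
        r = rankdata(ratio.to_numpy(), method="average")
        ratios[region] = ratio
        scores[region] = pd.Series(100.0 * r / len(r), index=ratio.index)
    return pd.DataFrame(ratios), pd.DataFrame(scores)


def _ectoderm_pass(expr) -> pd.Series:
    """True when the highest dissected-region median log2 expression is at
    least the whole-embryo median log2 expression."""
    meta = expr.sample_meta
    we_cols = expr.samples[meta["is_whole_embryo"].to_numpy()]
    diss = meta.index[~meta["is_whole_embryo"].to_numpy()]
    we_median = expr.values[we_cols].median(axis=1)
    best = None
    for region, cols in meta.loc[diss].groupby("region").groups.items():
        med = expr.values[list(cols)].median(axis=1)
        best = med if best is None else np.maximum(best, med)
    return pd.Series(best - we_median >= 0, index=expr.genes,
                     name="ectoderm_pass")


def tissue_signatures(W_full: pd.DataFrame, expr, gini_min: float = 0.7):
    """Per-NMF-tissue signature gene lists.

    A gene belongs to tissue t's signature iff t is the argmax of its
    extended component row, its Gini index is >= ``gini_min``, and it passes
    the ectoderm-enrichment rule.

    Returns
    -------
    (signatures, table)
        ``signatures``: dict tissue -> list of genes (disjoint lists).
        ``table``: per-gene SignatureTable (tissue, gini, ectoderm_pass,
        in_signature).
    """
    g = gini_table(W_full)
    assigned = W_full.idxmax(axis=1)
    zero = W_full.sum(axis=1) == 0
    epass = _ectoderm_pass(expr).reindex(W_full.index, fill_value=False)
    in_sig = (g >= gini_min) & epass & ~zero
    table = pd.DataFrame({"tissue": assigned, "gini": g,
                          "ectoderm_pass": epass, "in_signature": in_sig})
    table.loc[zero, "tissue"] = pd.NA
    sigs = {t: table.index[(table["tissue"] == t)
                           & table["in_signature"]].tolist()
            for t in W_full.columns}
    return sigs, table
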