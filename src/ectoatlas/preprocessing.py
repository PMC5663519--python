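"""Count filtering and normalization downstream of read counting.

Genes are kept when they reach >= 10 counts in >= 2 samples; library sizes
are corrected by trimmed-mean-of-M-values (TMM) scaling factors; counts are
transformed to log2-CPM with a pseudo-count.  The TMM implementation follows
the canonical published definition: pairwise M (log-ratio) and A (average
log-abundance) values against a reference sample, trimming 30% of M-values
and 5% of A-values in each tail, precision-weighted mean of the surviving
M-values, and a final rescaling of the factors to geometric mean 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix


def filter_low_counts(counts: CountMatrix, min_count: int = 10,
                      min_samples: int = 2) -> CountMatrix:
    """Retain genes with at least ``min_count`` counts in ``min_samples``
    samples (order preserved)."""
    mask = (counts.counts >= min_count).sum(axis=1) >= min_samples
    if not mask.any():
        warnings.warn("filter_low_counts removed every gene")
    return counts.subset_genes(counts.genes[mask])


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.30,
                     abundance_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # delta-method variance of M -> precision weights
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) \
        & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, reference: str | None = None
                ) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th-percentile CPM is
    closest to the mean of those percentiles across samples.
    """
    mat = counts.counts.to_numpy().astype(float)
    lib = mat.sum(axis=0)
    zero = counts.samples[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    if reference is None:
        q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75)
                        for j in range(mat.shape[1])])
        ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_j = counts.samples.get_loc(reference)
    factors = np.array([
        _tmm_pair_factor(mat[:, j], mat[:, ref_j], lib[j], lib[ref_j])
        for j in range(mat.shape[1])])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


def to_log2_cpm(counts: CountMatrix, factors: pd.Series | None = None,
                prior_count: float = 0.5) -> ExpressionMatrix:
    """log2-CPM: log2((count + prior) / (libsize * factor) * 1e6).

    Monotone in the count; the effective library size is the raw total
    scaled by the TMM factor.
    """
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.counts.sum(axis=0).astype(float)
    eff = lib * factors.loc[counts.samples]
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    vals = np.log2((counts.counts.to_numpy() + prior_count)
                   / eff.to_numpy()[None, :] * 1e6)
    values = pd.DataFrame(vals, index=counts.genes, columns=counts.samples)
    return ExpressionMatrix(values, factors.loc[counts.samples], prior_count,
                            counts.sample_meta, counts.gene_meta)


def mean_variance_weights(counts: CountMatrix,
                          factors: pd.Series | None = None,
                          prior_count: float = 0.5,
                          frac: float = 0.5) -> pd.DataFrame:
    """Precision weights from the mean-variance trend of log-counts.

    A lowess fit of sqrt(per-gene residual sd) against mean log2 count
    predicts, for every observation, the expected sqrt-sd; the weight is the
    inverse fourth power (inverse predicted variance).  Consumed only by the
    homeolog differential test; all other stages use unweighted log2-CPM.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    expr = to_log2_cpm(counts, factors, prior_count)
    vals = expr.values.to_numpy()
    mean_log = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    sqrt_sd = np.sqrt(np.maximum(sd, 1e-8))
    fit = lowess(sqrt_sd, mean_log, frac=frac, return_sorted=True)
    xs, ys = fit[:, 0], np.maximum(fit[:, 1], 1e-4)
    pred = np.interp(vals, xs, ys)
    w = 1.0 / pred ** 4
    return pd.DataFrame(w, index=expr.genes, columns=expr.samples)
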