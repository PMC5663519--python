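"""Expression divergence of homeologous gene pairs.

Allotetraploid genomes retain duplicated gene copies from the two progenitor
genomes, marked .l (long chromosome) and .s (short).  Pairs are formed when
an ortholog name maps to exactly one .l and one .s gene, filtered to
length-comparable (< 20% relative length difference) and expressed pairs,
and tested region by region for differential expression between copies with
a moderated paired t-test: per-pair variances are shrunk toward a pooled
prior by empirical Bayes, and p-values are BH-adjusted across all
pair x region tests.  Classification: one copy significantly higher in >= 2
regions with no opposite-direction region = asymmetric decrease of the
other copy; significant regions in both directions = spatial
subfunctionalization; one significant region only = "one-region"; none =
similar.  A two-sided exact binomial test measures whether asymmetric
decrease preferentially hits the S subgenome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import binomtest, t as t_dist
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CLASSES = ("asymmetric", "subfunctionalized", "similar", "one-region",
           "untestable")


def pair_homeologs(gene_meta: pd.DataFrame) -> pd.DataFrame:
    """Form pairs from ortholog names mapping to exactly one .l and one .s
    gene; ambiguous names are skipped (count logged)."""
    meta = gene_meta[gene_meta["suffix"].isin(["l", "s"])]
    rows, skipped = [], 0
    for orth, sub in meta.groupby("ortholog"):
        if len(sub) != 2 or set(sub["suffix"]) != {"l", "s"}:
            skipped += 1
            continue
        gl = sub.index[sub["suffix"] == "l"][0]
        gs = sub.index[sub["suffix"] == "s"][0]
        rows.append({"ortholog": orth, "gene_l": gl, "gene_s": gs,
                     "length_l": sub.loc[gl, "length"],
                     "length_s": sub.loc[gs, "length"]})
    if skipped:
        log.info("pair_homeologs: skipped %d ambiguous ortholog name(s)",
                 skipped)
    return pd.DataFrame(rows, columns=["ortholog", "gene_l", "gene_s",
                                       "length_l", "length_s"])


def pair_filters(pairs: pd.DataFrame, counts,
                 max_length_diff: float = 0.20,
                 min_counts: int = 10) -> pd.DataFrame:
    """Retain testable pairs.

    Rules: relative transcript-length difference |l1 - l2| / max(l1, l2)
    strictly below ``max_length_diff``; pairs with zero counts in both
    copies discarded; total counts of the pair at least ``min_counts``.
    Pairs with a missing length are untestable and logged.
    """
    keep = []
    n_missing = 0
    totals = counts.counts.sum(axis=1)
    for _, row in pairs.iterrows():
        l1, l2 = row["length_l"], row["length_s"]
        if pd.isna(l1) or pd.isna(l2):
            n_missing += 1
            continue
        rel = abs(float(l1) - float(l2)) / max(float(l1), float(l2))
        if rel >= max_length_diff:
            continue
        tot_l = totals.get(row["gene_l"], 0)
        tot_s = totals.get(row["gene_s"], 0)
        if tot_l == 0 and tot_s == 0:
            continue
        if tot_l + tot_s < min_counts:
            continue
        keep.append(row)
    if n_missing:
        log.info("pair_filters: %d pair(s) untestable (missing length)",
                 n_missing)
    return pd.DataFrame(keep, columns=pairs.columns).reset_index(drop=True)


# --------------------------------------------------------------------------
# empirical-Bayes variance shrinkage (moderated t)

def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: np.ndarray):
    """Shrink sample variances toward a pooled prior.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by moment matching on log variances, then returns the
    posterior variances (d0 s0^2 + df s2) / (d0 + df) along with (d0, s0^2).
    d0 may be infinite when the variances show no excess spread.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    df = np.asarray(df, dtype=float)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = e.var(ddof=1) * n / (n - 1) if n > 1 else 0.0
    evar -= polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
        post = np.full_like(s2, s0_2)
    return post, d0, s0_2


def differential_by_region(pairs: pd.DataFrame, expr, alpha: float = 0.05,
                           weights: pd.DataFrame | None = None,
                           method: str = "fdr_bh") -> pd.DataFrame:
    """Moderated paired test of L vs S per pair per (stage, region).

    The per-replicate difference d = log2CPM(L) - log2CPM(S) is averaged
    within each dissected (stage, region) cell; per-cell variances are
    shrunk by empirical Bayes across all (pair, cell) tests; p-values come
    from a t distribution with df + d0 degrees of freedom and are adjusted
    jointly (BH by default, Bonferroni optional).  Cells with a single
    replicate are skipped.  Optional per-observation precision weights (from
    the mean-variance trend) turn the mean and variance into weighted ones.
    """
    sub = expr.dissected()
    meta = sub.sample_meta
    cells = list(meta.groupby(["stage", "region"]).groups.items())
    rows = []
    for _, pr in pairs.iterrows():
        gl, gs = pr["gene_l"], pr["gene_s"]
        if gl not in sub.genes or gs not in sub.genes:
            continue
        dvec = sub.values.loc[gl] - sub.values.loc[gs]
        for (stage, region), cols in cells:
            cols = list(cols)
            if len(cols) < 2:
                continue
            d = dvec[cols].to_numpy()
            if weights is not None:
                w = np.minimum(weights.loc[gl, cols].to_numpy(),
                               weights.loc[gs, cols].to_numpy())
                mean = np.average(d, weights=w)
                s2 = np.average((d - mean) ** 2, weights=w) \
                    * len(d) / (len(d) - 1)
            else:
                mean = d.mean()
                s2 = d.var(ddof=1)
            rows.append({"ortholog": pr["ortholog"], "stage": stage,
                         "region": region, "n": len(d), "lfc": mean,
                         "s2": s2})
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    df = res["n"].to_numpy() - 1.0
    post, d0, s0_2 = squeeze_var(res["s2"].to_numpy(), df)
    tstat = res["lfc"].to_numpy() / np.sqrt(post / res["n"].to_numpy())
    total_df = df + (d0 if np.isfinite(d0) else 1e6)
    p = 2.0 * t_dist.sf(np.abs(tstat), total_df)
    res["t"] = tstat
    res["p_value"] = p
    res["p_adj"] = multipletests(p, method=method)[1]
    res["significant"] = res["p_adj"] <= alpha
    res["direction"] = np.where(res["lfc"] > 0, "L>S", "S>L")
    res.attrs["d0"] = d0
    res.attrs["s0_2"] = s0_2
    return res.drop(columns=["s2"])


@dataclass
class PairClassification:
    ortholog: str
    klass: str
    decreased: str           # "L", "S" or "none"
    n_sig_l_up: int
    n_sig_s_up: int
    supporting_regions: tuple


def classify_pair(results: pd.DataFrame) -> PairClassification:
    """Classify one pair from its per-region test results."""
    orth = results["ortholog"].iloc[0]
    sig = results[results["significant"]]
    npos = int((sig["direction"] == "L>S").sum())
    nneg = int((sig["direction"] == "S>L").sum())
    regions = tuple(sig["region"])
    if npos >= 1 and nneg >= 1:
        klass, dec = "subfunctionalized", "none"
    elif npos >= 2:
        klass, dec = "asymmetric", "S"
    elif nneg >= 2:
        klass, dec = "asymmetric", "L"
    elif npos + nneg == 1:
        klass, dec = "one-region", "none"
    else:
        klass, dec = "similar", "none"
    return PairClassification(orth, klass, dec, npos, nneg, regions)


def classify_all(results: pd.DataFrame) -> pd.DataFrame:
    """Classify every pair; returns one row per ortholog."""
    rows = [classify_pair(sub) for _, sub in results.groupby("ortholog",
                                                             sort=True)]
    return pd.DataFrame([r.__dict__ for r in rows])


def chromosome_bias(classified: pd.DataFrame):
    """Two-sided exact binomial test of S-copy decrease among asymmetric
    pairs against the symmetric null of 1/2."""
    asym = classified[classified["klass"] == "asymmetric"]
    if len(asym) == 0:
        raise ValueError("no asymmetric pair to test")
    k = int((asym["decreased"] == "S").sum())
    n = int(len(asym))
    return binomtest(k, n, 0.5, alternative="two-sided")


def co_cluster_rate(pairs: pd.DataFrame, groups) -> float:
    """Fraction of pairs whose two copies share the same non-zero
    co-expression group, among pairs with both copies in the clustered set."""
    labels = groups.labels if hasattr(groups, "labels") else groups
    num = den = 0
    for _, row in pairs.iterrows():
        gl, gs = row["gene_l"], row["gene_s"]
        if gl not in labels.index or gs not in labels.index:
            continue
        den += 1
        if labels[gl] == labels[gs] and labels[gl] > 0:
            num += 1
    return num / den if den else float("nan")
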