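"""Signed weighted co-expression groups and functional enrichment.

Transcripts passing a low-expression filter are connected by a signed
adjacency a_ij = ((1 + bicor(x_i, x_j)) / 2)^power built on the biweight
midcorrelation (robust to outlier samples), with the soft power chosen so
the connectivity distribution approximates a scale-free topology.  The
signed topological overlap matrix (TOM) augments direct adjacency with
shared-neighbor structure; 1 - TOM is the dissimilarity fed to
average-linkage hierarchical clustering, whose branches are cut dynamically
with a minimum group size.  Groups are tested for annotation-term
overrepresentation with one-sided Fisher exact tests (Bonferroni-adjusted p
and BH q cutoffs), against size-preserving randomized group assignments as
the negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


def wgcna_filter(cpm: pd.DataFrame, max_cpm: float = 50.0,
                 sum_cpm: float = 40.0) -> pd.DataFrame:
    """Keep transcripts with at least one sample above ``max_cpm`` CPM or an
    absolute CPM sum across all samples above ``sum_cpm``."""
    keep = (cpm.max(axis=1) > max_cpm) | (cpm.abs().sum(axis=1) > sum_cpm)
    return cpm.loc[keep]


def bicor(values: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between rows.

    Uses the canonical 9-MAD weighting: u = (x - med) / (9 MAD),
    w = (1 - u^2)^2 for |u| < 1.  Rows with zero MAD fall back to
    Pearson standardization (their products with any row then reduce to a
    Pearson-style correlation), which is the standard fallback.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    ok = mad[:, 0] > 0
    u = np.zeros_like(x)
    u[ok] = (x[ok] - med[ok]) / (9.0 * mad[ok])
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    xt = (x - med) * w
    # Pearson fallback for zero-MAD rows
    if (~ok).any():
        mean = x[~ok].mean(axis=1, keepdims=True)
        xt[~ok] = x[~ok] - mean
    norm = np.linalg.norm(xt, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    z = xt / norm
    c = z @ z.T
    return np.clip(c, -1.0, 1.0)


def signed_adjacency(values, power: float = 22.0) -> np.ndarray:
    """a_ij = ((1 + bicor) / 2)^power, diagonal 1."""
    vals = values.to_numpy() if hasattr(values, "to_numpy") else values
    a = ((1.0 + bicor(vals)) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def unsigned_adjacency(values, power: float = 22.0) -> np.ndarray:
    """a_ij = |bicor|^power, diagonal 1 (keeps negative associations)."""
    vals = values.to_numpy() if hasattr(values, "to_numpy") else values
    a = np.abs(bicor(vals)) ** power
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(values, powers, signed: bool = True,
                   n_bins: int = 10) -> pd.DataFrame:
    """Scale-free-topology fit per candidate soft power.

    For each power: build the adjacency, compute per-node connectivity
    k_i = sum_j a_ij - 1, bin k, and regress log10 p(k) on log10 mean(k)
    per bin.  Reports the fit R^2, the regression slope and the mean
    connectivity.
    """
    vals = values.to_numpy() if hasattr(values, "to_numpy") else values
    if vals.shape[0] < 20:
        warnings.warn("scale-free fit on < 20 transcripts is unreliable")
    if np.any(vals.std(axis=1) == 0):
        raise ValueError("degenerate (constant) transcript in input")
    c = bicor(vals)
    rows = []
    for power in powers:
        a = ((1.0 + c) / 2.0) ** power if signed else np.abs(c) ** power
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=0) - 1.0
        r2, slope = _scale_free_r2(k, n_bins)
        rows.append({"power": power, "r_squared": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    return pd.DataFrame(rows)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10):
    """R^2 and slope of the binned log10 p(k) vs log10 k regression."""
    k = k[k > 0]
    if len(k) < 2:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = np.sum((np.asarray(ys) - pred) ** 2)
    ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(r2), float(slope)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Signed TOM for an adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    k_i the off-diagonal connectivity; diagonal 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    kmin = np.minimum(k[:, None], k[None, :])
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class CoexpressionGroups:
    """Transcript -> group assignment (group 0 = unassigned), groups
    relabeled by descending size (id 1 = largest)."""

    labels: pd.Series
    tree: np.ndarray
    cut_height: float
    min_size: int
    deep_split: int

    def __post_init__(self) -> None:
        sizes = self.sizes()
        if (sizes < self.min_size).any():
            raise ValueError("a non-zero group is below the minimum size")
        ids = sizes.index.to_numpy()
        if len(ids) and not np.array_equal(np.sort(ids),
                                           np.arange(1, len(ids) + 1)):
            raise ValueError("group ids must be contiguous from 1")

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts()
        return counts.sort_index()


def cluster_groups(dissimilarity, min_size: int = 15, deep_split: int = 4,
                   pam_stage: bool = False,
                   ids=None) -> CoexpressionGroups:
    """Average-linkage clustering of a TOM dissimilarity with a dynamic cut.

    The tree is cut at a deep-split-dependent fraction of its maximum merge
    height (0.95 - 0.05 * deep_split); clusters smaller than ``min_size``
    are dissolved into group 0.  With ``pam_stage``, unassigned transcripts
    closer (in mean dissimilarity) to some cluster than the cut height are
    reassigned to the nearest cluster.  Groups are relabeled by descending
    size, id 1 = largest.
    """
    d = dissimilarity.to_numpy() if hasattr(dissimilarity, "to_numpy") \
        else np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if ids is None:
        ids = getattr(dissimilarity, "index",
                      pd.RangeIndex(d.shape[0]))
    n = d.shape[0]
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if n < min_size:
        labels = pd.Series(0, index=ids, name="group")
        return CoexpressionGroups(labels, np.empty((0, 4)), float("nan"),
                                  min_size, deep_split)
    condensed = d[np.triu_indices(n, k=1)]
    tree = linkage(condensed, method="average")
    cut = float((0.95 - 0.05 * deep_split) * tree[:, 2].max())
    raw = fcluster(tree, t=cut, criterion="distance")
    lab = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for c, size in sizes.items():
        if size >= min_size:
            lab[raw == c] = next_id
            next_id += 1
    if pam_stage and (lab == 0).any() and next_id > 1:
        for i in np.flatnonzero(lab == 0):
            best, best_d = 0, np.inf
            for c in range(1, next_id):
                members = np.flatnonzero(lab == c)
                md = d[i, members].mean()
                if md < best_d:
                    best, best_d = c, md
            if best_d < cut:
                lab[i] = best
    # relabel by descending size (stable: ties broken by old id)
    counts = pd.Series(lab[lab > 0]).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    lab = np.array([remap.get(v, 0) for v in lab])
    labels = pd.Series(lab, index=ids, name="group")
    return CoexpressionGroups(labels, tree, cut, min_size, deep_split)


def enrichment_test(groups: CoexpressionGroups | pd.Series,
                    annotation: pd.DataFrame,
                    background=None, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact overrepresentation test per (group, term).

    ``annotation`` is a two-column (term, gene) table.  The background
    defaults to all transcripts carrying a group label.  p-values are
    Bonferroni-adjusted across all tests and complemented with BH q-values;
    a pair is significant iff adjusted p <= alpha and q <= alpha.
    """
    labels = groups.labels if isinstance(groups, CoexpressionGroups) \
        else groups
    if background is None:
        background = labels.index
    background = pd.Index(background)
    if len(background) == 0:
        raise ValueError("empty background")
    ann = annotation[annotation["gene"].isin(background)]
    term_sets = {t: set(g) for t, g in ann.groupby("term")["gene"]}
    n_bg = len(background)
    rows = []
    for gid in sorted(labels[labels > 0].unique()):
        members = set(labels.index[labels == gid]) & set(background)
        for term, tg in term_sets.items():
            a = len(members & tg)
            b = len(members) - a
            c = len(tg) - a
            dd = n_bg - a - b - c
            _, p = fisher_exact([[a, b], [c, dd]], alternative="greater")
            odds = (a * dd) / (b * c) if b * c > 0 else np.inf
            rows.append({"group": gid, "term": term, "n_overlap": a,
                         "n_group": a + b, "n_term": a + c,
                         "n_background": n_bg, "odds_ratio": odds,
                         "p_value": p})
    res = pd.DataFrame(rows)
    if len(res):
        res["p_bonferroni"] = np.minimum(res["p_value"] * len(res), 1.0)
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res["significant"] = (res["p_bonferroni"] <= alpha) \
            & (res["q_value"] <= alpha)
    return res


def randomized_control(groups: CoexpressionGroups | pd.Series,
                       n_datasets: int = 5, seed: int = 0) -> list:
    """Size-preserving shuffles of the group assignment (negative control
    for the enrichment rates)."""
    labels = groups.labels if isinstance(groups, CoexpressionGroups) \
        else groups
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        perm = rng.permutation(labels.to_numpy())
        out.append(pd.Series(perm, index=labels.index, name="group"))
    return out
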