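"""NMF deconvolution of dissected-region transcriptomes.

The normalized (max-1 per gene, linear scale) expression matrix X of the
selected high-variation genes is factorized as X ~ W H with W >= 0 the
gene x tissue component matrix and H >= 0 the tissue x sample mixing
matrix.  The rank is chosen by a stability scan: the NMF is run from many
random initializations and the pooled mixing-matrix rows are clustered; the
rank is robust when exactly `rank` tight clusters appear, each containing
one row per run.  The reported decomposition is the elementwise median of
aligned W and H over many runs (components matched across runs by Hungarian
assignment on mixing-row correlation).  Finally the component matrix is
extended to all genes by solving the linear system W_full H = X_full per
gene in least squares and clipping negatives to zero.

Each individual factorization is delegated to scikit-learn's NMF
(multiplicative updates, Frobenius loss, tol 1e-6, max 2000 iterations);
the stability scan, alignment, median aggregation and all-gene extension
are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF


def normalize_max1(expr, genes=None) -> pd.DataFrame:
    """Back-transform log2 expression to linear scale and rescale each gene
    so its row maximum is 1.  All-zero rows are left as zeros and flagged."""
    if genes is not None:
        expr = expr.subset_genes(genes)
    lin = expr.linear()
    mx = lin.max(axis=1)
    zero = mx == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero gene(s) left unscaled")
        mx = mx.replace(0, 1.0)
    return lin.div(mx, axis=0)


def _run_nmf(x: np.ndarray, rank: int, seed: int, max_iter: int = 2000,
             tol: float = 1e-6):
    model = NMF(n_components=rank, init="random", solver="mu",
                beta_loss="frobenius", tol=tol, max_iter=max_iter,
                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings handled below
        w = model.fit_transform(x)
    return w, model.components_, model.n_iter_, model.reconstruction_err_


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between rows of a and rows of b."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1)
    bn = np.linalg.norm(bz, axis=1)
    an[an == 0] = 1.0
    bn[bn == 0] = 1.0
    return (az / an[:, None]) @ (bz / bn[:, None]).T


@dataclass
class RankScanReport:
    table: pd.DataFrame   # rank, n_tight_clusters, tightness, robust
    n_init: int
    tight_corr: float

    def robust_ranks(self) -> list:
        return self.table.loc[self.table["robust"], "rank"].tolist()


def nmf_rank_scan(norm: pd.DataFrame, ranks, n_init: int = 20,
                  seed: int = 0, tight_corr: float = 0.95) -> RankScanReport:
    """Stability scan over candidate ranks.

    For each rank, ``n_init`` NMF fits from random non-negative
    initializations are computed; all mixing-matrix rows are pooled and
    hierarchically clustered (average linkage, correlation distance, cut at
    ``rank`` clusters).  The rank is robust when every cluster is tight
    (within-cluster mean pairwise correlation >= ``tight_corr``) and
    contains exactly one row per run.
    """
    x = norm.to_numpy()
    max_rank = min(x.shape)
    rows = []
    ss = np.random.SeedSequence(seed)
    for rank in ranks:
        if rank < 2 or rank > max_rank:
            raise ValueError(f"rank {rank} outside [2, {max_rank}]")
        child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                       for s in ss.spawn(n_init)]
        hs, run_of_row = [], []
        for run, s in enumerate(child_seeds):
            _, h, _, _ = _run_nmf(x, rank, s)
            keep = h.sum(axis=1) > 0
            hs.append(h[keep])
            run_of_row.extend([run] * int(keep.sum()))
        pooled = np.vstack(hs)
        run_of_row = np.asarray(run_of_row)
        corr = np.clip(_row_corr(pooled, pooled), -1, 1)
        dist = 1.0 - corr
        tree = linkage(dist[np.triu_indices_from(dist, k=1)],
                       method="average")
        labels = fcluster(tree, t=rank, criterion="maxclust")
        n_tight = 0
        tightness = []
        one_per_run = True
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            runs, cnt = np.unique(run_of_row[members], return_counts=True)
            ok_runs = len(runs) == n_init and (cnt == 1).all()
            sub = corr[np.ix_(members, members)]
            mean_corr = sub[np.triu_indices_from(sub, k=1)].mean() \
                if len(members) > 1 else 1.0
            tightness.append(mean_corr)
            if ok_runs and mean_corr >= tight_corr:
                n_tight += 1
            one_per_run &= ok_runs
        robust = (n_tight == rank) and one_per_run
        rows.append({"rank": rank, "n_tight_clusters": n_tight,
                     "tightness": float(np.mean(tightness)),
                     "robust": robust})
    return RankScanReport(pd.DataFrame(rows), n_init, tight_corr)


@dataclass
class NMFDecomposition:
    W: pd.DataFrame          # genes x tissues
    H: pd.DataFrame          # tissues x samples
    rank: int
    n_runs: int
    seed: int
    convergence: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.W.to_numpy() < 0).any() or (self.H.to_numpy() < 0).any():
            raise ValueError("W and H must be non-negative")
        if self.rank < 2:
            raise ValueError("rank must be >= 2")

    def reconstruction(self) -> pd.DataFrame:
        return pd.DataFrame(self.W.to_numpy() @ self.H.to_numpy(),
                            index=self.W.index, columns=self.H.columns)


def nmf_fit_median(norm: pd.DataFrame, rank: int, n_runs: int = 100,
                   seed: int = 0, max_unalignable: float = 0.2,
                   min_match_corr: float = 0.5) -> NMFDecomposition:
    """Median decomposition over ``n_runs`` random initializations.

    The run with the lowest reconstruction error is the alignment reference;
    every other run's components are matched to it by Hungarian assignment
    on the Pearson correlation of mixing-matrix rows, then W and H are
    aggregated by elementwise median.  If more than ``max_unalignable`` of
    the runs contain a component whose best match correlates below
    ``min_match_corr``, the rank is judged unstable and an error advises
    choosing a different rank.
    """
    x = norm.to_numpy()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_runs)]
    ws, hs, conv = [], [], []
    for run, s in enumerate(child_seeds):
        w, h, n_iter, err = _run_nmf(x, rank, s)
        ws.append(w)
        hs.append(h)
        conv.append({"run": run, "seed": s, "n_iter": n_iter,
                     "reconstruction_error": err})
    conv = pd.DataFrame(conv)
    ref = int(conv["reconstruction_error"].idxmin())
    h_ref = hs[ref]
    aligned_w, aligned_h = [], []
    n_bad = 0
    for w, h in zip(ws, hs):
        corr = _row_corr(h, h_ref)
        ri, ci = linear_sum_assignment(-corr)
        order = np.empty(rank, dtype=int)
        order[ci] = ri
        matched = corr[ri, ci]
        if matched.min() < min_match_corr:
            n_bad += 1
        w_o, h_o = w[:, order], h[order]
        # fix the per-component scale indeterminacy (W c, H / c) before
        # taking medians: H rows to unit norm, scale pushed into W
        scale = np.linalg.norm(h_o, axis=1)
        scale[scale == 0] = 1.0
        aligned_w.append(w_o * scale[None, :])
        aligned_h.append(h_o / scale[:, None])
    if n_bad > max_unalignable * n_runs:
        raise ValueError(
            f"{n_bad}/{n_runs} runs could not be aligned to the reference "
            f"(component correlation < {min_match_corr}); the factorization "
            "is not stable at this rank - try a different rank")
    w_med = np.median(np.stack(aligned_w), axis=0)
    h_med = np.median(np.stack(aligned_h), axis=0)
    tissues = [f"NMF{i + 1}" for i in range(rank)]
    return NMFDecomposition(
        W=pd.DataFrame(w_med, index=norm.index, columns=tissues),
        H=pd.DataFrame(h_med, index=tissues, columns=norm.columns),
        rank=rank, n_runs=n_runs, seed=seed, convergence=conv)


def extend_components(full_linear: pd.DataFrame, H: pd.DataFrame
                      ) -> pd.DataFrame:
    """Extend NMF-tissue expression to all genes.

    Solves w H = x per gene in least squares with the mixing matrix fixed,
    then clips negative entries to zero.  ``full_linear`` must be on the
    same (linear) scale as the matrix the NMF was fitted on.
    """
    h = H.to_numpy()
    if np.linalg.matrix_rank(h) < h.shape[0]:
        raise np.linalg.LinAlgError("mixing matrix H is rank-deficient")
    x = full_linear[H.columns].to_numpy()
    # W = X H^T (H H^T)^-1   (all genes at once)
    w, *_ = np.linalg.lstsq(h.T, x.T, rcond=None)
    w = np.clip(w.T, 0.0, None)
    return pd.DataFrame(w, index=full_linear.index, columns=H.index)


def extension_deviation(W_full: pd.DataFrame, decomposition: NMFDecomposition,
                        norm: pd.DataFrame) -> pd.Series:
    """Per-gene max deviation between extended and fitted component values,
    as a percentage of that gene's highest expression in the fitted matrix."""
    genes = decomposition.W.index
    fitted = decomposition.W.to_numpy()
    ext = W_full.loc[genes].to_numpy()
    peak = norm.loc[genes].to_numpy().max(axis=1)
    peak[peak == 0] = 1.0
    dev = np.abs(ext - fitted).max(axis=1) / peak * 100.0
    return pd.Series(dev, index=genes, name="deviation_pct")


def nmf_pattern(W_full: pd.DataFrame, gene: str) -> pd.Series:
    """NMF-tissue levels of one gene rescaled to percent of its maximum
    tissue (0-100); an all-zero gene keeps an all-zero pattern."""
    if gene not in W_full.index:
        raise KeyError(f"unknown gene {gene!r}")
    row = W_full.loc[gene]
    mx = row.max()
    if mx == 0:
        return row * 0.0
    return (row / mx) * 100.0


def average_pattern(expr, gene: str) -> pd.DataFrame:
    """Mean linear expression of one gene per dissected region, with the
    same percent-of-max rescaling as the NMF pattern."""
    if gene not in expr.genes:
        raise KeyError(f"unknown gene {gene!r}")
    sub = expr.dissected()
    lin = 2.0 ** sub.values.loc[gene]
    mean = lin.groupby(sub.sample_meta["region"]).mean()
    mx = mean.max()
    pct = mean * 0.0 if mx == 0 else (mean / mx) * 100.0
    return pd.DataFrame({"mean_expression": mean, "percent_of_max": pct})


def plot_pattern(pattern: pd.Series, ax=None, title: str = ""):
    """Render a pattern on a white-to-blue scale (0 -> white, 100 -> blue)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("wb", ["white", "#08519c"])
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(pattern), 1.6))
    ax.imshow(pattern.to_numpy()[None, :], cmap=cmap, vmin=0, vmax=100,
              aspect="auto")
    ax.set_xticks(range(len(pattern)), pattern.index, rotation=45,
                  ha="right")
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    return ax
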