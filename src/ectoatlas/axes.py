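"""Positional decoding of dissected-sample transcriptomes by PCA.

High-variation genes are selected per stage by the range of their log2
expression (minimum range 5 by default, with variance and IQR as alternative
ranking statistics, compared through silhouette curves).  PCA is computed on
gene-standardized data and calibrated against a permutation null: each
gene's values are permuted independently across samples, the eigenvalue
spectrum of the scrambled data is recomputed many times (10,000 by default),
and a per-rank empirical p-value plus a per-gene loading significance band
are derived.  Components can then be read as embryonic axes; samples are
positioned by projection, and dissected regions summarized by barycenters
with a Voronoi tessellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, QhullError

VARIABILITY_METHODS = ("range", "var", "iqr")


def _variability(values: np.ndarray, method: str) -> np.ndarray:
    if method == "range":
        return values.max(axis=1) - values.min(axis=1)
    if method == "var":
        return values.var(axis=1, ddof=1)
    if method == "iqr":
        q75 = np.quantile(values, 0.75, axis=1)
        q25 = np.quantile(values, 0.25, axis=1)
        return q75 - q25
    raise ValueError(f"unknown variability method {method!r}; "
                     f"choose one of {VARIABILITY_METHODS}")


def rank_gene_variability(expr, method: str = "range") -> pd.Series:
    """Genes sorted by descending variability statistic across samples."""
    if expr.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to rank variability")
    stat = _variability(expr.values.to_numpy(), method)
    s = pd.Series(stat, index=expr.genes, name=method)
    return s.sort_values(ascending=False, kind="stable")


@dataclass
class GeneSelection:
    method: str
    threshold: float
    per_stage: dict                      # stage -> list of gene ids
    union: list
    silhouette_curve: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        want = set()
        for genes in self.per_stage.values():
            want |= set(genes)
        if set(self.union) != want:
            raise ValueError("union must be the set-union of per-stage lists")


def select_genes(expr, threshold: float = 5.0,
                 method: str = "range") -> GeneSelection:
    """Per-stage selection of genes whose log2-expression range (or other
    statistic) reaches ``threshold`` within that stage's samples."""
    stages = expr.sample_meta["stage"]
    per_stage = {}
    order = []
    for stage in pd.unique(stages):
        cols = expr.samples[stages.to_numpy() == stage]
        stat = _variability(expr.values[cols].to_numpy(), method)
        sel = expr.genes[stat >= threshold].tolist()
        per_stage[stage] = sel
        order.extend(g for g in sel if g not in order)
    return GeneSelection(method=method, threshold=threshold,
                         per_stage=per_stage, union=order)


def _standardize(values: np.ndarray):
    """Center/scale each gene (row) across samples; drops ddof-1 sd."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mean) / sd, mean.ravel(), sd.ravel()


def _eigs_and_loadings(z: np.ndarray, n_samples: int):
    """SVD of standardized data (genes x samples); returns scores (samples x
    c), loadings (genes x c), eigenvalues."""
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    eig = s ** 2 / (n_samples - 1)
    scores = u * s
    loadings = vt.T
    return scores, loadings, eig


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    eig_significance: np.ndarray
    loading_significance: pd.DataFrame
    n_permutations: int
    alpha: float
    significant_components: np.ndarray = None
    gene_means: pd.Series = field(repr=False, default=None)
    gene_sds: pd.Series = field(repr=False, default=None)


def pca_with_null(expr, n_permutations: int = 10_000, alpha: float = 0.01,
                  seed: int | None = None,
                  loading_perm_cap: int = 1000) -> PCAResult:
    """Standardized PCA with permutation-calibrated significance.

    Each gene is centered and scaled across samples; the null is built by
    permuting every gene's values independently across samples and
    recomputing the eigenvalue spectrum.  The p-value of eigenvalue rank
    ``i`` is the (add-one) fraction of permutations whose rank-``i``
    eigenvalue is at least as large; a gene's loading on a component is
    flagged significant when it falls outside the two-sided empirical
    alpha-band of the pooled null loadings of that rank.
    """
    if expr.values.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives unstable p-values")
    vals = expr.values.to_numpy().astype(float)
    sd = vals.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant gene(s) before PCA")
        vals = vals[~const]
    genes = expr.genes[~const]
    n_genes, n_samples = vals.shape
    z, mean, sdev = _standardize(vals)
    scores, loadings, eig = _eigs_and_loadings(z, n_samples)
    n_comp = len(eig)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_comp)
    n_load = min(n_permutations, loading_perm_cap)
    null_loads = np.empty((n_load, n_comp, 2))  # per-perm quantiles
    for p in range(n_permutations):
        zp = z.copy()
        # permute each gene independently across samples
        idx = np.argsort(rng.random((n_genes, n_samples)), axis=1)
        zp = np.take_along_axis(zp, idx, axis=1)
        if p < n_load:
            _, lperm, eperm = _eigs_and_loadings(zp, n_samples)
            null_loads[p, :, 0] = np.quantile(lperm, alpha / 2, axis=0)
            null_loads[p, :, 1] = np.quantile(lperm, 1 - alpha / 2, axis=0)
        else:
            eperm = np.linalg.svd(zp.T, compute_uv=False) ** 2 \
                / (n_samples - 1)
        exceed += eperm[:n_comp] >= eig
    p_eig = (1.0 + exceed) / (1.0 + n_permutations)
    # sequential rule: a component is significant only while every
    # earlier-rank component is too, so the familywise null rate stays ~alpha
    sig_comp = np.cumprod(p_eig <= alpha).astype(bool)
    lo_band = null_loads[:, :, 0].mean(axis=0)
    hi_band = null_loads[:, :, 1].mean(axis=0)
    sig_load = (loadings < lo_band[None, :]) | (loadings > hi_band[None, :])

    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=genes, columns=comp_names),
        eigenvalues=eig,
        percent_variance=100.0 * eig / eig.sum(),
        eig_significance=p_eig,
        loading_significance=pd.DataFrame(sig_load, index=genes,
                                          columns=comp_names),
        n_permutations=n_permutations, alpha=alpha,
        significant_components=sig_comp,
        gene_means=pd.Series(mean, index=genes),
        gene_sds=pd.Series(sdev, index=genes))


def silhouette_curve(expr, labels: pd.Series, gene_counts,
                     method: str = "range", n_components: int = 3
                     ) -> pd.DataFrame:
    """Mean silhouette of region labels in 3-component PCA score space, for
    each candidate number of top-variability genes."""
    from sklearn.metrics import silhouette_score

    labels = labels.loc[expr.samples]
    classes = labels.value_counts()
    if len(classes) < 2 or (classes < 2).any():
        raise ValueError("need >= 2 label classes with >= 2 samples each")
    ranked = rank_gene_variability(expr, method)
    rows = []
    for n in gene_counts:
        if n > len(ranked):
            warnings.warn(f"requested {n} genes, only {len(ranked)} "
                          "available; truncating")
            n = len(ranked)
        top = ranked.index[:n]
        vals = expr.values.loc[top].to_numpy()
        vals = vals[vals.std(axis=1, ddof=1) > 0]
        z, _, _ = _standardize(vals)
        scores, _, _ = _eigs_and_loadings(z, z.shape[1])
        k = min(n_components, scores.shape[1])
        sil = silhouette_score(scores[:, :k], labels.to_numpy(),
                               metric="euclidean")
        rows.append({"n_genes": n, "silhouette": sil})
    return pd.DataFrame(rows)


def correlate_genes_to_component(expr, component_scores: pd.Series,
                                 top_n: int = 60):
    """Pearson correlation of every gene with one component's scores.

    Returns (all correlations sorted descending, top positive, top
    negative); zero-variance genes are excluded with a note.
    """
    s = component_scores.loc[expr.samples].to_numpy().astype(float)
    vals = expr.values.to_numpy().astype(float)
    sd = vals.std(axis=1)
    ok = sd > 0
    if (~ok).any():
        warnings.warn(f"{(~ok).sum()} zero-variance gene(s) excluded from "
                      "component correlation")
    zc = (vals[ok] - vals[ok].mean(axis=1, keepdims=True)) \
        / sd[ok][:, None]
    zs = (s - s.mean()) / s.std()
    r = zc @ zs / len(s)
    corr = pd.Series(r, index=expr.genes[ok], name="pearson_r")
    corr = corr.sort_values(ascending=False, kind="stable")
    return corr, corr.head(top_n), corr.tail(top_n)[::-1]


def project_sample(pca: PCAResult, new_expr: pd.Series | pd.DataFrame
                   ) -> pd.DataFrame:
    """Project new expression profiles onto stored components using the
    training means/sds: coordinates = standardized vector x loadings."""
    if isinstance(new_expr, pd.Series):
        new_expr = new_expr.to_frame().T
    missing = pca.loadings.index.difference(new_expr.columns)
    if len(missing):
        raise ValueError(f"missing genes: {list(missing[:10])}"
                         + ("..." if len(missing) > 10 else ""))
    x = new_expr[pca.loadings.index].to_numpy().astype(float)
    z = (x - pca.gene_means.to_numpy()) / pca.gene_sds.to_numpy()
    coords = z @ pca.loadings.to_numpy()
    return pd.DataFrame(coords, index=new_expr.index,
                        columns=pca.loadings.columns)


@dataclass
class RegionLayout:
    barycenters: pd.DataFrame          # region x 2 coordinates
    assignment: pd.Series              # sample -> nearest-barycenter region
    voronoi: object | None
    degenerate: bool
    own_cell_fraction: float


def region_layout(scores: pd.DataFrame, labels: pd.Series) -> RegionLayout:
    """Barycenter per region and Voronoi tessellation in a 2-D score plane;
    each sample is assigned to the cell of its nearest barycenter."""
    labels = labels.loc[scores.index]
    pts = scores.iloc[:, :2]
    bary = pts.groupby(labels).mean()
    d = ((pts.to_numpy()[:, None, :] - bary.to_numpy()[None, :, :]) ** 2
         ).sum(axis=2)
    nearest = bary.index[np.argmin(d, axis=1)]
    assignment = pd.Series(nearest, index=scores.index, name="region")
    vor, degenerate = None, False
    if len(bary) >= 3:
        try:
            vor = Voronoi(bary.to_numpy())
        except QhullError:
            degenerate = True
            warnings.warn("collinear barycenters: degenerate tessellation")
    own = float((assignment.to_numpy() == labels.to_numpy()).mean())
    return RegionLayout(bary, assignment, vor, degenerate, own)


def embed_tsne(expr, perplexity: float = 7.0, seed: int = 0) -> pd.DataFrame:
    """2-D tSNE embedding of standardized expression (library-wrapped)."""
    from sklearn.manifold import TSNE

    vals = expr.values.to_numpy().astype(float)
    vals = vals[vals.std(axis=1, ddof=1) > 0]
    z, _, _ = _standardize(vals)
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(z.T)
    return pd.DataFrame(emb, index=expr.samples, columns=["tsne1", "tsne2"])
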