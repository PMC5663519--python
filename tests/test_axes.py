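"""Gene selection, permutation-calibrated PCA and sample positioning."""

import numpy as np
import pandas as pd
import pytest

from ectoatlas import axes
from conftest import make_expression


@pytest.fixture(scope="module")
def selected_pca(small_expr):
    diss = small_expr.dissected()
    sel = axes.select_genes(diss, threshold=5.0)
    pca = axes.pca_with_null(diss.subset_genes(sel.union),
                             n_permutations=300, seed=1)
    return diss, sel, pca


class TestVariabilityRanking:
    def test_constant_gene_last_and_range_values(self):
        vals = np.array([[0, 1, 2, 3, 4, 5],        # range 5
                         [2, 2, 2, 2, 2, 2],        # constant, range 0
                         [0, 0, 0, 0, 0, 7]])       # range 7
        expr = make_expression(vals)
        ranked = axes.rank_gene_variability(expr, "range")
        assert list(ranked.index) == ["g2", "g0", "g1"]
        assert ranked["g0"] == 5.0
        assert ranked["g1"] == 0.0

    def test_toy_ordering_matches_independent_sort(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (20, 8))
        expr = make_expression(vals)
        for method, stat in [
            ("range", vals.max(1) - vals.min(1)),
            ("var", vals.var(1, ddof=1)),
            ("iqr", np.quantile(vals, .75, axis=1)
                - np.quantile(vals, .25, axis=1)),
        ]:
            ranked = axes.rank_gene_variability(expr, method)
            oracle = [f"g{i}" for i in np.argsort(-stat, kind="stable")]
            assert list(ranked.index) == oracle

    def test_unknown_method_raises(self):
        expr = make_expression(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="unknown"):
            axes.rank_gene_variability(expr, "mad")


class TestSelectGenes:
    def test_boundary_range_exactly_at_threshold_is_selected(self):
        vals = np.array([[0, 5, 1, 2], [0, 4.9, 1, 2]])
        expr = make_expression(vals)
        sel = axes.select_genes(expr, threshold=5.0)
        assert sel.union == ["g0"]

    def test_infinite_threshold_empties_selection(self, small_expr):
        sel = axes.select_genes(small_expr.dissected(),
                                threshold=np.inf)
        assert sel.union == []

    def test_selection_monotone_in_threshold(self, small_expr):
        diss = small_expr.dissected()
        tight = set(axes.select_genes(diss, threshold=6.0).union)
        loose = set(axes.select_genes(diss, threshold=5.0).union)
        assert tight <= loose

    def test_strong_signature_genes_all_selected(self, small_atlas,
                                                 small_expr, small_config):
        """Ground-truth signature genes carry a fold change of 2^6 > 2^5
        and must all appear in the selection union."""
        _, truth = small_atlas
        sel = axes.select_genes(small_expr.dissected(), threshold=5.0)
        sig = truth.signature_membership.dropna()
        sig = sig.index.intersection(small_expr.genes)
        missing = set(sig) - set(sel.union)
        assert not missing


class TestPCANull:
    def test_scores_are_projection_of_standardized_data(self, selected_pca):
        diss, sel, pca = selected_pca
        vals = diss.values.loc[pca.loadings.index].to_numpy()
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1,
                                                            keepdims=True)
        recomputed = z.T @ pca.loadings.to_numpy()
        assert np.allclose(recomputed, pca.scores.to_numpy(), atol=1e-8)

    def test_variance_conservation(self, selected_pca):
        _, _, pca = selected_pca
        assert pca.eigenvalues.sum() == pytest.approx(len(pca.loadings),
                                                      rel=1e-9)
        assert pca.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(pca.eigenvalues) <= 1e-9).all()

    def test_planted_gradient_detected_and_loadings_flagged(self):
        rng = np.random.default_rng(3)
        n_genes, n_samples = 80, 30
        grad = np.linspace(-2, 2, n_samples)
        vals = rng.normal(0, 1, (n_genes, n_samples))
        vals[:10] += 4 * grad[None, :]
        expr = make_expression(vals)
        pca = axes.pca_with_null(expr, n_permutations=300, seed=4)
        assert pca.eig_significance[0] < 0.01
        assert pca.significant_components[0]
        flagged = pca.loading_significance["PC1"].to_numpy()
        assert flagged[:10].all()
        assert flagged[10:].sum() == 0

    def test_constant_genes_dropped_with_warning(self):
        vals = np.vstack([np.random.default_rng(0).normal(0, 1, (5, 8)),
                          np.ones((1, 8))])
        expr = make_expression(vals)
        with pytest.warns(UserWarning, match="constant"):
            pca = axes.pca_with_null(expr, n_permutations=100, seed=0)
        assert "g5" not in pca.loadings.index


class TestSilhouette:
    def test_separable_regions_score_near_one(self, small_expr, small_atlas):
        _, truth = small_atlas
        diss = small_expr.dissected()
        sig = truth.signature_membership.dropna().index
        sig = sig.intersection(diss.genes)
        expr = diss.subset_genes(sig)
        curve = axes.silhouette_curve(expr, diss.sample_meta["region"],
                                      [len(sig)])
        assert curve["silhouette"].iloc[0] > 0.5

    def test_permuted_labels_score_at_most_zeroish(self, small_expr):
        diss = small_expr.dissected()
        rng = np.random.default_rng(5)
        sils = []
        for _ in range(20):
            perm = pd.Series(rng.permutation(diss.sample_meta["region"]
                                             .to_numpy()),
                             index=diss.samples)
            c = axes.silhouette_curve(diss, perm, [100])
            sils.append(c["silhouette"].iloc[0])
        assert np.mean(sils) <= 0.05

    def test_noise_genes_degrade_silhouette(self, small_expr):
        """Adding genes ranked below the informative ones monotonically
        (in trend) drags the silhouette down."""
        diss = small_expr.dissected()
        counts = [40, 100, 200, 400, len(diss.genes)]
        curve = axes.silhouette_curve(diss, diss.sample_meta["region"],
                                      counts)
        s = curve["silhouette"].to_numpy()
        assert s[0] > s[-1]
        assert np.polyfit(np.log(counts), s, 1)[0] < 0


class TestProjection:
    def test_training_sample_projects_to_stored_scores(self, selected_pca):
        diss, _, pca = selected_pca
        sample = diss.samples[3]
        prof = diss.values.loc[pca.loadings.index, sample]
        coords = axes.project_sample(pca, prof.rename(sample))
        assert np.allclose(coords.to_numpy()[0],
                           pca.scores.loc[sample].to_numpy(), atol=1e-8)

    def test_mean_profile_projects_to_origin(self, selected_pca):
        _, _, pca = selected_pca
        coords = axes.project_sample(pca, pca.gene_means.rename("mean"))
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-8)

    def test_projection_is_linear_between_mixtures(self, selected_pca):
        diss, _, pca = selected_pca
        a = diss.values.loc[pca.loadings.index, diss.samples[0]]
        b = diss.values.loc[pca.loadings.index, diss.samples[-1]]
        mix = (0.5 * a + 0.5 * b).rename("mix")
        ca = axes.project_sample(pca, a.rename("a")).to_numpy()
        cb = axes.project_sample(pca, b.rename("b")).to_numpy()
        cm = axes.project_sample(pca, mix).to_numpy()
        assert np.allclose(cm, 0.5 * (ca + cb), atol=1e-8)

    def test_missing_genes_raise(self, selected_pca):
        _, _, pca = selected_pca
        short = pd.Series(0.0, index=pca.loadings.index[:-3], name="x")
        with pytest.raises(ValueError, match="missing genes"):
            axes.project_sample(pca, short)


class TestRegionLayout:
    def test_sample_at_barycenter_assigned_to_it(self):
        scores = pd.DataFrame({"PC1": [0, 0, 10, 10, 5],
                               "PC2": [0, 2, 0, 2, 10.0]},
                              index=list("abcde"))
        labels = pd.Series(["L", "L", "R", "R", "T"], index=scores.index)
        layout = axes.region_layout(scores, labels)
        assert layout.assignment["a"] == "L"
        assert layout.assignment["c"] == "R"
        assert not layout.degenerate

    def test_two_barycenters_split_by_perpendicular_bisector(self):
        scores = pd.DataFrame({"PC1": [0.0, 0, 10, 10, 4.9, 5.1],
                               "PC2": [0.0, 0, 0, 0, 0, 0]},
                              index=list("abcdef"))
        labels = pd.Series(["L", "L", "R", "R", "L", "R"],
                           index=scores.index)
        layout = axes.region_layout(scores, labels)
        # barycenters at x=0 and x=10; bisector at x=5
        assert layout.assignment["e"] == "L"
        assert layout.assignment["f"] == "R"

    def test_collinear_barycenters_flagged_degenerate(self):
        scores = pd.DataFrame({"PC1": [0, 0, 5, 5, 10, 10.0],
                               "PC2": [0.0, 0, 0, 0, 0, 0]},
                              index=list("abcdef"))
        labels = pd.Series(["A", "A", "B", "B", "C", "C"],
                           index=scores.index)
        with pytest.warns(UserWarning, match="degenerate"):
            layout = axes.region_layout(scores, labels)
        assert layout.degenerate

    def test_true_labels_beat_shuffled_labels(self, selected_pca):
        diss, _, pca = selected_pca
        labels = diss.sample_meta["region"]
        real = axes.region_layout(pca.scores, labels).own_cell_fraction
        rng = np.random.default_rng(6)
        shuffled = []
        for _ in range(20):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            shuffled.append(
                axes.region_layout(pca.scores, perm).own_cell_fraction)
        assert real >= np.mean(shuffled)


def test_component_correlation_endpoints(selected_pca):
    diss, _, pca = selected_pca
    score1 = pca.scores["PC1"]
    vals = diss.values.copy()
    vals.loc["synthetic_pos"] = score1.to_numpy()
    vals.loc["synthetic_neg"] = -score1.to_numpy()
    expr = make_expression(vals.to_numpy())
    expr.values.index = vals.index
    expr.values.columns = diss.samples
    corr, top_pos, top_neg = axes.correlate_genes_to_component(expr, score1)
    assert corr["synthetic_pos"] == pytest.approx(1.0)
    assert corr["synthetic_neg"] == pytest.approx(-1.0)
    assert corr.index[0] == "synthetic_pos"
    assert top_neg.index[0] == "synthetic_neg"
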