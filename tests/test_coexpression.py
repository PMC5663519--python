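"""Adjacency, TOM, dynamic-cut clustering and Fisher enrichment oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from ectoatlas import coexpression as coex


def planted_blocks(sizes, n_noise, n_samples=30, within_sd=0.3, seed=0):
    """Correlated transcript blocks plus independent noise transcripts."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b, s in enumerate(sizes, start=1):
        base = rng.normal(0, 1, n_samples)
        for _ in range(s):
            rows.append(base + rng.normal(0, within_sd, n_samples))
            truth.append(b)
    for _ in range(n_noise):
        rows.append(rng.normal(0, 1, n_samples))
        truth.append(0)
    x = pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))])
    return x, np.array(truth)


def bicor_oracle(x, y):
    """Direct scalar evaluation of the biweight midcorrelation formula."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestFilter:
    @pytest.mark.parametrize("values, kept", [
        ([51.0] + [0.0] * 78, True),      # one sample above 50 CPM
        ([0.6] * 79, True),               # sum 47.4 > 40
        ([0.4] * 79, False),              # max 0.4, sum 31.6
    ])
    def test_disjuncts(self, values, kept):
        cpm = pd.DataFrame([values], index=["t0"])
        out = coex.wgcna_filter(cpm)
        assert ("t0" in out.index) is kept


class TestBicorAdjacency:
    def test_matches_direct_formula_on_toy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (5, 12))
        c = coex.bicor(x)
        for i in range(5):
            for j in range(i + 1, 5):
                assert c[i, j] == pytest.approx(bicor_oracle(x[i], x[j]),
                                                abs=1e-10)
        a = coex.signed_adjacency(x, power=22)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else \
                    ((1 + bicor_oracle(x[i], x[j])) / 2) ** 22
                assert a[i, j] == pytest.approx(expected, abs=1e-10)

    def test_self_and_anticorrelated_limits(self):
        v = np.arange(10.0)
        x = np.vstack([v, -v])
        a = coex.signed_adjacency(x, power=22)
        assert a[0, 0] == 1.0
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)
        u = coex.unsigned_adjacency(x, power=22)
        assert u[0, 1] == pytest.approx(1.0)

    def test_zero_mad_transcript_falls_back_to_pearson(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, 11),
                       np.r_[np.zeros(10), 5.0]])  # MAD 0, variance > 0
        c = coex.bicor(x)
        assert np.isfinite(c).all()
        assert abs(c[0, 1]) <= 1.0


class TestScaleFree:
    def test_perfect_correlation_power_one_connectivity(self):
        base = np.arange(12.0)
        x = np.vstack([base * s for s in np.linspace(1, 3, 25)])
        res = coex.scale_free_fit(x, [1.0])
        assert res["mean_connectivity"].iloc[0] == pytest.approx(24.0,
                                                                 rel=1e-6)

    def test_mean_connectivity_nonincreasing_in_power(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (30, 15))
        res = coex.scale_free_fit(x, [2, 6, 12, 22])
        k = res["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 1e-12).all()

    def test_r2_matches_direct_binned_regression(self):
        from scipy.stats import linregress

        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (40, 20))
        res = coex.scale_free_fit(x, [6], n_bins=8)
        a = coex.signed_adjacency(x, power=6)
        k = a.sum(axis=0) - 1
        k = k[k > 0]
        edges = np.linspace(k.min(), k.max() + 1e-12, 9)
        which = np.clip(np.digitize(k, edges) - 1, 0, 7)
        xs = [np.log10(k[which == b].mean()) for b in range(8)
              if (which == b).any()]
        ys = [np.log10((which == b).mean()) for b in range(8)
              if (which == b).any()]
        fit = linregress(xs, ys)
        assert res["r_squared"].iloc[0] == pytest.approx(fit.rvalue ** 2,
                                                         abs=1e-10)


class TestTOM:
    def test_pair_connected_only_to_each_other(self):
        a = np.array([[0.0, 1.0, 0], [1.0, 0, 0], [0, 0, 0.0]])
        np.fill_diagonal(a, 1.0)
        tom = coex.topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 2] == pytest.approx(0.0)
        assert tom[2, 1] == pytest.approx(0.0)

    def test_toy_matches_brute_force(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = coex.topological_overlap(a)
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a0[i, u] * a0[u, j] for u in range(6))
                ki = a0[i].sum()
                kj = a0[j].sum()
                expected = (shared + a0[i, j]) \
                    / (min(ki, kj) + 1 - a0[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            coex.topological_overlap(a)


@pytest.fixture(scope="module")
def blocks():
    x, truth = planted_blocks([30, 30, 30], n_noise=60, seed=9)
    adj = coex.signed_adjacency(x, power=22)
    tom = coex.topological_overlap(adj)
    d = pd.DataFrame(1 - tom, index=x.index, columns=x.index)
    return d, truth


class TestClusterGroups:
    def test_planted_partition_recovered(self, blocks):
        from sklearn.metrics import adjusted_rand_score

        d, truth = blocks
        groups = coex.cluster_groups(d)
        planted = truth > 0
        ari = adjusted_rand_score(truth[planted],
                                  groups.labels.to_numpy()[planted])
        assert ari >= 0.9

    def test_small_block_dissolved_to_group_zero(self):
        x, truth = planted_blocks([14, 30], n_noise=40, seed=10)
        adj = coex.signed_adjacency(x, power=22)
        tom = coex.topological_overlap(adj)
        groups = coex.cluster_groups(
            pd.DataFrame(1 - tom, index=x.index, columns=x.index))
        small = groups.labels.to_numpy()[truth == 1]
        assert (small == 0).all()
        assert groups.sizes().min() >= 15

    def test_group_one_is_largest_and_ids_contiguous(self, blocks):
        d, _ = blocks
        groups = coex.cluster_groups(d)
        sizes = groups.sizes()
        assert sizes.loc[1] == sizes.max()
        assert list(sizes.index) == list(range(1, len(sizes) + 1))

    def test_fewer_transcripts_than_min_size(self):
        d = pd.DataFrame(np.zeros((5, 5)))
        groups = coex.cluster_groups(d, min_size=15)
        assert (groups.labels == 0).all()


def hypergeom_tail_exact(a, b, c, d):
    """One-sided Fisher p by direct hypergeometric summation with exact
    rational arithmetic."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    p = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        p += Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    return float(p)


class TestEnrichment:
    def test_reference_table_matches_hypergeometric_summation(self):
        genes = [f"g{i}" for i in range(1000)]
        labels = pd.Series(0, index=genes)
        labels[genes[:20]] = 1                       # group of 20
        term_genes = genes[:10] + genes[20:60]       # 10 overlap, 40 outside
        ann = pd.DataFrame({"term": "T", "gene": term_genes})
        res = coex.enrichment_test(labels, ann)
        row = res.iloc[0]
        assert (row["n_overlap"], row["n_group"], row["n_term"]) \
            == (10, 20, 50)
        assert row["p_value"] == pytest.approx(
            hypergeom_tail_exact(10, 10, 40, 940), rel=1e-10)

    def test_zero_overlap_not_enriched(self):
        genes = [f"g{i}" for i in range(100)]
        labels = pd.Series(0, index=genes)
        labels[genes[:10]] = 1
        ann = pd.DataFrame({"term": "T", "gene": genes[50:70]})
        res = coex.enrichment_test(labels, ann)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0, abs=1e-9)
        assert not res.iloc[0]["significant"]

    def test_empty_background_raises(self):
        labels = pd.Series(dtype=int)
        ann = pd.DataFrame({"term": [], "gene": []})
        with pytest.raises(ValueError, match="background"):
            coex.enrichment_test(labels, ann, background=[])


class TestRandomizedControl:
    def test_sizes_preserved_and_seed_reproducible(self):
        labels = pd.Series([1] * 20 + [2] * 15 + [0] * 30,
                           index=[f"t{i}" for i in range(65)])
        c1 = coex.randomized_control(labels, n_datasets=3, seed=5)
        c2 = coex.randomized_control(labels, n_datasets=3, seed=5)
        for s1, s2 in zip(c1, c2):
            pd.testing.assert_series_equal(s1, s2)
            assert s1.value_counts().to_dict() \
                == labels.value_counts().to_dict()

    def test_real_groups_more_enriched_than_random(self, small_atlas,
                                                   small_config):
        """With annotation terms planted on the true signature sets, real
        groups built from the truth show more enriched terms than
        size-preserving random reassignments."""
        from ectoatlas.synthetic_data import generate_annotation

        _, truth = small_atlas
        ann = generate_annotation(small_config, truth, odds_ratio=12.0)
        sigm = truth.signature_membership
        labels = pd.Series(0, index=truth.prototype_matrix.index)
        for i, t in enumerate(sorted(sigm.dropna().unique()), start=1):
            labels[sigm.index[sigm == t]] = i
        real = coex.enrichment_test(labels, ann)
        n_real = real.groupby("group")["significant"].any().sum()
        rand_counts = []
        for ctrl in coex.randomized_control(labels, n_datasets=3, seed=1):
            r = coex.enrichment_test(ctrl, ann)
            rand_counts.append(r.groupby("group")["significant"].any().sum())
        assert n_real > max(rand_counts)
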