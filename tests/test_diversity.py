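import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amplistat import (FeatureTable, SampleMetadata, hill_number, hill_profile,
                       alpha_contrasts, hellinger, bray_curtis, DistanceMatrix,
                       pcoa, permanova, anosim, pairwise_beta)


class TestHillNumber:
    @pytest.mark.parametrize("q", [0, 0.5, 1, 2, 3])
    def test_uniform_community(self, q):
        assert hill_number(np.full(5, 0.2), q) == pytest.approx(5.0, abs=1e-9)

    def test_hand_values(self):
        p = np.array([0.9, 0.1])
        assert hill_number(p, 0) == 2
        assert hill_number(p, 2) == pytest.approx(1 / 0.82, abs=1e-5)
        # exp(-(0.9 ln 0.9 + 0.1 ln 0.1)) = exp(0.3250829...) by hand
        assert hill_number(p, 1) == pytest.approx(1.3841455, abs=1e-5)

    def test_q1_matches_general_form_limit(self):
        p = np.array([0.9, 0.1])
        for eps in (1e-4, -1e-4):
            assert hill_number(p, 1) == pytest.approx(
                hill_number(p, 1 + eps), abs=1e-3)
        # tighter: the limit itself
        assert abs(hill_number(p, 1 + 1e-6) - hill_number(p, 1)) < 1e-5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hill_number(np.zeros(3), 1)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=20),
           st.floats(0, 4))
    def test_profile_nonincreasing_in_q(self, weights, q):
        p = np.asarray(weights)
        assert hill_number(p, q) >= hill_number(p, q + 0.5) - 1e-9


class TestAlphaContrasts:
    def make_meta(self):
        df = pd.DataFrame({"group": ["HC"] * 3 + ["ESCC"] * 3},
                          index=[f"s{i}" for i in range(6)])
        return SampleMetadata(df)

    def test_extreme_ranking_exact_p(self):
        meta = self.make_meta()
        prof = pd.DataFrame({0: [1, 2, 3, 10, 11, 12]},
                            index=[f"s{i}" for i in range(6)])
        out = alpha_contrasts(prof, meta, q=0)
        assert out.loc[0, "p"] == pytest.approx(0.1, abs=1e-9)

    def test_identical_groups_p_one(self):
        meta = self.make_meta()
        prof = pd.DataFrame({0: [1, 2, 3, 3, 2, 1]},
                            index=[f"s{i}" for i in range(6)])
        out = alpha_contrasts(prof, meta, q=0)
        assert out.loc[0, "p"] == 1.0

    def test_symmetric_in_group_order(self):
        df = pd.DataFrame({"group": ["ESCC"] * 3 + ["HC"] * 3},
                          index=[f"s{i}" for i in range(6)])
        meta_swapped = SampleMetadata(df)
        prof = pd.DataFrame({0: [1, 2, 3, 10, 11, 12]},
                            index=[f"s{i}" for i in range(6)])
        out = alpha_contrasts(prof, meta_swapped, q=0)
        assert out.loc[0, "p"] == pytest.approx(0.1, abs=1e-9)


class TestHellinger:
    def test_hand_column(self):
        t = FeatureTable(pd.DataFrame([[1], [4]], index=["a", "b"],
                                      columns=["s"]))
        h = hellinger(t)
        assert h.data["s"].tolist() == pytest.approx([0.44721, 0.89443],
                                                     abs=1e-5)

    def test_unit_norm_columns(self, tiny_table):
        h = hellinger(tiny_table)
        norms = np.sqrt((h.data ** 2).sum(axis=0))
        assert np.allclose(norms, 1.0)

    def test_equal_column(self):
        t = FeatureTable(pd.DataFrame([[1]] * 4, index=list("abcd"),
                                      columns=["s"]))
        assert np.allclose(hellinger(t).data["s"], 0.5)


class TestBrayCurtis:
    def from_cols(self, cols):
        df = pd.DataFrame(np.array(cols).T,
                          index=[f"t{i}" for i in range(len(cols[0]))],
                          columns=[f"s{i}" for i in range(len(cols))])
        return bray_curtis(FeatureTable(df))

    def test_disjoint_supports(self):
        assert self.from_cols([[1, 0], [0, 1]]).matrix[0, 1] == 1.0

    def test_identical_samples(self):
        assert self.from_cols([[2, 3], [2, 3]]).matrix[0, 1] == 0.0

    def test_hand_value(self):
        assert self.from_cols([[2, 0], [1, 1]]).matrix[0, 1] == pytest.approx(0.5)

    def test_invariant_to_taxon_and_sample_order(self, small_cohort):
        bacteria = small_cohort[0]
        sub = bacteria.subset_samples(bacteria.sample_ids[:6])
        d1 = bray_curtis(sub)
        shuffled = FeatureTable(
            sub.data.iloc[::-1][list(reversed(sub.sample_ids))])
        d2 = bray_curtis(shuffled)
        ids = d1.sample_ids
        assert np.allclose(d1.matrix, d2.submatrix(ids).matrix)


class TestPcoa:
    def test_equilateral_round_trip(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.]]))
        res = pcoa(d, k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-9)
        from scipy.spatial.distance import pdist, squareform
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d.matrix, atol=1e-9)

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.5]])
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        res = pcoa(d, k=1)
        assert res.eigenvalues[0] > 1e-6
        assert np.all(np.abs(res.eigenvalues[1:]) < 1e-8)

    def test_euclidean_embedding_reproduces_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix([f"s{i}" for i in range(6)],
                           squareform(pdist(pts)))
        res = pcoa(d, k=3)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d.matrix, atol=1e-9)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        x = rng.random((8, 5))
        from scipy.spatial.distance import pdist, squareform
        m = squareform(pdist(x, metric="braycurtis"))
        ours = pcoa(DistanceMatrix([str(i) for i in range(8)], m), k=2)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(m))
        assert np.allclose(np.abs(ours.coordinates),
                           np.abs(theirs.samples.values[:, :2]), atol=1e-6)


class TestPermanova:
    def hand_case(self):
        # two groups of 2; all six pairwise distances equal 1
        m = np.ones((4, 4)) - np.eye(4)
        return DistanceMatrix(list("abcd"), m), np.array(["g1", "g1", "g2", "g2"])

    def test_hand_partition(self):
        d, labels = self.hand_case()
        res = permanova(d, labels, n_perm=10, seed=0)
        assert res["F"] == pytest.approx(1.0)
        assert res["R2"] == pytest.approx(1 / 3)

    def test_degenerate_all_zero(self):
        d = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        res = permanova(d, ["a", "a", "b", "b"], n_perm=10, seed=0)
        assert res["R2"] == 0.0 and res["degenerate"]

    def test_reproducible_and_valid_p(self, small_cohort):
        bacteria, _, _, meta, _ = small_cohort
        sub = bacteria.subset_samples(bacteria.sample_ids[:20])
        d = bray_curtis(hellinger(sub))
        labels = meta.labels_for(sub.sample_ids)
        r1 = permanova(d, labels, n_perm=99, seed=5)
        r2 = permanova(d, labels, n_perm=99, seed=5)
        assert r1 == r2
        assert r1["p"] >= 1 / 100

    def test_matches_skbio(self, small_cohort):
        skbio = pytest.importorskip("skbio")
        bacteria, _, _, meta, _ = small_cohort
        sub = bacteria.subset_samples(bacteria.sample_ids[:23])
        d = bray_curtis(hellinger(sub))
        labels = list(meta.labels_for(sub.sample_ids))
        ours = permanova(d, labels, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.matrix, ids=d.sample_ids), labels,
            permutations=99)
        assert ours["F"] == pytest.approx(theirs["test statistic"], abs=1e-9)


class TestAnosim:
    def test_complete_separation(self):
        # within distances all smaller than between distances
        m = np.array([[0, .1, .9, .9],
                      [.1, 0, .9, .9],
                      [.9, .9, 0, .1],
                      [.9, .9, .1, 0]])
        d = DistanceMatrix(list("abcd"), m)
        res = anosim(d, ["x", "x", "y", "y"], n_perm=10, seed=0)
        assert res["R"] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.random((8, 4))
        from scipy.spatial.distance import pdist, squareform
        m = squareform(pdist(x))
        labels = ["a"] * 4 + ["b"] * 4
        d1 = DistanceMatrix([str(i) for i in range(8)], m)
        d2 = DistanceMatrix([str(i) for i in range(8)], m ** 3)
        r1 = anosim(d1, labels, n_perm=49, seed=1)
        r2 = anosim(d2, labels, n_perm=49, seed=1)
        assert r1["R"] == pytest.approx(r2["R"], abs=1e-12)

    def test_matches_skbio(self, small_cohort):
        skbio = pytest.importorskip("skbio")
        bacteria, _, _, meta, _ = small_cohort
        sub = bacteria.subset_samples(bacteria.sample_ids[:23])
        d = bray_curtis(hellinger(sub))
        labels = list(meta.labels_for(sub.sample_ids))
        ours = anosim(d, labels, n_perm=99, seed=0)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.matrix, ids=d.sample_ids), labels,
            permutations=99)
        assert ours["R"] == pytest.approx(theirs["test statistic"], abs=1e-9)


class TestPairwiseBeta:
    def test_bh_adjustment_by_hand(self):
        from statsmodels.stats.multitest import multipletests
        raw = np.array([0.001, 0.005, 0.424])
        adj = multipletests(raw, method="fdr_bh")[1]
        assert adj == pytest.approx([0.003, 0.0075, 0.424])

    def test_family_size_and_single_pair(self, small_cohort):
        bacteria, _, _, meta, _ = small_cohort
        d = bray_curtis(hellinger(bacteria))
        out = pairwise_beta(d, meta, n_perm=19, seed=0)
        assert len(out) == 10  # C(5,2) group pairs
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()
        one = pairwise_beta(d, meta, n_perm=19, seed=0,
                            pairs=[("HC", "ESCC")])
        assert len(one) == 1
        assert one.loc[0, "p_adjusted"] == one.loc[0, "p"]

    def test_anosim_statistic_kind(self, small_cohort):
        bacteria, _, _, meta, _ = small_cohort
        d = bray_curtis(hellinger(bacteria))
        out = pairwise_beta(d, meta, statistic_kind="anosim_R", n_perm=19,
                            seed=0, pairs=[("HC", "ESIN"), ("HC", "ESCC")])
        assert set(out["statistic_kind"]) == {"anosim_R"}
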