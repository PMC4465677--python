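"""Plant-composition pipeline against brute-force and cross-implementation oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.spatial.distance import pdist, squareform

from occucam.habitat_covariates import (
    SiteCovariates,
    _stress1,
    apply_transform,
    bray_curtis,
    cluster_group_average,
    cover_to_importance,
    nmds,
    simper,
    standardize_fourth_root,
    transform_covariates,
)


def cover_long(entries):
    return pd.DataFrame(entries, columns=["site", "species", "tier", "score"])


class TestImportance:
    def test_midpoints_sum_over_tiers(self):
        cov = cover_long(
            [("a", "tawa", "0-30cm", 4), ("a", "tawa", "2-5m", 4)]
        )
        imp = cover_to_importance(cov)
        assert imp.loc["a", "tawa"] == pytest.approx(76.0)  # 38 + 38

    def test_top_class_midpoint(self):
        imp = cover_to_importance(cover_long([("a", "kanuka", ">25m", 6)]))
        assert imp.loc["a", "kanuka"] == pytest.approx(88.0)

    def test_absent_species_is_zero(self):
        cov = cover_long(
            [("a", "tawa", "0-30cm", 2), ("b", "fern", "0-30cm", 3)]
        )
        imp = cover_to_importance(cov)
        assert imp.loc["a", "fern"] == 0.0

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0-6"):
            cover_to_importance(cover_long([("a", "tawa", "0-30cm", 7)]))

    @given(st.integers(1, 5), st.integers(0, 6))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_class_scores(self, base, bump):
        cov = cover_long([("a", "x", "0-30cm", base), ("a", "y", "2-5m", 2)])
        cov2 = cov.copy()
        cov2.loc[0, "score"] = min(6, base + bump)
        low = cover_to_importance(cov).loc["a", "x"]
        high = cover_to_importance(cov2).loc["a", "x"]
        assert high >= low


class TestStandardise:
    def test_proportions_then_fourth_root(self):
        imp = pd.DataFrame([[1.0, 3.0]], index=["a"], columns=["x", "y"])
        out = standardize_fourth_root(imp)
        assert out.loc["a", "x"] == pytest.approx(0.25**0.25, abs=1e-4)
        assert out.loc["a", "y"] == pytest.approx(0.75**0.25, abs=1e-4)

    def test_single_species_site_maps_to_one(self):
        imp = pd.DataFrame([[5.0, 0.0]], index=["a"], columns=["x", "y"])
        assert standardize_fourth_root(imp).loc["a", "x"] == pytest.approx(1.0)

    def test_row_scaling_invariance(self):
        imp = pd.DataFrame([[1.0, 2.0, 5.0]], index=["a"])
        out1 = standardize_fourth_root(imp)
        out2 = standardize_fourth_root(imp * 7.3)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_site_rejected(self):
        imp = pd.DataFrame([[0.0, 0.0]], index=["a"])
        with pytest.raises(ValueError, match="no recorded species"):
            standardize_fourth_root(imp)


class TestBrayCurtis:
    def test_formula_on_toy_rows(self):
        mat = pd.DataFrame([[1.0, 3.0], [2.0, 1.0]], index=["a", "b"])
        sim = bray_curtis(mat)
        assert sim.loc["a", "b"] == pytest.approx(1 - 3 / 7)

    def test_identical_and_disjoint_rows(self):
        mat = pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 5]], dtype=float)
        sim = bray_curtis(mat)
        assert sim.iloc[0, 1] == pytest.approx(1.0)
        assert sim.iloc[0, 2] == pytest.approx(0.0)

    def test_two_empty_sites_rejected(self):
        mat = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(mat)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_scipy_and_is_symmetric_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((5, 4)) * rng.integers(1, 20)
        sim = bray_curtis(pd.DataFrame(X)).to_numpy()
        assert np.allclose(sim, sim.T)
        assert (sim >= -1e-12).all() and (sim <= 1 + 1e-12).all()
        assert np.allclose(np.diag(sim), 1.0)
        assert sim[0, 1] == pytest.approx(1 - scipy_bc(X[0], X[1]))


def brute_upgma_heights(D):
    """Naive group-average agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(D.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestClustering:
    def test_obvious_pairs_recovered_and_heights_match_brute_force(self):
        D = np.array(
            [
                [0.0, 0.10, 0.80, 0.90],
                [0.10, 0.0, 0.85, 0.95],
                [0.80, 0.85, 0.0, 0.15],
                [0.90, 0.95, 0.15, 0.0],
            ]
        )
        sim = pd.DataFrame(1 - D, index=list("abcd"), columns=list("abcd"))
        labels = cluster_group_average(sim, 2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]
        from scipy.cluster.hierarchy import linkage

        scipy_heights = linkage(squareform(D), method="average")[:, 2]
        assert np.allclose(sorted(scipy_heights), brute_upgma_heights(D))

    def test_brute_force_agreement_on_random_six_site_matrices(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.random((6, 4)) * 10
            D = squareform(pdist(X, metric="braycurtis"))
            heights = linkage(squareform(D), method="average")[:, 2]
            assert np.allclose(sorted(heights), brute_upgma_heights(D), atol=1e-12)

    def test_extreme_cuts(self):
        rng = np.random.default_rng(0)
        sim = bray_curtis(pd.DataFrame(rng.random((5, 3))))
        assert cluster_group_average(sim, 5).nunique() == 5
        assert cluster_group_average(sim, 1).nunique() == 1
        with pytest.raises(ValueError, match="n_groups"):
            cluster_group_average(sim, 6)


class TestSimper:
    def test_singleton_groups_equal_single_pair_terms(self):
        mat = pd.DataFrame([[1.0, 3.0], [2.0, 1.0]], index=["a", "b"])
        tab = simper(mat, pd.Series([1, 2], index=["a", "b"]))
        denom = 7.0
        expected = {"0": 1 / denom, "1": 2 / denom}
        got = dict(zip(tab["species"].astype(str), tab["contribution"]))
        assert got == pytest.approx(expected)

    def test_constant_species_contributes_nothing(self):
        mat = pd.DataFrame(
            [[2.0, 1.0], [2.0, 5.0], [2.0, 9.0]], columns=["const", "var"]
        )
        tab = simper(mat, pd.Series([1, 1, 2]))
        assert tab.set_index("species").loc["const", "contribution"] == 0.0

    def test_contributions_sum_to_mean_cross_pair_dissimilarity(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.random((6, 5)) * 4, index=list("abcdef"))
        groups = pd.Series([1, 1, 2, 2, 3, 3], index=mat.index)
        tab = simper(mat, groups)
        X = mat.to_numpy()
        for (ga, gb), sub in tab.groupby(["group_1", "group_2"]):
            ia = np.flatnonzero(groups == ga)
            ib = np.flatnonzero(groups == gb)
            oracle = np.mean([scipy_bc(X[i], X[j]) for i in ia for j in ib])
            assert sub["contribution"].sum() == pytest.approx(oracle, abs=1e-10)
            assert sub["mean_dissimilarity"].iloc[0] == pytest.approx(oracle, abs=1e-10)

    def test_empty_group_rejected(self):
        mat = pd.DataFrame([[1.0], [2.0]])
        with pytest.raises(ValueError, match="two groups"):
            simper(mat, pd.Series([1, 1]))


class TestNMDS:
    def test_three_equidistant_sites_embed_exactly(self):
        sim = pd.DataFrame(1 - (np.ones((3, 3)) - np.eye(3)) * 0.5)
        res = nmds(sim, restarts=5, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-6)

    def test_duplicate_sites_attain_minimum_embedded_distance(self):
        # nonmetric scaling preserves ranks, so the zero-dissimilarity pair
        # must be the closest pair in the configuration
        rng = np.random.default_rng(2)
        X = rng.random((6, 4)) * 6
        X[1] = X[0]  # exact duplicate
        sim = bray_curtis(pd.DataFrame(X))
        res = nmds(sim, restarts=10, seed=1)
        dists = squareform(pdist(res.coords.to_numpy()))
        np.fill_diagonal(dists, np.inf)
        d01 = dists[0, 1]
        assert d01 == pytest.approx(dists.min(), abs=1e-9)
        assert d01 < 0.5 * np.mean(dists[np.isfinite(dists)])

    def test_stress_matches_independent_implementation(self):
        # sklearn's nonmetric MDS is the independent optimiser; both should
        # find configurations of (numerically) equal Kruskal stress-1
        from sklearn.isotonic import IsotonicRegression
        from sklearn.manifold import MDS

        rng = np.random.default_rng(42)
        mat = pd.DataFrame(rng.random((6, 5)) * 10)
        sim = bray_curtis(mat)
        ours = nmds(sim, restarts=20, seed=0)
        D = 1 - sim.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            mds = MDS(
                n_components=2, metric=False, dissimilarity="precomputed",
                n_init=50, max_iter=500, random_state=0, eps=1e-9,
            )
            emb = mds.fit_transform(D)
        d = pdist(emb)
        diss = squareform(D, checks=False)
        order = np.lexsort((d, diss))
        iso = IsotonicRegression(increasing=True)
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
        theirs = _stress1(d, dhat)
        assert ours.stress == pytest.approx(theirs, abs=1e-3)

    def test_stress_invariant_to_rigid_motion_of_input_scores(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.random((6, 4)))
        sim = bray_curtis(mat)
        res = nmds(sim, restarts=8, seed=2)
        X = res.coords.to_numpy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for Y in (X @ R, X * 3.0, -X):
            d = pdist(Y)
            diss = squareform(1 - sim.to_numpy(), checks=False)
            from sklearn.isotonic import IsotonicRegression

            order = np.lexsort((d, diss))
            iso = IsotonicRegression(increasing=True)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            assert _stress1(d, dhat) == pytest.approx(res.stress, abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        sim = bray_curtis(pd.DataFrame(rng.random((5, 4))))
        r1 = nmds(sim, restarts=4, seed=5)
        r2 = nmds(sim, restarts=4, seed=5)
        pd.testing.assert_frame_equal(r1.coords, r2.coords)


class TestCovariateTransforms:
    def make_raw(self):
        frame = pd.DataFrame(
            {
                "direct_winter": [4.0, 0.0, 1.0],
                "diffuse_winter": [1.0, 0.5, 0.2],
                "total_winter": [5.0, 0.5, 1.2],
                "cn": [11.0, 24.0, 14.9],
                "ph": [5.4, 6.9, 6.2],
                "p_avail": [3.0, 41.0, 13.5],
                "axis1": [-1.0, 0.0, 1.0],
            },
            index=pd.Index(["a", "b", "c"], name="site_id"),
        )
        return SiteCovariates(frame)

    def test_sqrt_for_solar_log_for_soil(self):
        out = transform_covariates(self.make_raw())
        assert out.data.loc["a", "direct_winter"] == pytest.approx(2.0)
        assert out.data.loc["b", "direct_winter"] == 0.0  # zero allowed, no offset
        assert out.data.loc["a", "p_avail"] == pytest.approx(np.log(3), abs=1e-4)
        assert out.data.loc["a", "axis1"] == -1.0
        assert out.transforms["cn"] == "log"

    def test_non_positive_soil_rejected(self):
        raw = self.make_raw()
        raw.data.loc["a", "cn"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            transform_covariates(raw)

    def test_total_must_equal_direct_plus_diffuse(self):
        frame = self.make_raw().data.copy()
        frame.loc["a", "total_winter"] = 9.0
        with pytest.raises(ValueError, match="direct \\+ diffuse"):
            SiteCovariates(frame)

    def test_apply_transform_by_name(self):
        assert apply_transform("Direct", 4.0) == pytest.approx(2.0)
        assert apply_transform("P", np.e) == pytest.approx(1.0)
        assert apply_transform("Axis1", -0.3) == pytest.approx(-0.3)
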