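import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.ordination import pcoa as skbio_pcoa

from assemblyscape import (
    CommunityTable,
    anosim,
    axis_vs_distance,
    bray_curtis_matrix,
    distance_decay,
    geographic_distance_matrix,
    haversine_km,
    pcoa,
    preset,
    simper,
    simulate_metacommunity,
)


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        t = CommunityTable(pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 5], [0, 1, 1]],
            index=["a", "b", "c", "d"], columns=["x", "y", "z"]))
        bc = bray_curtis_matrix(t)
        assert bc["a", "b"] == 0.0
        assert bc["a", "c"] == 1.0
        assert bc["a", "d"] == pytest.approx(0.5)

    def test_invariant_to_column_and_row_order(self, het_dataset):
        table, _, _ = het_dataset
        bc = bray_curtis_matrix(table)
        shuffled = CommunityTable(
            table.counts.iloc[::-1, ::-1])
        bc2 = bray_curtis_matrix(shuffled).filter(bc.ids)
        np.testing.assert_allclose(bc.data, bc2.data, atol=1e-12)


class TestPcoa:
    def test_collinear_points_reconstructed_on_first_axis(self):
        pts = np.array([0.0, 3.0, 5.0])
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]),
                           ids=["a", "b", "c"])
        res = pcoa(d)
        ax1 = res.coordinates.iloc[:, 0].to_numpy()
        got = np.abs(ax1[:, None] - ax1[None, :])
        np.testing.assert_allclose(got, d.data, atol=1e-8)

    def test_gower_identity_for_euclidean_input(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        d = DistanceMatrix(squareform(pdist(pts)), ids=list("abcdef"))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        got = squareform(pdist(coords))
        np.testing.assert_allclose(got, d.data, atol=1e-8)

    def test_eigenvalues_match_skbio(self, het_dataset):
        table, _, _ = het_dataset
        bc = bray_curtis_matrix(CommunityTable(table.counts.iloc[:5]))
        ours = pcoa(bc)
        ref = skbio_pcoa(bc, method="eigh")
        np.testing.assert_allclose(
            ours.eigenvalues[:3], ref.eigvals.to_numpy()[:3], atol=1e-8)
        np.testing.assert_allclose(
            ours.proportion_explained[0],
            ref.proportion_explained.iloc[0], atol=1e-8)

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError):
            pcoa(d)


class TestAnosim:
    def _separated(self):
        # between-group distances strictly exceed within-group distances
        data = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.85, 0.95],
            [0.9, 0.85, 0.0, 0.15],
            [0.8, 0.95, 0.15, 0.0]])
        return DistanceMatrix(data, ids=list("abcd")), ["g1", "g1", "g2", "g2"]

    def test_perfect_separation_gives_r_one(self):
        d, g = self._separated()
        r, p = anosim(d, g, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_four_samples(self):
        """R for every distinct 2+2 labelling equals a brute-force
        computation from rank definitions."""
        d, _ = self._separated()
        iu = np.triu_indices(4, k=1)
        from scipy.stats import rankdata
        ranks = rankdata(d.data[iu])
        for combo in itertools.combinations(range(4), 2):
            labels = np.array(["g2"] * 4, dtype=object)
            labels[list(combo)] = "g1"
            within = labels[iu[0]] == labels[iu[1]]
            expect = (ranks[~within].mean() - ranks[within].mean()) / (6 / 2)
            got, _ = anosim(DistanceMatrix(d.data, ids=list("abcd")),
                            list(labels), n_perm=99, seed=1)
            assert got == pytest.approx(expect)

    def test_agrees_with_skbio_on_random_matrix(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(8)])
        g = ["a"] * 4 + ["b"] * 4
        ours, _ = anosim(d, g, n_perm=99, seed=0)
        ref = skbio_anosim(d, np.array(g), permutations=99)
        assert ours == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(50):
            pts = rng.normal(size=(10, 2))
            d = DistanceMatrix(squareform(pdist(pts)),
                               ids=[f"s{i}" for i in range(10)])
            g = list(rng.permutation(["a"] * 5 + ["b"] * 5))
            r, _ = anosim(d, g, n_perm=49, seed=int(rng.integers(2**31)))
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_two_way_crossed_with_strata(self):
        # two strata, each with clean group separation
        data = np.full((8, 8), 0.9)
        np.fill_diagonal(data, 0.0)
        ids = [f"s{i}" for i in range(8)]
        groups = ["x", "x", "y", "y"] * 2
        strata = ["t1"] * 4 + ["t2"] * 4
        for i, j in [(0, 1), (2, 3), (4, 5), (6, 7)]:
            data[i, j] = data[j, i] = 0.1
        d = DistanceMatrix(data, ids=ids)
        r, p = anosim(d, groups, n_perm=99, seed=0, strata=strata)
        assert r > 0.99

    def test_singleton_group_rejected(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.]]),
                           ids=list("abc"))
        with pytest.raises(ValueError):
            anosim(d, ["g1", "g2", "g2"], n_perm=49, seed=0)


class TestSimper:
    def test_single_discriminating_taxon_takes_all(self):
        t = CommunityTable(pd.DataFrame(
            [[5, 10], [5, 10], [5, 0], [5, 0]],
            index=["a1", "a2", "b1", "b2"], columns=["shared", "marker"]))
        rows = simper(t, ["A", "A", "B", "B"], "A", "B")
        assert rows.iloc[0].taxon_id == "marker"
        assert rows.iloc[0].cumulative_pct == pytest.approx(100.0)

    def test_contributions_sum_to_mean_between_group_bc(self, het_dataset):
        table, _, meta = het_dataset
        sites = meta["site"]
        a, b = sites.unique()[:2]
        rows = simper(table, sites, a, b)
        bc = bray_curtis_matrix(table)
        ia = sites.index[sites == a]
        ib = sites.index[sites == b]
        mean_bc = np.mean([bc[i, j] for i in ia for j in ib])
        assert rows.contribution.sum() == pytest.approx(mean_bc, abs=1e-12)

    def test_two_by_two_hand_expansion(self):
        t = CommunityTable(pd.DataFrame([[3, 1], [1, 3]], index=["a", "b"],
                                        columns=["x", "y"]))
        rows = simper(t, ["A", "B"], "A", "B").set_index("taxon_id")
        assert rows.loc["x", "contribution"] == pytest.approx(2 / 8)
        assert rows.loc["y", "contribution"] == pytest.approx(2 / 8)

    def test_empty_group_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            simper(tiny_table, ["A"] * 4, "A", "B")


class TestHaversine:
    def test_identity_antipode_and_equator_degree(self):
        assert haversine_km(10, 20, 10, 20) == 0.0
        assert haversine_km(0, 0, 0, 180) == pytest.approx(
            np.pi * 6371.0, rel=1e-6)
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            haversine_km(0, 181, 0, 0)


class TestDistanceDecay:
    def _geo(self, n=6, spacing=10.0):
        ids = [f"s{i}" for i in range(n)]
        pos = np.arange(n) * spacing
        return DistanceMatrix(np.abs(pos[:, None] - pos[None, :]), ids=ids)

    def test_constant_similarity_zero_slope(self):
        geo = self._geo()
        d = DistanceMatrix(np.full((6, 6), 0.4) - 0.4 * np.eye(6),
                           ids=list(geo.ids))
        slope, _, _, _ = distance_decay(d, geo, n_perm=99, seed=0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_decay_recovered(self):
        geo = self._geo()
        sim = 1.0 - 0.001 * geo.data
        d = DistanceMatrix(1.0 - sim, ids=list(geo.ids))
        slope, intercept, r, _ = distance_decay(d, geo, n_perm=99, seed=0)
        assert slope == pytest.approx(-0.001)
        assert abs(r) == pytest.approx(1.0)

    def test_spatially_structured_communities_decay(self):
        cfg = preset("dispersal_limitation", n_taxa=120, n_sites=5, n_reps=2,
                     depth=1000, seed=17)
        table, _, meta = simulate_metacommunity(cfg)
        bc = bray_curtis_matrix(table)
        geo = geographic_distance_matrix(meta)
        slope, _, _, p = distance_decay(bc, geo, n_perm=199, seed=5)
        assert slope < 0 and p < 0.05

    def test_zero_geo_variance_rejected(self):
        d = self._geo()
        geo = DistanceMatrix(np.zeros((6, 6)), ids=list(d.ids))
        with pytest.raises(ValueError):
            distance_decay(d, geo, n_perm=99, seed=0)


class TestAxisVsDistance:
    def _ordination(self, axis_vals):
        from assemblyscape.patterns import OrdinationResult
        n = len(axis_vals)
        coords = pd.DataFrame({"PC1": axis_vals},
                              index=[f"s{i}" for i in range(n)])
        return OrdinationResult(coords, np.array([1.0]), np.array([1.0]))

    def test_identical_axis_perfect_correlation(self):
        dtl = np.linspace(5, 65, 8)
        res = axis_vs_distance(self._ordination(dtl), dtl, n_perm=99, seed=0)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["p"] < 0.05

    def test_quadratic_relationship_recovered(self):
        dtl = np.linspace(-3, 3, 12)
        axis = dtl ** 2
        res = axis_vs_distance(self._ordination(axis), dtl, n_perm=99, seed=1)
        a, b, c = res["quadratic"]
        assert a == pytest.approx(1.0, abs=1e-8)
        assert abs(res["pearson_r"]) < 0.2

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            axis_vs_distance(self._ordination(np.ones(5)),
                             np.linspace(0, 1, 5))
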