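import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from assemblyscape import (
    bray_curtis_matrix,
    dbrda_adjusted_r2,
    forward_selection,
    geographic_distance_matrix,
    marginal_tests,
    pcnm,
    pcoa,
    variation_partition,
)


def line_sites(n=5, spacing=10.0):
    ids = [f"s{i}" for i in range(n)]
    pos = np.arange(n) * spacing
    return DistanceMatrix(np.abs(pos[:, None] - pos[None, :]), ids=ids)


class TestPcnm:
    def test_two_sites_at_most_one_axis(self):
        basis = pcnm(line_sites(2))
        assert basis.eigenvectors.shape[1] <= 1

    def test_eigenvectors_orthogonal(self):
        basis = pcnm(line_sites(7))
        V = basis.eigenvectors.to_numpy()
        gram = V.T @ V
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_matches_brute_force_pcoa_of_truncated_matrix(self):
        """5 equally spaced collinear sites: build the truncated matrix by
        hand (MST longest edge = spacing; larger entries -> 4x truncation)
        and compare to an independent PCoA (scikit-bio)."""
        geo = line_sites(5, spacing=10.0)
        basis = pcnm(geo)
        assert basis.truncation == pytest.approx(10.0)
        trunc = geo.data.copy()
        trunc[trunc > 10.0] = 40.0
        ref = skbio_pcoa(DistanceMatrix(trunc, ids=list(geo.ids)),
                         method="eigh")
        refvals = ref.eigvals.to_numpy()
        refvals = refvals[refvals > 1e-8]
        np.testing.assert_allclose(basis.eigenvalues, refvals, atol=1e-8)
        refcoords = ref.samples.to_numpy()[:, :len(refvals)]
        ours = basis.eigenvectors.to_numpy()
        for k in range(ours.shape[1]):
            col, refcol = ours[:, k], refcoords[:, k]
            sign = np.sign(col @ refcol)
            np.testing.assert_allclose(col, sign * refcol, atol=1e-6)

    def test_colocated_sites_rejected(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            pcnm(d)


class TestDbrda:
    def _toy(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 4))
        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"s{i}" for i in range(n)])
        return d

    def test_first_axis_explains_its_own_inertia_share(self):
        d = self._toy()
        res_ord = pcoa(d)
        X = res_ord.coordinates.iloc[:, [0]]
        res = dbrda_adjusted_r2(d, X, n_perm=99, seed=1)
        assert res["r2"] == pytest.approx(res_ord.proportion_explained[0],
                                          abs=1e-8)

    def test_noise_predictor_unbiased_after_adjustment(self):
        rng = np.random.default_rng(2)
        vals = []
        d = self._toy(n=20, seed=3)
        for _ in range(200):
            X = pd.DataFrame({"x": rng.normal(size=20)},
                             index=list(d.ids))
            res = dbrda_adjusted_r2(d, X, n_perm=9, seed=0)
            vals.append(res["adj_r2"])
        assert abs(np.mean(vals)) < 0.02

    def test_collinear_block_rejected_naming_columns(self):
        d = self._toy()
        x = np.random.default_rng(4).normal(size=12)
        X = pd.DataFrame({"a": x, "dup": x}, index=list(d.ids))
        with pytest.raises(ValueError, match="dup"):
            dbrda_adjusted_r2(d, X, n_perm=9, seed=0)

    def test_scale_invariance(self):
        d = self._toy(seed=5)
        X = pd.DataFrame({"x": np.arange(12.0)}, index=list(d.ids))
        r1 = dbrda_adjusted_r2(d, X, n_perm=49, seed=6)
        r2 = dbrda_adjusted_r2(d, X * 1e4, n_perm=49, seed=6)
        assert r1["r2"] == pytest.approx(r2["r2"], abs=1e-10)
        assert r1["p"] == r2["p"]


class TestMarginalTests:
    def test_true_driver_ranks_first(self, het_dataset):
        table, _, meta = het_dataset
        bc = bray_curtis_matrix(table)
        rng = np.random.default_rng(0)
        preds = pd.DataFrame({
            "temperature": meta["temperature"],
            "junk1": rng.normal(size=len(meta)),
            "junk2": rng.normal(size=len(meta)),
        }, index=meta.index)
        res = marginal_tests(bc, preds, n_perm=199, seed=1)
        best = res.sort_values(["p", "pseudo_f"],
                               ascending=[True, False]).iloc[0]
        assert best.variable == "temperature"

    def test_duplicated_variable_identical_statistics(self, het_dataset):
        table, _, meta = het_dataset
        bc = bray_curtis_matrix(table)
        preds = pd.DataFrame({"t1": meta["temperature"],
                              "t2": meta["temperature"]}, index=meta.index)
        res = marginal_tests(bc, preds, n_perm=99, seed=2).set_index("variable")
        assert res.loc["t1", "r2"] == pytest.approx(res.loc["t2", "r2"])
        assert res.loc["t1", "pseudo_f"] == pytest.approx(
            res.loc["t2", "pseudo_f"])

    def test_constant_variable_skipped(self, het_dataset):
        table, _, meta = het_dataset
        bc = bray_curtis_matrix(table)
        preds = pd.DataFrame({"const": 1.0, "temperature": meta["temperature"]},
                             index=meta.index)
        res = marginal_tests(bc, preds, n_perm=99, seed=3)
        assert list(res.variable) == ["temperature"]


@pytest.fixture(scope="module")
def gradient_dataset():
    """25-sample gradient design; forward selection needs adequate n for
    the full-model adjusted-R2 stopping bound to be meaningful."""
    from assemblyscape import preset, simulate_metacommunity
    cfg = preset("heterogeneous_selection", n_taxa=100, n_sites=5, n_reps=5,
                 depth=800, seed=8)
    return simulate_metacommunity(cfg)


class TestForwardSelection:
    def test_true_driver_selected_first(self, gradient_dataset):
        table, _, meta = gradient_dataset
        bc = bray_curtis_matrix(table)
        rng = np.random.default_rng(1)
        for rep in range(3):
            preds = pd.DataFrame({
                "temperature": meta["temperature"],
                "junk": rng.normal(size=len(meta)),
            }, index=meta.index)
            sel = forward_selection(bc, preds, n_perm=199, seed=10 + rep)
            assert sel and sel[0] == "temperature"

    def test_duplicate_of_selected_never_admitted(self, het_dataset):
        table, _, meta = het_dataset
        bc = bray_curtis_matrix(table)
        preds = pd.DataFrame({"temperature": meta["temperature"],
                              "copy": meta["temperature"]}, index=meta.index)
        sel = forward_selection(bc, preds, n_perm=99, seed=4)
        assert sel in (["temperature"], ["copy"])

    def test_alpha_zero_selects_nothing(self, het_dataset):
        table, _, meta = het_dataset
        bc = bray_curtis_matrix(table)
        sel = forward_selection(bc, meta[["temperature"]], alpha=0.0,
                                n_perm=99, seed=5)
        assert sel == []


class TestVariationPartition:
    def _case(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, 1))
        s = rng.normal(size=(n, 1))
        y = np.hstack([a + 0.3 * rng.normal(size=(n, 1)),
                       s + 0.3 * rng.normal(size=(n, 1))])
        d = DistanceMatrix(squareform(pdist(y)),
                           ids=[f"s{i}" for i in range(n)])
        ids = list(d.ids)
        A = pd.DataFrame({"a": a[:, 0]}, index=ids)
        S = pd.DataFrame({"s": s[:, 0]}, index=ids)
        return d, A, S

    def test_identical_blocks_share_everything(self):
        d, A, _ = self._case()
        part = variation_partition(d, abiotic=A, biotic=A.rename(
            columns={"a": "b"}))
        assert part.fractions["abiotic_pure"] == pytest.approx(0.0, abs=1e-9)
        assert part.fractions["biotic_pure"] == pytest.approx(0.0, abs=1e-9)
        assert part.fractions["abiotic_biotic_shared"] > 0.1

    def test_orthogonal_blocks_share_almost_nothing(self):
        shared = []
        for seed in range(5):
            d, A, S = self._case(seed)
            part = variation_partition(d, abiotic=A, spatial=S)
            shared.append(part.fractions["abiotic_spatial_shared"])
        assert max(abs(v) for v in shared) < 0.05

    def test_inclusion_exclusion_sums_to_one(self):
        d, A, S = self._case(3)
        rng = np.random.default_rng(4)
        B = pd.DataFrame({"b": rng.normal(size=20)}, index=list(d.ids))
        part = variation_partition(d, abiotic=A, biotic=B, spatial=S)
        assert part.total == pytest.approx(1.0, abs=1e-9)

    def test_empty_blocks_allowed(self):
        d, A, _ = self._case(5)
        part = variation_partition(d, abiotic=A)
        assert part.fractions["spatial_pure"] == 0.0
        assert part.total == pytest.approx(1.0, abs=1e-9)
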