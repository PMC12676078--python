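"""PCoA, PERMANOVA, dbMEM, dbRDA and forward selection against independent
oracles (classical ANOVA, full enumeration, direct least squares, geometry).
"""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from rhizoadapt import ordination as o, synthetic as syn, community as com
from rhizoadapt.datatypes import DistanceMatrix, ValidationError
from .conftest import euclidean_dm


class TestGowerAndPcoa:
    def test_gower_equals_centered_gram_matrix(self, rng):
        X = rng.normal(size=(15, 4))
        G = o.gower_center(euclidean_dm(X)).G
        Xc = X - X.mean(axis=0)
        assert np.allclose(G, Xc @ Xc.T, atol=1e-10)

    def test_zero_distances_give_zero_matrix_and_row_sums(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "z")
        G = o.gower_center(dm).G
        assert np.allclose(G, 0.0)
        X = np.random.default_rng(1).normal(size=(8, 2))
        G2 = o.gower_center(euclidean_dm(X)).G
        assert np.allclose(G2.sum(axis=0), 0.0, atol=1e-10)

    def test_pcoa_reconstructs_planar_distances(self, rng):
        pts = rng.normal(size=(10, 2))
        res = o.pcoa(euclidean_dm(pts))
        rec = squareform(pdist(res.coordinates[:, :2]))
        assert np.allclose(rec, squareform(pdist(pts)), atol=1e-8)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(o.gower_center(euclidean_dm(pts)).G), abs=1e-8
        )

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 4]])
        res = o.pcoa(euclidean_dm(pts))
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-10)

    def test_pcoa_agrees_with_skbio(self, rng):
        import warnings
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(9, 3))
        dm = euclidean_dm(pts)
        ours = np.sort(o.pcoa(dm).eigenvalues)[::-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = np.sort(skbio_pcoa(dm.to_skbio()).eigvals.to_numpy())[::-1]
        k = min(len(ours), len(theirs))
        assert np.allclose(ours[:k], theirs[:k], atol=1e-8)


class TestPermanova:
    def test_pseudo_f_equals_classical_anova_f(self, rng):
        y = rng.normal(size=18)
        groups = np.repeat(list("abc"), 6)
        dm = euclidean_dm(y[:, None])
        tab = o.permanova(dm, pd.DataFrame({"g": groups}), ["g"], n_perm=99, seed=0)
        F = stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert tab.F[0] == pytest.approx(F, abs=1e-8)

    def test_permutation_p_equals_full_enumeration(self, rng):
        y = rng.normal(size=6)
        groups = ["a"] * 3 + ["b"] * 3
        dm = euclidean_dm(y[:, None])
        tab = o.permanova(dm, pd.DataFrame({"g": groups}), ["g"], permutations="exact")
        Fobs = stats.f_oneway(y[:3], y[3:]).statistic
        count = sum(
            stats.f_oneway(y[list(p[:3])], y[list(p[3:])]).statistic >= Fobs - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert tab.p[0] == pytest.approx(count / 720)

    def test_total_ss_is_mcardle_anderson_identity(self, rng):
        pts = rng.normal(size=(14, 5))
        dm = euclidean_dm(pts)
        tab = o.permanova(dm, pd.DataFrame({"g": ["a", "b"] * 7}), ["g"],
                          n_perm=99, seed=0)
        ss_total = tab.loc[tab.term == "Total", "SS"].iloc[0]
        n = 14
        assert ss_total == pytest.approx(
            (dm.values ** 2).sum() / (2 * n), abs=1e-8
        )

    def test_r2_invariant_to_sample_reordering(self, rng):
        pts = rng.normal(size=(12, 3))
        groups = np.array(["a", "b", "c"] * 4)
        dm = euclidean_dm(pts)
        tab1 = o.permanova(dm, pd.DataFrame({"g": groups}), ["g"], n_perm=99, seed=0)
        perm = rng.permutation(12)
        dm2 = dm.reorder([dm.ids[i] for i in perm])
        tab2 = o.permanova(dm2, pd.DataFrame({"g": groups[perm]}), ["g"],
                           n_perm=99, seed=0)
        assert tab1.R2[0] == pytest.approx(tab2.R2[0], abs=1e-10)

    def test_aliased_term_rejected_by_name(self, rng):
        pts = rng.normal(size=(8, 2))
        g = ["a", "a", "b", "b", "c", "c", "d", "d"]
        design = pd.DataFrame({"g": g, "alias": g})
        with pytest.raises(ValidationError, match="alias"):
            o.permanova(euclidean_dm(pts), design, ["g", "alias"], n_perm=99, seed=0)

    def test_agrees_with_skbio_single_factor(self, rng):
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(15, 4))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        dm = euclidean_dm(pts)
        ours = o.permanova(dm, pd.DataFrame({"g": groups}), ["g"], n_perm=99, seed=0)
        theirs = skbio_permanova(dm.to_skbio(), grouping=groups, permutations=99)
        assert ours.F[0] == pytest.approx(theirs["test statistic"], abs=1e-8)


class TestDbmem:
    def test_transect_leading_eigenvector_is_smoothest_gradient(self):
        xs = np.arange(10.0)[:, None]
        mem = o.dbmem(euclidean_dm(xs))
        v = mem.eigenvectors[:, 0]
        # single sign change around its mean and a strong monotone trend
        assert int(np.sum(np.diff(np.sign(v - v.mean())) != 0)) == 1
        assert abs(np.corrcoef(v, xs.ravel())[0, 1]) > 0.8

    def test_eigenvectors_orthonormal_with_positive_eigenvalues(self, rng):
        pts = rng.normal(size=(20, 2))
        mem = o.dbmem(euclidean_dm(pts))
        k = mem.eigenvectors.shape[1]
        assert np.allclose(mem.eigenvectors.T @ mem.eigenvectors, np.eye(k),
                           atol=1e-8)
        assert (mem.eigenvalues > 0).all()

    def test_hamming_distance_from_ssr(self, panel12):
        ssr = syn.gen_ssr(panel12, n_loci=10, seed=3, missing_rate=0.1)
        dm = o.hamming_distance_matrix(ssr)
        a = ssr.data.iloc[0].to_numpy(dtype=float, na_value=np.nan)
        b = ssr.data.iloc[1].to_numpy(dtype=float, na_value=np.nan)
        ok = ~np.isnan(a) & ~np.isnan(b)
        assert dm.values[0, 1] == pytest.approx(np.mean(a[ok] != b[ok]))

    def test_coincident_points_rejected(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)), "z")
        with pytest.raises(ValidationError):
            o.dbmem(dm)


class TestDbrda:
    def test_constrained_proportion_equals_regression_r2(self, rng):
        Y = rng.normal(size=(20, 5))
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        model = o.dbrda(euclidean_dm(Y), X)
        Yc = Y - Y.mean(axis=0)
        D = np.hstack([np.ones((20, 1)), X.to_numpy()])
        B = np.linalg.lstsq(D, Yc, rcond=None)[0]
        r2 = 1 - ((Yc - D @ B) ** 2).sum() / (Yc ** 2).sum()
        assert model.constrained_proportion == pytest.approx(r2, abs=1e-8)

    def test_orthogonal_predictor_explains_nothing(self, rng):
        Y = rng.normal(size=(30, 3))
        x = rng.normal(size=30)
        x -= np.linalg.lstsq(
            np.hstack([np.ones((30, 1)), Y - Y.mean(0)]), x, rcond=None
        )[0] @ np.hstack([np.ones((30, 1)), Y - Y.mean(0)]).T
        model = o.dbrda(euclidean_dm(Y), pd.DataFrame({"x": x}))
        assert model.constrained_proportion < 0.05

    def test_inertia_components_sum_to_total(self, rng):
        Y = rng.normal(size=(18, 4))
        X = pd.DataFrame(rng.normal(size=(18, 2)), columns=["a", "b"])
        Z = rng.normal(size=(18, 3))
        model = o.dbrda(euclidean_dm(Y), X, condition=Z)
        total = (model.conditioned_inertia + model.constrained_inertia
                 + model.unconstrained_inertia)
        assert total == pytest.approx(model.total_inertia, abs=1e-8)

    def test_condition_collinear_predictor_dropped_with_warning(self, rng):
        Y = rng.normal(size=(16, 3))
        z = rng.normal(size=16)
        X = pd.DataFrame({"dup": z, "indep": rng.normal(size=16)})
        with pytest.warns(UserWarning, match="dup"):
            model = o.dbrda(euclidean_dm(Y), X, condition=z[:, None])
        assert model.predictors == ["indep"]

    def test_overconditioning_leaves_no_constrained_inertia(self, rng):
        Y = rng.normal(size=(12, 3))
        dm = euclidean_dm(Y)
        coords = o.pcoa(dm).coordinates
        model = o.dbrda(dm, pd.DataFrame({"x": rng.normal(size=12)}),
                        condition=coords)
        assert abs(model.constrained_inertia) < 1e-6 * model.total_inertia


class TestForwardSelect:
    def test_alpha_one_selects_all_and_tiny_alpha_none(self, rng):
        Y = rng.normal(size=(20, 4))
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        dm = euclidean_dm(Y)
        assert sorted(o.forward_select(dm, X, alpha=1.0, n_perm=99, seed=0).selected) \
            == ["a", "b", "c"]
        assert o.forward_select(dm, X, alpha=0.004, n_perm=99, seed=0).selected == []

    def test_selection_deterministic_given_seed(self, rng):
        Y = rng.normal(size=(25, 4))
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        X["a"] += Y[:, 0]
        dm = euclidean_dm(Y)
        s1 = o.forward_select(dm, X, alpha=0.2, n_perm=99, seed=5).selected
        s2 = o.forward_select(dm, X, alpha=0.2, n_perm=99, seed=5).selected
        assert s1 == s2

    def test_sequential_partition_sums_below_total(self, rng):
        Y = rng.normal(size=(30, 4))
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X["a"] += 2 * Y[:, 0]
        model = o.forward_select(euclidean_dm(Y), X, alpha=0.5, n_perm=99, seed=1)
        if len(model.selected):
            assert model.selection_table["R2"].sum() <= 1.0 + 1e-9


class TestGeography:
    def test_haversine_quarter_meridian(self):
        import pandas as pd
        from rhizoadapt.datatypes import GenotypePanel, ENV_VARS

        rows = []
        for name, lat in (("eq", 0.0), ("pole", 90.0)):
            row = dict(genotype=name, lon=0.0, lat=lat, elevation=0.0)
            row.update({v: 1.0 for v in ENV_VARS})
            rows.append(row)
        panel = GenotypePanel(pd.DataFrame(rows))
        dm = o.haversine_distance_matrix(panel)
        assert dm.values[0, 1] == pytest.approx(np.pi / 2 * 6371.0, rel=1e-6)

    def test_mantel_detects_isolation_by_distance(self, panel40):
        from skbio.stats.distance import mantel

        ssr_ibd = syn.gen_ssr(panel40, n_loci=30, ibd_strength=3.0, seed=2)
        r_ibd, p_ibd, _ = mantel(
            o.hamming_distance_matrix(ssr_ibd).to_skbio(),
            o.haversine_distance_matrix(panel40).to_skbio(),
            permutations=199, seed=1,
        )
        assert r_ibd > 0.2 and p_ibd < 0.05
        rs = []
        for s in range(5):
            ssr0 = syn.gen_ssr(panel40, n_loci=30, ibd_strength=0.0, seed=10 + s)
            r0, _, _ = mantel(
                o.hamming_distance_matrix(ssr0).to_skbio(),
                o.haversine_distance_matrix(panel40).to_skbio(),
                permutations=0, seed=1,
            )
            rs.append(r0)
        assert abs(np.mean(rs)) < 0.1
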