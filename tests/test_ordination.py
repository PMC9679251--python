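"""PCoA, dbMEM, PCA, DAPC, dbRDA, permutational ANOVA, variance partition."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from mothscape._core import MothscapeError, RasterStack, as_square
from mothscape.geno_qc import genetic_distance
from mothscape.ordination import (
    dapc_xval,
    dbmem,
    dbrda_fit,
    env_raster_pca,
    morans_i,
    pca_genotypes,
    pcoa,
    permutation_anova,
    select_mems,
    varpart3,
)
from mothscape.synthdata import simulate_dataset

from conftest import make_config, toy_genotypes


class TestPCoA:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.random((5, 2)) * 10
        res = pcoa(squareform(pdist(pts)))
        assert np.abs(squareform(pdist(res.coordinates))
                      - squareform(pdist(pts))).max() < 1e-8

    def test_zero_matrix_zero_eigenvalues(self):
        res = pcoa(np.zeros((4, 4)))
        assert np.allclose(res.eigenvalues, 0)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_input_no_negative_eigenvalues(self):
        rng = np.random.default_rng(1)
        res = pcoa(squareform(pdist(rng.random((10, 4)))))
        assert res.n_negative == 0

    def test_asymmetric_rejected(self):
        M = np.arange(9.0).reshape(3, 3)
        with pytest.raises(MothscapeError):
            pcoa(M)


class TestDbMEM:
    def test_collinear_worked_example(self):
        coords = np.array([[0, 0], [1, 0], [5, 0]], float)
        basis = dbmem(coords)
        assert basis.msd == 4.0
        assert basis.threshold == 16.0

    def test_threshold_is_four_times_msd_on_random_configs(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            coords = rng.random((int(rng.integers(5, 30)), 2)) * 100
            basis = dbmem(coords)
            assert basis.threshold == 4.0 * basis.msd
            assert basis.vectors.shape[1] <= coords.shape[0] - 1

    def test_first_eigenvector_broadest_scale(self):
        # on a regular lattice the leading MEM has the largest Moran's I
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        basis = dbmem(coords)
        D = squareform(pdist(coords))
        W = ((D > 0) & (D <= basis.threshold)).astype(float)
        eye = [morans_i(basis.vectors[:, k], W)
               for k in range(basis.vectors.shape[1])]
        assert np.argmax(eye) == 0

    def test_coincident_points_rejected(self):
        coords = np.zeros((4, 2))
        with pytest.raises(MothscapeError):
            dbmem(coords)

    def test_paper_literal_mode_uses_threshold_replacement(self):
        coords = np.array([[0, 0], [1, 0], [5, 0]], float)
        basis = dbmem(coords, truncation="paper-literal")
        assert basis.replacement == basis.threshold


class TestSelectMems:
    def test_null_retention_near_alpha(self):
        rng = np.random.default_rng(3)
        rates = []
        for rep in range(100):
            coords = rng.random((25, 2)) * 100
            basis = dbmem(coords)
            noise = rng.standard_normal((25, 5))
            D = as_square(squareform(pdist(noise)))
            retained, table = select_mems(basis, D, n_perm=99, seed=rep)
            rates.append(len(retained) / basis.vectors.shape[1])
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_signal_eigenvector_recovered(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 20
        for rep in range(reps):
            coords = rng.random((30, 2)) * 100
            basis = dbmem(coords)
            signal = basis.vectors[:, 1]
            Y = np.column_stack([signal * 5, rng.standard_normal(30) * 0.5])
            D = as_square(squareform(pdist(Y)))
            retained, _ = select_mems(basis, D, n_perm=99, seed=rep)
            hits += 1 in retained
        assert hits / reps >= 0.95

    def test_empty_retention_allowed(self):
        rng = np.random.default_rng(5)
        coords = rng.random((15, 2)) * 100
        basis = dbmem(coords)
        D = as_square(squareform(pdist(rng.standard_normal((15, 4)))))
        retained, _ = select_mems(basis, D, n_perm=49, seed=1)
        assert isinstance(retained, np.ndarray)  # possibly empty, no crash


class TestEnvPCA:
    def _stack(self, layers, seed=0):
        rng = np.random.default_rng(seed)
        data = np.stack([rng.random((12, 12)) for _ in range(layers)])
        return RasterStack(names=[f"env{k + 1}" for k in range(layers)],
                           data=data)

    def test_duplicated_layer_adds_no_retained_pc(self):
        stack = self._stack(3)
        dup = RasterStack(names=stack.names + ["env4"],
                          data=np.concatenate([stack.data,
                                               stack.data[:1]]),
                          cell_size=stack.cell_size)
        base = env_raster_pca(stack)
        extra = env_raster_pca(dup)
        assert extra.var_frac[-1] < 1e-10

    def test_variance_fractions_sum_to_one(self):
        res = env_raster_pca(self._stack(5))
        assert abs(res.var_frac.sum() - 1) < 1e-8

    def test_loadings_orthonormal(self):
        res = env_raster_pca(self._stack(4))
        Q = res.loadings.to_numpy()
        assert np.allclose(Q.T @ Q, np.eye(Q.shape[1]), atol=1e-10)


class TestGenotypePCA:
    def test_two_clusters_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        p1 = rng.uniform(0.1, 0.9, 300)
        p2 = np.clip(p1 + rng.choice([-0.4, 0.4], 300), 0.02, 0.98)
        X = np.vstack([rng.binomial(2, p1, (25, 300)),
                       rng.binomial(2, p2, (25, 300))]).astype(float)
        scores, frac = pca_genotypes(toy_genotypes(X))
        labels = np.r_[np.zeros(25), np.ones(25)]
        assert silhouette_score(scores[:, :1], labels) > 0.5

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.4, (20, 50)).astype(float)
        _, frac = pca_genotypes(toy_genotypes(X))
        assert (np.diff(frac) <= 1e-12).all()

    def test_full_rank_scores_reproduce_distances(self):
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.5, (15, 40)).astype(float)
        g = toy_genotypes(X)
        scores, _ = pca_genotypes(g)
        assert np.allclose(squareform(pdist(scores)),
                           genetic_distance(g).values, atol=1e-8)


class TestDAPC:
    def test_strong_separation_high_success(self):
        cfg = make_config(host_effect=3.0, frac_host_loci=0.3, ibd_sd=0.0,
                          env_effect=0.0, frac_env_loci=0.0, host_mixing=1.0,
                          n_individuals=80, n_loci=500, seed=41)
        _, _, samples, g, _ = simulate_dataset(cfg)
        res = dapc_xval(g, samples["host"].to_numpy(), replicates=20, seed=1)
        assert res.success[res.chosen] >= 0.9
        assert res.chosen in res.candidates

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.5, (80, 300)).astype(float)
        labels = np.repeat(list("abcd"), 20)
        res = dapc_xval(toy_genotypes(X), labels, replicates=30, seed=2)
        assert abs(res.success[res.chosen] - 0.25) < 0.12


class TestDbRDA:
    def test_matches_classical_rda_on_euclidean_coordinates(self):
        rng = np.random.default_rng(10)
        Y0 = rng.random((20, 3))
        D = as_square(squareform(pdist(Y0)))
        X = pd.DataFrame(rng.random((20, 2)), columns=["a", "b"])
        m = dbrda_fit(D, env=X)
        Yc = Y0 - Y0.mean(0)
        Xs = X.to_numpy() - X.to_numpy().mean(0)
        Xs = Xs / Xs.std(0)
        Xs = Xs - Xs.mean(0)
        coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
        r2_classic = np.sum((Xs @ coef) ** 2) / np.sum(Yc ** 2)
        assert abs(m.r2 - r2_classic) < 1e-10

    def test_deterministic_response_fully_explained(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((25, 3)),
                         columns=["a", "b", "c"])
        Y = X.to_numpy() @ rng.standard_normal((3, 4))
        Y += rng.standard_normal(Y.shape) * 1e-4
        D = as_square(squareform(pdist(Y)))
        m = dbrda_fit(D, env=X)
        assert m.r2 > 0.99

    def test_orthonormal_predictors_unit_vif(self):
        rng = np.random.default_rng(12)
        Q, _ = np.linalg.qr(rng.standard_normal((20, 2)))
        X = pd.DataFrame(Q, columns=["q1", "q2"])
        D = as_square(squareform(pdist(rng.random((20, 2)))))
        m = dbrda_fit(D, env=X, standardize=False)
        assert np.allclose(m.vif["vif"], 1.0, atol=1e-8)

    def test_duplicated_predictor_rejected(self):
        rng = np.random.default_rng(13)
        v = rng.random(20)
        X = pd.DataFrame({"a": v, "b": v})
        D = as_square(squareform(pdist(rng.random((20, 2)))))
        with pytest.raises(MothscapeError, match="collinear"):
            dbrda_fit(D, env=X)

    def test_raw_r2_non_decreasing_adjusted_penalizes(self):
        rng = np.random.default_rng(14)
        D = as_square(squareform(pdist(rng.random((25, 3)))))
        X = pd.DataFrame(rng.standard_normal((25, 5)),
                         columns=list("abcde"))
        r2s, adj = [], []
        for k in (1, 3, 5):
            m = dbrda_fit(D, env=X.iloc[:, :k])
            r2s.append(m.r2)
            adj.append(m.adj_r2)
        assert r2s[0] <= r2s[1] <= r2s[2]
        assert adj[2] < r2s[2]

    def test_host_term_df_is_levels_minus_one(self):
        rng = np.random.default_rng(15)
        D = as_square(squareform(pdist(rng.random((24, 3)))))
        host = np.repeat(list("abcd"), 6)
        m = dbrda_fit(D, host=host)
        tab = permutation_anova(m, n_perm=19, seed=0)
        assert int(tab.loc[tab["term"] == "host", "df"].iloc[0]) == 3


class TestPermutationAnova:
    def test_pseudo_f_matches_brute_force(self):
        rng = np.random.default_rng(16)
        D = as_square(squareform(pdist(rng.random((20, 3)))))
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        m = dbrda_fit(D, env=X)
        tab = permutation_anova(m, n_perm=9, seed=0)
        Y, Xm = m.Y, m.X
        n, p = Xm.shape
        for t, cols in enumerate([[0], [1]]):
            Xr = Xm[:, [k for k in range(p) if k not in cols]]
            coef_r, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
            ss_red = np.sum((Xr @ coef_r) ** 2)
            ss_term = m.ss_explained - ss_red
            F = (ss_term / 1) / ((m.ss_total - m.ss_explained) / (n - 1 - p))
            assert abs(tab["F"].iloc[t] - F) < 1e-10

    def test_host_effect_power(self):
        hits = 0
        reps = 10
        for rep in range(reps):
            cfg = make_config(ibd_sd=0.3, env_effect=0.0, host_effect=1.0,
                              frac_env_loci=0.0, frac_host_loci=0.1,
                              n_individuals=100, n_loci=1000, seed=300 + rep)
            _, _, samples, g, _ = simulate_dataset(cfg)
            m = dbrda_fit(genetic_distance(g),
                          host=samples["host"].to_numpy())
            tab = permutation_anova(m, n_perm=99, seed=rep)
            hits += tab["p"].iloc[0] <= 0.05
        assert hits / reps >= 0.8


class TestVarpart:
    def test_orthogonal_sets_have_no_shared_fractions(self):
        rng = np.random.default_rng(17)
        n = 60
        Q, _ = np.linalg.qr(rng.standard_normal((n, 6)))
        G = pd.DataFrame(Q[:, :2], columns=["g1", "g2"])
        E = pd.DataFrame(Q[:, 2:4], columns=["e1", "e2"])
        H = pd.DataFrame(Q[:, 4:6], columns=["h1", "h2"])
        Y = (Q[:, :2].sum(1) + Q[:, 2:4].sum(1) + Q[:, 4:6].sum(1))[:, None]
        Y = np.column_stack([Y, rng.standard_normal(n) * 0.5])
        vp = varpart3(as_square(squareform(pdist(Y))), G, E, H,
                      standardize=False)
        for key in ("shared_GE", "shared_EH", "shared_GH", "shared_GEH"):
            assert abs(vp.fractions[key]) < 0.05

    def test_fractions_sum_to_full_adjusted_r2(self):
        rng = np.random.default_rng(18)
        D = as_square(squareform(pdist(rng.random((30, 3)))))
        G = pd.DataFrame(rng.standard_normal((30, 2)), columns=["g1", "g2"])
        E = pd.DataFrame(rng.standard_normal((30, 2)), columns=["e1", "e2"])
        H = pd.DataFrame(rng.standard_normal((30, 1)), columns=["h1"])
        vp = varpart3(D, G, E, H)
        assert abs(sum(vp.fractions.values()) - vp.adj_r2_full) < 1e-10
        assert abs(vp.residual - (1 - vp.adj_r2_full)) < 1e-12

    def test_geography_only_signal_recovered(self):
        rng = np.random.default_rng(19)
        uniques = {"G": [], "E": [], "H": []}
        for rep in range(20):
            cfg = make_config(ibd_sd=1.0, env_effect=0.0, host_effect=0.0,
                              frac_env_loci=0.0, frac_host_loci=0.0,
                              n_individuals=60, n_loci=500, seed=500 + rep)
            _, _, samples, g, _ = simulate_dataset(cfg)
            basis = dbmem(samples)
            k = min(3, basis.vectors.shape[1])
            geo = pd.DataFrame(basis.vectors[:, :k],
                               columns=[f"M{j + 1}" for j in range(k)])
            E = pd.DataFrame({"e": rng.standard_normal(60)})
            H = pd.DataFrame({"h": rng.standard_normal(60)})
            vp = varpart3(genetic_distance(g), geo, E, H)
            for k in uniques:
                uniques[k].append(vp.fractions[f"unique_{k}"])
        assert np.mean(uniques["G"]) > 0
        assert abs(np.mean(uniques["E"])) < 0.01
        assert abs(np.mean(uniques["H"])) < 0.01

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(20)
        D = as_square(squareform(pdist(rng.random((5, 2)))))
        F = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
        with pytest.raises(MothscapeError):
            varpart3(D, F, F.copy().rename(columns={"a": "c", "b": "d"}),
                     F.copy().rename(columns={"a": "e", "b": "f"}))
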