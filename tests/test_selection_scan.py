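"""FST estimation, outlier scan, latent-factor GEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mothscape._core import MothscapeError
from mothscape.selection_scan import (
    _wc_components,
    assign_strongest,
    fst_outlier_scan,
    gea_scan,
    gif_calibrate,
    latent_factors,
    multi_test_correct,
    pairwise_host_fst,
    wc_fst,
)
from mothscape.synthdata import simulate_dataset

from conftest import make_config, neutral_config, toy_genotypes


def wc_two_group_by_hand(d1, d2):
    """Direct scalar transcription of the 1984 two-group formulas."""
    r = 2
    n1, n2 = len(d1), len(d2)
    p1, p2 = sum(d1) / (2 * n1), sum(d2) / (2 * n2)
    h1 = sum(1 for v in d1 if v == 1) / n1
    h2 = sum(1 for v in d2 if v == 1) / n2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                           - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_fixed_differences_theta_one(self):
        X = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], float)
        res = wc_fst(X, np.array(["a", "a", "b", "b"]))
        assert np.allclose(res.theta, 1.0)
        assert res.overall == 1.0

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, np.tile(rng.uniform(0.1, 0.9, 3000),
                                    (60, 1))).astype(float)
        res = wc_fst(X, np.array(["a"] * 30 + ["b"] * 30))
        assert abs(res.overall) < 0.005

    def test_hand_built_locus_matches_formula_arithmetic(self):
        # group sizes 10/10, fixed allele and heterozygote counts
        d1 = [2] * 3 + [1] * 4 + [0] * 3   # p=0.5, het=0.4
        d2 = [2] * 1 + [1] * 2 + [0] * 7   # p=0.2, het=0.2
        X = np.array(d1 + d2, float)[:, None]
        res = wc_fst(X, np.array(["a"] * 10 + ["b"] * 10))
        a, b, c = wc_two_group_by_hand(d1, d2)
        assert abs(res.a[0] - a) < 1e-12
        assert abs(res.b[0] - b) < 1e-12
        assert abs(res.c[0] - c) < 1e-12
        assert abs(res.theta[0] - a / (a + b + c)) < 1e-12

    def test_exhaustive_small_configurations(self):
        # every two-group dosage configuration with group sizes <= 3 (and a
        # random sweep at sizes 4-5) matches the direct formulas
        import itertools

        for n1, n2 in [(2, 2), (2, 3), (3, 3)]:
            for d1 in itertools.product((0, 1, 2), repeat=n1):
                for d2 in itertools.product((0, 1, 2), repeat=n2):
                    X = np.array(d1 + d2, float)[:, None]
                    labels = np.array(["a"] * n1 + ["b"] * n2)
                    a, b, c = _wc_components(X, labels)
                    ao, bo, co = wc_two_group_by_hand(list(d1), list(d2))
                    assert abs(a[0] - ao) < 1e-12
                    assert abs(b[0] - bo) < 1e-12
                    assert abs(c[0] - co) < 1e-12
        rng = np.random.default_rng(1)
        for _ in range(200):
            n1, n2 = rng.integers(4, 6, 2)
            d1 = list(rng.integers(0, 3, n1))
            d2 = list(rng.integers(0, 3, n2))
            a, b, c = _wc_components(np.array(d1 + d2, float)[:, None],
                                     np.array(["a"] * n1 + ["b"] * n2))
            ao, bo, co = wc_two_group_by_hand(d1, d2)
            assert max(abs(a[0] - ao), abs(b[0] - bo), abs(c[0] - co)) < 1e-12

    def test_overall_is_ratio_of_sums(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.4, (20, 50)).astype(float)
        res = wc_fst(X, np.array(["a"] * 10 + ["b"] * 10))
        ok = np.isfinite(res.theta)
        assert np.isclose(res.overall,
                          res.a[ok].sum()
                          / (res.a + res.b + res.c)[ok].sum())
        # not the mean of per-locus ratios in general
        assert not np.isclose(res.overall, np.nanmean(res.theta), atol=1e-6)

    def test_six_pairwise_comparisons_for_four_hosts(self, structured_dataset):
        d = structured_dataset
        results = pairwise_host_fst(d["genotypes"],
                                    d["samples"]["host"].to_numpy())
        assert len(results) == 6
        assert len({r.pair for r in results}) == 6


class TestOutlierScan:
    def test_neutral_data_no_outliers(self):
        # BH controls the familywise false-positive replicate rate near the
        # 5% FDR level; most neutral replicates must be outlier-free
        misses = 0
        reps = 40
        for rep in range(reps):
            cfg = neutral_config(700 + rep, n_loci=300)
            _, _, samples, g, _ = simulate_dataset(cfg)
            scan = fst_outlier_scan(g, samples["host"].to_numpy(),
                                    n_perm=200, seed=rep)
            misses += int(scan.outliers.sum()) == 0
        assert misses / reps >= 0.9

    def test_host_linked_loci_detected(self):
        cfg = make_config(ibd_sd=0.0, env_effect=0.0, host_effect=2.0,
                          frac_env_loci=0.0, frac_host_loci=0.01,
                          host_mixing=1.0, n_individuals=150, n_loci=1000,
                          seed=71)
        _, _, samples, g, truth = simulate_dataset(cfg)
        scan = fst_outlier_scan(g, samples["host"].to_numpy(), n_perm=500,
                                seed=3)
        linked = np.nonzero((truth.loci["class"] == "host").to_numpy())[0]
        assert scan.outliers[linked].sum() >= 8

    def test_null_pvalues_uniform(self):
        cfg = neutral_config(73, n_loci=1000, n_individuals=80)
        _, _, samples, g, _ = simulate_dataset(cfg)
        scan = fst_outlier_scan(g, samples["host"].to_numpy(), n_perm=500,
                                seed=5)
        p = scan.p[np.isfinite(scan.p)]
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestLatentFactors:
    def test_two_cluster_factor_separates(self):
        rng = np.random.default_rng(3)
        p1 = rng.uniform(0.1, 0.9, 500)
        p2 = np.clip(p1 + rng.choice([-0.35, 0.35], 500), 0.02, 0.98)
        X = np.vstack([rng.binomial(2, p1, (30, 500)),
                       rng.binomial(2, p2, (30, 500))]).astype(float)
        lf = latent_factors(toy_genotypes(X), K=1)
        labels = np.r_[np.zeros(30), np.ones(30)]
        r = np.corrcoef(lf.scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.5, (40, 200)).astype(float)
        lf = latent_factors(toy_genotypes(X), K=5)
        assert np.allclose(lf.scores.T @ lf.scores, np.eye(5), atol=1e-10)

    def test_k_zero_empty_block(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, 0.5, (10, 50)).astype(float)
        lf = latent_factors(toy_genotypes(X), K=0)
        assert lf.scores.shape == (10, 0)

    def test_k_beyond_rank_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.5, (5, 50)).astype(float)
        with pytest.raises(MothscapeError):
            latent_factors(toy_genotypes(X), K=5)


class TestGEA:
    def test_env_linked_locus_attains_max_z(self):
        hits = 0
        reps = 15
        for rep in range(reps):
            cfg = make_config(ibd_sd=0.0, host_effect=0.0, env_effect=2.0,
                              frac_env_loci=0.001, frac_host_loci=0.0,
                              n_individuals=100, n_loci=1000, seed=900 + rep)
            _, _, samples, g, truth = simulate_dataset(cfg)
            linked = np.nonzero((truth.loci["class"] == "env").to_numpy())[0]
            var = truth.loci.loc[linked[0], "variable"]
            gea = gea_scan(g, samples[[var]], K=0, runs=1, seed=rep)
            hits += np.argmax(np.abs(gea.z[:, 0])) == linked[0]
        assert hits / reps >= 0.85

    def test_lambda_near_one_with_true_k(self):
        # two-cluster confounding controlled by K=1
        rng = np.random.default_rng(7)
        lams = []
        for rep in range(5):
            p1 = rng.uniform(0.2, 0.8, 800)
            p2 = np.clip(p1 + rng.choice([-0.2, 0.2], 800), 0.05, 0.95)
            X = np.vstack([rng.binomial(2, p1, (40, 800)),
                           rng.binomial(2, p2, (40, 800))]).astype(float)
            env = pd.DataFrame(
                {"env1": np.r_[rng.standard_normal(40) - 1,
                               rng.standard_normal(40) + 1]})
            gea = gea_scan(toy_genotypes(X), env, K=1, runs=1, seed=rep)
            lams.append(gea.lam[0])
        assert abs(np.mean(lams) - 1.0) < 0.1

    def test_unrelated_env_no_bonferroni_hits(self):
        # Bonferroni holds the familywise error near 5%: most neutral
        # replicates yield no significant association at all
        clean = 0
        reps = 40
        rng = np.random.default_rng(8)
        for rep in range(reps):
            cfg = neutral_config(800 + rep, n_loci=400)
            _, _, samples, g, _ = simulate_dataset(cfg)
            env = pd.DataFrame({"envx": rng.standard_normal(g.n_samples)})
            gea = gea_scan(g, env, K=0, runs=1, seed=rep)
            clean += int(gea.bonferroni.sum()) == 0
        assert clean / reps >= 0.9

    def test_detection_rate_monotone_in_effect_size(self):
        rates = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            found = []
            for rep in range(5):
                cfg = make_config(ibd_sd=0.0, host_effect=0.0,
                                  env_effect=effect, frac_env_loci=0.05,
                                  frac_host_loci=0.0, n_individuals=100,
                                  n_loci=400, seed=1100 + rep)
                _, _, samples, g, truth = simulate_dataset(cfg)
                gea = gea_scan(g, samples[["env1"]], K=0, runs=1, seed=rep)
                linked = (truth.loci["variable"] == "env1").to_numpy()
                if effect == 0:
                    found.append(0.0)
                else:
                    found.append(gea.bonferroni[linked, 0].mean())
            rates.append(np.mean(found))
        assert all(rates[k] <= rates[k + 1] + 0.05 for k in range(3))
        assert rates[-1] > rates[0]


class TestCalibration:
    def test_gif_null_lambda_and_uniform_adjusted_p(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(10000)
        lam, p_adj = gif_calibrate(z)
        assert 0.95 <= lam <= 1.05
        assert stats.kstest(p_adj, "uniform").pvalue > 0.01

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal(500)
        lam1, _ = gif_calibrate(z)
        lam2, _ = gif_calibrate(2 * z)
        assert np.isclose(lam2, 4 * lam1)

    def test_all_zero_z_rejected(self):
        with pytest.raises(MothscapeError):
            gif_calibrate(np.zeros(10))


class TestMultipleTesting:
    def test_bh_step_up_by_hand(self):
        q, _ = multi_test_correct(np.array([0.01, 0.02, 0.03, 0.04]), "bh")
        assert np.allclose(q, 0.04)

    def test_bonferroni_capped(self):
        corrected, _ = multi_test_correct(
            np.array([0.3, 0.01, 0.5, 0.9]), "bonferroni")
        assert corrected[0] == 1.0
        assert np.isclose(corrected[1], 0.04)

    def test_bh_bounds(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.001, 1, 50)
        q, _ = multi_test_correct(p, "bh")
        assert (q <= 1).all()
        assert (q >= p - 1e-12).all()


class TestAssignStrongest:
    def _fake_result(self, z, bonf):
        from mothscape.selection_scan import GEAResult

        z = np.asarray(z, float)
        return GEAResult(variables=["A", "B"], z=z, lam=np.ones(2),
                         p_adj=np.ones_like(z),
                         bonferroni=np.asarray(bonf, bool),
                         bh=np.asarray(bonf, bool), K=0, runs=1)

    def test_largest_median_z_wins(self):
        res = self._fake_result([[5.0, 3.0]], [[True, True]])
        tab = assign_strongest(res)
        assert list(tab["variable"]) == ["A"]

    def test_no_significant_loci_empty(self):
        res = self._fake_result([[1.0, 0.5]], [[False, False]])
        assert assign_strongest(res).empty

    def test_recovery_of_true_variable(self, ):
        cfg = make_config(ibd_sd=0.0, host_effect=0.0, env_effect=2.0,
                          frac_env_loci=0.05, frac_host_loci=0.0,
                          n_individuals=120, n_loci=500, seed=55)
        _, _, samples, g, truth = simulate_dataset(cfg)
        env_cols = [c for c in samples.columns if c.startswith("env")]
        gea = gea_scan(g, samples[env_cols], K=0, runs=1, seed=1)
        merged = gea.strongest.merge(
            truth.loci[["locus", "variable", "class"]],
            on="locus", suffixes=("_called", "_true"))
        linked = merged[merged["class"] == "env"]
        if len(linked) >= 5:
            agree = (linked["variable_called"]
                     == linked["variable_true"]).mean()
            assert agree >= 0.8
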