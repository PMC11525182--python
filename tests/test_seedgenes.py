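"""Burden and SKAT score tests: closed-form checks, independent oracles
(projection-matrix algebra, Monte-Carlo mixture sampling, permutation at
small scale), collapsing rules and the Bonferroni combination."""

import numpy as np
import pytest
from scipy import stats

import setrvat as sv
from setrvat.seedgenes import (
    NullModel,
    beta_weight,
    burden_score_test,
    chi2_mixture_sf,
    collapse_ultra_rare,
    combine_gene_pvalues,
    fit_null_linear,
    fit_null_logistic,
    skat_test,
    weighted_burden,
)


class TestBetaWeight:
    def test_at_zero(self):
        assert beta_weight(0.0) == pytest.approx(25.0)

    def test_at_one_percent(self):
        assert beta_weight(0.01) == pytest.approx(25 * 0.99 ** 24, rel=1e-10)

    def test_at_half(self):
        assert beta_weight(0.5) == pytest.approx(25 * 0.5 ** 24, rel=1e-10)

    def test_vectorised_matches_scalar(self):
        p = np.array([0.0, 0.001, 0.01, 0.1])
        assert np.allclose(beta_weight(p), [beta_weight(x) for x in p])


class TestCollapseUltraRare:
    def test_identity_when_all_common(self):
        G = np.tile(np.arange(3.0), (20, 1))  # MAC 20 and 40 per column
        out, _ = collapse_ultra_rare(G[:, 1:], mac_threshold=10)
        assert np.array_equal(out, G[:, 1:])

    def test_disjoint_singletons_union(self):
        G = np.zeros((10, 2))
        G[2, 0] = 1
        G[7, 1] = 1
        out, _ = collapse_ultra_rare(G, mac_threshold=10)
        assert out.shape == (10, 1)
        assert (out[:, 0] > 0).sum() == 2

    def test_max_rule_for_multi_carrier(self):
        G = np.zeros((10, 2))
        G[3, 0] = 1
        G[3, 1] = 2
        out, _ = collapse_ultra_rare(G, mac_threshold=10)
        assert out[3, 0] == 2.0

    def test_weights_follow_pseudo_marker(self):
        G = np.zeros((100, 3))
        G[0, 0] = 1
        G[1, 1] = 1
        G[:40, 2] = 1  # MAC 40: kept
        w = beta_weight(G.sum(axis=0) / 200.0)
        out, w2 = collapse_ultra_rare(G, weights=w)
        assert out.shape[1] == 2 and w2.size == 2
        assert w2[0] == pytest.approx(w[2])


class TestBurdenScoreTest:
    def test_worked_instance_matches_projection_algebra(self):
        # independent oracle: explicit hat-matrix algebra on fixed vectors
        y = np.array([0.3, -1.2, 0.5, 2.0, -0.4, 0.8])
        g = np.array([0.0, 1.0, 0.0, 2.0, 1.0, 0.0])
        X = np.ones((6, 1))
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        r = (np.eye(6) - H) @ y
        gt = (np.eye(6) - H) @ g
        sigma2 = r @ r / (6 - 1)
        T_expected = (gt @ r) ** 2 / (sigma2 * (gt @ gt))
        res = burden_score_test(g, fit_null_linear(y, X))
        assert res.statistic == pytest.approx(T_expected, abs=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(T_expected, 1), abs=1e-12)

    def test_orthogonal_burden_gives_null(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        g = np.array([1.0, 1.0, -1.0, -1.0])
        res = burden_score_test(g, fit_null_linear(y, np.ones((4, 1))))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_collinear_burden_warns_p_one(self):
        y = np.random.default_rng(0).normal(size=20)
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        res = burden_score_test(2.0 + 3.0 * np.arange(20.0), fit_null_linear(y, X))
        assert res.p_value == 1.0

    def test_rank_deficient_covariates_raise(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(sv.DataError):
            fit_null_linear(np.arange(10.0), X)

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.05, size=n).astype(float)
        A = np.array([[1, 0, 0, 0], [2, 3, 0, 1], [0, 1, 5, 0], [1, 0, 2, 4.0]])
        r1 = burden_score_test(g, fit_null_linear(y, X))
        r2 = burden_score_test(g, fit_null_linear(y, X @ A))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-8)

    def test_permutation_oracle_small(self, rng):
        # 20,000 label permutations at n=200 with intercept-only null
        n = 200
        g = rng.binomial(2, 0.05, size=n).astype(float)
        y = 0.25 * g + rng.normal(size=n)
        null = fit_null_linear(y, np.ones((n, 1)))
        res = burden_score_test(g, null)
        gt = g - g.mean()
        B = 20_000
        perms = rng.permuted(np.tile(y, (B, 1)), axis=1)
        t_obs = (gt @ y) ** 2
        t_perm = (perms @ gt) ** 2
        p_perm = (np.sum(t_perm >= t_obs - 1e-12) + 1) / (B + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p_value - p_perm) <= 3 * max(se, 1e-4)

    def test_logistic_null_calibration(self, rng):
        n, reps = 400, 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.binomial(1, 0.3, size=n).astype(float)
        null = fit_null_logistic(y, X)
        ps = []
        for _ in range(reps):
            g = rng.binomial(2, 0.05, size=n).astype(float)
            ps.append(burden_score_test(g, null).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSkat:
    def _null_and_G(self, rng, n=300, m=5):
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        G = rng.binomial(2, 0.03, size=(n, m)).astype(float)
        return fit_null_linear(y, X), G

    def test_single_marker_equals_burden(self, rng):
        null, G = self._null_and_G(rng, m=1)
        w = np.array([beta_weight(0.03)])
        p_skat = skat_test(G, w, null, collapse=False).p_value
        p_burden = burden_score_test(weighted_burden(G, w), null).p_value
        assert p_skat == pytest.approx(p_burden, abs=1e-6)

    def test_marker_order_invariance(self, rng):
        null, G = self._null_and_G(rng)
        w = np.full(5, 2.0)
        q1 = skat_test(G, w, null, collapse=False)
        perm = [3, 1, 4, 0, 2]
        q2 = skat_test(G[:, perm], w[perm], null, collapse=False)
        assert q1.statistic == pytest.approx(q2.statistic, rel=1e-10)
        assert q1.p_value == pytest.approx(q2.p_value, rel=1e-8)

    def test_statistic_monotone_in_weight_magnitude(self, rng):
        null, G = self._null_and_G(rng)
        w = np.full(5, 1.0)
        q1 = skat_test(G, w, null, collapse=False).statistic
        w2 = w.copy()
        w2[0] = 3.0
        q2 = skat_test(G, w2, null, collapse=False).statistic
        assert q2 >= q1

    def test_marker_limit_skip(self):
        G = np.zeros((10, 5001))
        G[0, :] = 1.0
        res = skat_test(G, np.ones(5001), fit_null_linear(
            np.arange(10.0), np.ones((10, 1))), collapse=False)
        assert res.skipped and res.p_value is None

    def test_all_zero_matrix_p_one(self):
        res = skat_test(np.zeros((10, 3)), np.ones(3),
                        fit_null_linear(np.arange(10.0), np.ones((10, 1))))
        assert res.p_value == 1.0

    def test_permutation_oracle_small(self, rng):
        n, m, B = 200, 5, 5000
        X = np.ones((n, 1))
        G = rng.binomial(2, 0.05, size=(n, m)).astype(float)
        y = 0.2 * G[:, 0] + rng.normal(size=n)
        null = fit_null_linear(y, X)
        w = np.full(m, 1.0)
        res = skat_test(G, w, null, collapse=False)
        GW = G * w
        perms = rng.permuted(np.tile(y - y.mean(), (B, 1)), axis=1)
        q_perm = np.sum((perms @ GW) ** 2, axis=1)
        p_perm = (np.sum(q_perm >= res.statistic - 1e-12) + 1) / (B + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p_value - p_perm) <= 3 * max(se, 1e-3)


class TestChiSquareMixtureTail:
    def test_monte_carlo_oracle(self, rng):
        lam = np.array([2.0, 1.0, 0.5, 0.2])
        draws = rng.chisquare(1, size=(500_000, 4)) @ lam
        for q in (2.0, 6.0, 12.0):
            mc = np.mean(draws >= q)
            se = np.sqrt(mc * (1 - mc) / draws.shape[0])
            assert chi2_mixture_sf(q, lam) == pytest.approx(mc, abs=4 * se)

    def test_single_weight_reduces_to_chi2(self):
        assert chi2_mixture_sf(7.0, np.array([2.0])) == pytest.approx(
            stats.chi2.sf(3.5, 1), rel=1e-10)

    def test_three_approximations_agree_in_moderate_tail(self):
        from setrvat.seedgenes import _imhof_sf, _liu_sf, _saddlepoint_sf

        lam = np.array([1.5, 1.0, 0.7, 0.3, 0.1])
        for q in (5.0, 10.0):
            p_im, err = _imhof_sf(q, lam)
            assert err < 1e-6
            assert _saddlepoint_sf(q, lam) == pytest.approx(p_im, rel=0.05)
            assert _liu_sf(q, lam) == pytest.approx(p_im, abs=1e-2)

    def test_deep_tail_uses_saddlepoint_and_stays_monotone(self):
        lam = np.array([2.0, 1.0, 0.5, 0.2])
        qs = np.linspace(2.0, 120.0, 60)
        ps = [chi2_mixture_sf(q, lam) for q in qs]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-12


class TestCombineGenePvalues:
    def test_bonferroni_of_minimum(self):
        assert combine_gene_pvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(0.04)

    def test_capped_at_one(self):
        assert combine_gene_pvalues([0.5, 0.6, 0.9, 0.95]) == 1.0

    def test_single_p_identity(self):
        assert combine_gene_pvalues([0.123]) == pytest.approx(0.123)

    def test_skipped_tests_excluded_from_multiplier(self):
        assert combine_gene_pvalues([0.01, None, np.nan, 0.05]) == pytest.approx(0.02)

    def test_empty_raises(self):
        with pytest.raises(sv.DataError):
            combine_gene_pvalues([])


class TestDiscovery:
    def test_missense_only_signal_found_without_plof(self):
        cfg = sv.SimulationConfig(
            n_individuals=4000, n_genes=30,
            class_probs=(0.0, 0.9, 0.1, 0.0),  # no pLOF variants at all
            traits=(sv.TraitConfig(name="t", seed_genes=(0, 1, 2, 3, 4),
                                   variance_fraction=0.5),),
            rng_seed=17)
        ds, truth = sv.simulate_cohort(cfg)
        tab = sv.discover_seed_genes(ds, "t", truth.assignment)
        assert tab["p_plof_burden"].isna().all()
        found = set(tab.loc[tab["seed"], "gene"]) & set(truth.seed_genes["t"])
        assert len(found) >= 2

    def test_null_trait_yields_no_seeds(self, small_cohort):
        _, dataset, truth = small_cohort
        tab = sv.discover_seed_genes(dataset, "null", truth.assignment,
                                     apply_eaf=False)
        assert tab["seed"].sum() <= 1

    def test_burden_p_uniform_under_null(self, rng):
        # marginal calibration of the weighted-burden score test
        n, genes = 300, 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        null = fit_null_linear(y, X)
        ps = np.empty(genes)
        for i in range(genes):
            G = rng.binomial(2, rng.uniform(0.01, 0.05), size=(n, 4)).astype(float)
            ps[i] = burden_score_test(weighted_burden(G, np.ones(4)), null).p_value
        assert stats.kstest(ps, "uniform").pvalue > 0.01
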