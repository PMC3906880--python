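import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

import cormclust as cc
from cormclust.clmm import SuffStats, _e_step, _m_step
from cormclust.design import GeneDesign

from conftest import make_dataset


def dense_gaussian_loglik(y, X, Z, beta, D, sigma2):
    """Independent oracle: explicit marginal covariance, dense density."""
    V = Z @ D @ Z.T + sigma2 * np.eye(len(y))
    return multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


def toy_params(p=2, q=1, K=1, seed=0):
    rng = np.random.default_rng(seed)
    beta = rng.normal(size=(K, p))
    D = np.stack([np.atleast_2d(0.5 + rng.random()) if q == 1 else 0.3 * np.eye(q) for _ in range(K)])
    if q == 0:
        D = np.zeros((K, 0, 0))
    return cc.ClmmParams(np.full(K, 1.0 / K), beta, D, 0.2 + rng.random(K))


class TestMarginalLoglik:
    def test_single_observation_at_mean(self):
        params = cc.ClmmParams([1.0], [[2.0]], np.zeros((1, 1, 1)), [0.7])
        design = GeneDesign(np.array([[1.0]]), np.array([[1.0]]), 1)
        y = np.array([2.0])  # y = X beta exactly
        expected = -0.5 * np.log(2 * np.pi * 0.7)
        assert cc.marginal_loglik_gene(y, design, 0, params) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3, 2))
        Z = rng.normal(size=(3, 1))
        y = rng.normal(size=3)
        params = toy_params(p=2, q=1, seed=seed)
        ours = cc.marginal_loglik_gene(y, GeneDesign(X, Z, 3), 0, params)
        oracle = dense_gaussian_loglik(y, X, Z, params.beta[0], params.D[0], params.sigma2[0])
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_sigma2_doubling_identity_at_mean(self):
        X = np.eye(4)
        design = GeneDesign(X, np.zeros((4, 0)), 4)
        beta = np.array([1.0, -1.0, 0.5, 0.0])
        y = X @ beta
        p1 = cc.ClmmParams([1.0], beta[None], np.zeros((1, 0, 0)), [0.3])
        p2 = cc.ClmmParams([1.0], beta[None], np.zeros((1, 0, 0)), [0.6])
        l1 = cc.marginal_loglik_gene(y, design, 0, p1)
        l2 = cc.marginal_loglik_gene(y, design, 0, p2)
        assert l1 - l2 == pytest.approx(2.0 * np.log(2.0))  # (n/2) log 2 with n=4

    def test_dimension_mismatch(self):
        params = toy_params(p=2, q=1)
        with pytest.raises(cc.ShapeError):
            cc.marginal_loglik_gene(np.zeros(3), GeneDesign(np.zeros((3, 5)), np.zeros((3, 1)), 3), 0, params)


class TestESTep:
    def test_single_component_posterior(self, small_dataset):
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0))
        designs = cc.build_designs(small_dataset, spec)
        est = cc.e_step(small_dataset, designs, toy_params(p=2, q=2, K=1, seed=1))
        np.testing.assert_allclose(est.posterior, 1.0)

    def test_equidistant_gene_symmetric_posterior(self):
        ds = make_dataset(G=1, conditions=("WT",), replicates=1, times=(0.0, 5.0, 10.0), fill=0.0)
        spec = cc.DesignSpec(degree=0, n_interior_knots=0, time_range=(0.0, 10.0), random_design="none")
        designs = cc.build_designs(ds, spec)
        params = cc.ClmmParams([0.5, 0.5], [[1.0], [-1.0]], np.zeros((2, 0, 0)), [0.5, 0.5])
        est = cc.e_step(ds, designs, params)
        np.testing.assert_allclose(est.posterior[0], [0.5, 0.5], atol=1e-12)

    def test_posteriors_match_direct_densities(self):
        ds = make_dataset(G=2, conditions=("WT",), replicates=1, times=(0.0, 5.0, 10.0), seed=3)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0), random_design="none")
        designs = cc.build_designs(ds, spec)
        params = toy_params(p=2, q=0, K=2, seed=4)
        est = cc.e_step(ds, designs, params)
        for g in range(2):
            y = ds.values[g]
            dens = np.array(
                [
                    params.pi[k]
                    * np.exp(
                        dense_gaussian_loglik(
                            y, designs[g].X, np.zeros((3, 1)), params.beta[k],
                            np.zeros((1, 1)), params.sigma2[k],
                        )
                    )
                    for k in range(2)
                ]
            )
            np.testing.assert_allclose(est.posterior[g], dens / dens.sum(), atol=1e-12)
        # rows sum to one
        np.testing.assert_allclose(est.posterior.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_saturated_single_cluster_is_column_means(self):
        ds = make_dataset(G=6, conditions=("WT",), replicates=1, times=(0.0, 5.0, 10.0), seed=5)
        n = ds.n_obs
        designs = [GeneDesign(np.eye(n), np.zeros((n, 0)), n, np.arange(n)) for _ in range(6)]
        est = cc.e_step(ds, designs, cc.ClmmParams([1.0], np.zeros((1, n)), np.zeros((1, 0, 0)), [1.0]))
        params = cc.m_step(ds, designs, est)
        np.testing.assert_allclose(params.beta[0], ds.values.mean(axis=0))
        np.testing.assert_allclose(params.sigma2[0], ((ds.values - ds.values.mean(0)) ** 2).mean())

    def test_hard_posteriors_give_pooled_ols(self):
        ds = make_dataset(G=8, conditions=("WT",), replicates=2, times=(0.0, 2.0, 4.0, 6.0), seed=6)
        spec = cc.DesignSpec(degree=1, n_interior_knots=1, time_range=(0.0, 6.0), random_design="none")
        designs = cc.build_designs(ds, spec)
        stats = SuffStats.from_dataset(ds, designs)
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        post = np.zeros((8, 2))
        post[np.arange(8), labels] = 1.0
        params = _m_step(stats, post, np.zeros((8, 2, 0)), np.zeros((8, 2, 0, 0)))
        for k in range(2):
            members = np.flatnonzero(labels == k)
            Xs = np.vstack([designs[g].X for g in members])
            ys = np.concatenate([ds.values[g] for g in members])
            oracle = np.linalg.lstsq(Xs, ys, rcond=None)[0]
            np.testing.assert_allclose(params.beta[k], oracle, atol=1e-10)

    def test_uniform_posteriors_give_identical_clusters(self):
        ds = make_dataset(G=5, seed=7)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0))
        designs = cc.build_designs(ds, spec)
        stats = SuffStats.from_dataset(ds, designs)
        est = _e_step(stats, toy_params(p=2, q=2, K=3, seed=8))
        post = np.full((5, 3), 1.0 / 3.0)
        bhat = np.repeat(est.bhat.mean(axis=1, keepdims=True), 3, axis=1)
        C = np.repeat(est.C.mean(axis=1, keepdims=True), 3, axis=1)
        params = _m_step(stats, post, bhat, C)
        for k in (1, 2):
            np.testing.assert_allclose(params.beta[k], params.beta[0])
            np.testing.assert_allclose(params.sigma2[k], params.sigma2[0])
            np.testing.assert_allclose(params.D[k], params.D[0])


class TestFit:
    def test_figure1_partition_recovered(self):
        ds, labels = cc.simulate_clm_figure1(seed=5)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(1.0, 10.0), random_design="none")
        fit = cc.fit_clmm(ds, spec, 2, seed=0, n_restarts=3)
        assert adjusted_rand_score(labels, fit.map_labels) == 1.0

    def test_k1_matches_dense_marginal_loglik(self):
        ds = make_dataset(G=6, seed=10)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0))
        fit = cc.fit_clmm(ds, spec, 1, seed=0, n_restarts=1)
        np.testing.assert_allclose(fit.posterior, 1.0)
        designs = cc.build_designs(ds, spec)
        oracle = sum(
            dense_gaussian_loglik(
                ds.values[g], designs[g].X, designs[g].Z,
                fit.params.beta[0], fit.params.D[0], fit.params.sigma2[0],
            )
            for g in range(6)
        )
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_loglik_trace_monotone(self):
        ds, _, _ = cc.simulate_lwr_timecourse(cc.SimSpec(n_genes=40, seed=1))
        for hard in (False, True):
            fit = cc.fit_clmm(
                ds, cc.DesignSpec(condition_blocking=True), 3,
                seed=2, n_restarts=2, hard_assign=hard,
            )
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_deterministic_given_seed(self):
        ds, _, _ = cc.simulate_lwr_timecourse(cc.SimSpec(n_genes=30, seed=3))
        spec = cc.DesignSpec(condition_blocking=True)
        a = cc.fit_clmm(ds, spec, 2, seed=9, n_restarts=2)
        b = cc.fit_clmm(ds, spec, 2, seed=9, n_restarts=2)
        np.testing.assert_array_equal(a.map_labels, b.map_labels)
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)

    def test_masking_zero_cells_is_bitwise_noop(self):
        ds, _, _ = cc.simulate_lwr_timecourse(cc.SimSpec(n_genes=30, seed=4))
        spec = cc.DesignSpec(condition_blocking=True)
        a = cc.fit_clmm(ds, spec, 2, seed=1, n_restarts=2)
        b = cc.fit_clmm(cc.mask_entries(ds, []), spec, 2, seed=1, n_restarts=2)
        assert np.array_equal(a.posterior, b.posterior)
        assert np.array_equal(a.params.beta, b.params.beta)
        assert np.array_equal(a.loglik_trace, b.loglik_trace)

    def test_gene_permutation_permutes_outputs(self):
        ds, labels, _ = cc.simulate_lwr_timecourse(cc.SimSpec(n_genes=24, n_clusters=2, seed=5))
        spec = cc.DesignSpec(condition_blocking=True)
        init = np.array(labels)
        fit = cc.fit_clmm(ds, spec, 2, init={"labels": init})
        perm = np.random.default_rng(0).permutation(24)
        ds_p = cc.ExpressionDataset(
            [ds.genes[i] for i in perm], list(ds.observations), ds.values[perm], ds.mask[perm]
        )
        fit_p = cc.fit_clmm(ds_p, spec, 2, init={"labels": init[perm]})
        np.testing.assert_array_equal(fit_p.map_labels, fit.map_labels[perm])
        np.testing.assert_allclose(fit_p.posterior, fit.posterior[perm], atol=1e-9)

    def test_clm_is_nested_in_clmm_at_zero_D(self):
        ds = make_dataset(G=5, seed=11)
        spec_mixed = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0))
        spec_clm = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0), random_design="none")
        beta = np.random.default_rng(1).normal(size=(2, 2))
        sigma2 = np.array([0.4, 0.8])
        p_mixed = cc.ClmmParams([0.5, 0.5], beta, np.zeros((2, 2, 2)), sigma2)
        p_clm = cc.ClmmParams([0.5, 0.5], beta, np.zeros((2, 0, 0)), sigma2)
        ll_mixed = cc.e_step(ds, cc.build_designs(ds, spec_mixed), p_mixed).loglik
        ll_clm = cc.e_step(ds, cc.build_designs(ds, spec_clm), p_clm).loglik
        assert ll_mixed == pytest.approx(ll_clm, abs=1e-8)

    def test_equal_proportions_mode(self):
        ds, _, _ = cc.simulate_lwr_timecourse(cc.SimSpec(n_genes=20, n_clusters=2, seed=6))
        fit = cc.fit_clmm(ds, cc.DesignSpec(condition_blocking=True), 2,
                          seed=0, n_restarts=1, equal_proportions=True)
        np.testing.assert_allclose(fit.params.pi, 0.5)


class TestBlup:
    def test_zero_residual_gives_zero_blup(self):
        ds = make_dataset(G=3, seed=12)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0))
        designs = cc.build_designs(ds, spec)
        params = toy_params(p=2, q=2, K=1, seed=13)
        ds.values[:] = designs[0].X @ params.beta[0]
        est = cc.e_step(ds, designs, params)
        np.testing.assert_allclose(est.bhat, 0.0, atol=1e-10)

    def test_shrinks_to_zero_as_D_vanishes(self):
        ds = make_dataset(G=2, seed=14)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(0.0, 10.0))
        designs = cc.build_designs(ds, spec)
        base = toy_params(p=2, q=2, K=1, seed=15)
        for eps in (1e-2, 1e-5, 1e-8):
            params = cc.ClmmParams(base.pi, base.beta, eps * np.eye(2)[None], base.sigma2)
            est = cc.e_step(ds, designs, params)
            assert np.max(np.abs(est.bhat)) < eps * 1e3

    def test_matches_explicit_formula(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(4, 2))
        Z = rng.normal(size=(4, 1))
        y = rng.normal(size=4)
        params = toy_params(p=2, q=1, seed=17)
        obs = [cc.Observation("WT", "r1", float(t)) for t in range(4)]
        ds = cc.ExpressionDataset(["g1"], obs, y[None], np.ones((1, 4), bool))
        est = cc.e_step(ds, [GeneDesign(X, Z, 4)], params)
        D, s2 = params.D[0], params.sigma2[0]
        V = Z @ D @ Z.T + s2 * np.eye(4)
        oracle = D @ Z.T @ np.linalg.solve(V, y - X @ params.beta[0])
        np.testing.assert_allclose(est.bhat[0, 0], oracle, atol=1e-10)
        # accessor by gene name on a full fit
        fit = cc.fit_clmm(ds, None, 1, designs=[GeneDesign(X, Z, 4)], n_restarts=1, seed=0)
        assert cc.blup(fit, "g1").shape == (1,)
        with pytest.raises(KeyError):
            cc.blup(fit, "nope")


class TestPredict:
    def _fitted(self):
        ds, labels = cc.simulate_clm_figure1(seed=21)
        spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(1.0, 10.0), random_design="none")
        fit = cc.fit_clmm(ds, spec, 2, seed=0, n_restarts=2)
        return ds, spec, fit

    def test_training_gene_round_trip(self):
        ds, spec, fit = self._fitted()
        designs = cc.build_designs(ds, spec)
        post, lab = cc.predict_new_gene(fit.params, ds.values[0], designs[0])
        np.testing.assert_allclose(post, fit.posterior[0], atol=1e-9)
        assert lab == fit.map_labels[0]

    def test_at_the_mean_assignment(self):
        ds, spec, fit = self._fitted()
        designs = cc.build_designs(ds, spec)
        y_new = designs[0].X @ fit.params.beta[0]
        post, lab = cc.predict_new_gene(fit.params, y_new, designs[0])
        assert lab == 0 and post[0] > 0.99

    def test_partial_profile_equals_reduced_design(self):
        ds, spec, fit = self._fitted()
        designs = cc.build_designs(ds, spec)
        keep = np.arange(0, ds.n_obs, 2)
        y_part = ds.values[0][keep]
        d_part = GeneDesign(designs[0].X[keep], designs[0].Z[keep], len(keep))
        post, _ = cc.predict_new_gene(fit.params, y_part, d_part)
        ds_part = cc.mask_entries(ds, [(0, j) for j in range(ds.n_obs) if j not in set(keep.tolist())])
        est = cc.e_step(ds_part, cc.build_designs(ds_part, spec), fit.params)
        np.testing.assert_allclose(post, est.posterior[0], atol=1e-9)

    def test_width_mismatch(self):
        _, _, fit = self._fitted()
        with pytest.raises(cc.ShapeError):
            cc.predict_new_gene(fit.params, np.zeros(3), GeneDesign(np.zeros((3, 9)), np.zeros((3, 0)), 3))


class TestFittedProfiles:
    def test_constant_coefficients_give_constant_profile(self):
        ds = make_dataset(G=4, seed=20)
        spec = cc.DesignSpec(degree=1, n_interior_knots=1, time_range=(0.0, 10.0), random_design="none")
        fit = cc.fit_clmm(ds, spec, 1, seed=0, n_restarts=1)
        fit.params.beta[0][:] = 2.5  # constant on a partition-of-unity basis
        prof = fit.cluster_profiles("WT", np.linspace(0, 10, 7))
        np.testing.assert_allclose(prof, 2.5, atol=1e-12)

    def test_blocked_conditions_are_independent(self):
        ds = make_dataset(G=4, seed=21)
        spec = cc.DesignSpec(degree=1, n_interior_knots=1, time_range=(0.0, 10.0), condition_blocking=True, random_design="none")
        fit = cc.fit_clmm(ds, spec, 1, seed=0, n_restarts=1)
        nb = spec.n_basis
        fit.params.beta[0][:nb] = 0.0  # zero the SM block (conditions sorted)
        prof = fit.cluster_profiles("SM", np.linspace(0, 10, 5))
        np.testing.assert_allclose(prof, 0.0, atol=1e-12)

    def test_profile_at_observed_times_matches_design_rows(self):
        ds = make_dataset(G=4, conditions=("WT",), seed=22)
        spec = cc.DesignSpec(degree=1, n_interior_knots=1, time_range=(0.0, 10.0), random_design="none")
        fit = cc.fit_clmm(ds, spec, 2, seed=0, n_restarts=2)
        designs = cc.build_designs(ds, spec)
        times = ds.times
        prof = fit.cluster_profiles("WT", times)
        for k in range(2):
            np.testing.assert_allclose(prof[k], designs[0].X @ fit.params.beta[k], atol=1e-12)

    def test_grid_outside_range_rejected(self):
        ds = make_dataset(G=3, seed=23)
        spec = cc.DesignSpec(degree=1, n_interior_knots=1, time_range=(0.0, 10.0), random_design="none")
        fit = cc.fit_clmm(ds, spec, 1, seed=0, n_restarts=1)
        with pytest.raises(cc.DomainError):
            fit.cluster_profiles("WT", [11.0])


def test_fit_serialization_round_trip(tmp_path):
    ds, _ = cc.simulate_clm_figure1(seed=2)
    spec = cc.DesignSpec(degree=1, n_interior_knots=0, time_range=(1.0, 10.0), random_design="none")
    fit = cc.fit_clmm(ds, spec, 2, seed=3, n_restarts=2)
    path = tmp_path / "fit.json"
    fit.save_json(path)
    back = cc.ClmmFit.load_json(path)
    np.testing.assert_array_equal(back.map_labels, fit.map_labels)
    np.testing.assert_allclose(back.params.beta, fit.params.beta)
    assert back.spec == fit.spec
    # reloaded artifact supports prediction
    designs = cc.build_designs(ds, back.spec)
    post, _ = cc.predict_new_gene(back.params, ds.values[0], designs[0])
    np.testing.assert_allclose(post, fit.posterior[0], atol=1e-9)
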