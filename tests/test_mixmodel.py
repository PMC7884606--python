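import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

import trajmix
from trajmix.cohort import SubjectRecord, VisitRecord
from trajmix.mixmodel import (
    McmcConfig,
    TrajectoryMixture,
    TrajectoryMixtureModel,
    _Stats,
    _marginal_loglik_stats,
    deviance,
    fit_mixture,
    permute_clusters,
    relabel_chains,
    subject_marginal_loglik,
)

from conftest import make_cohort, toy_manifest


def _model(K, R, rng, pi=None):
    return TrajectoryMixtureModel(
        K=K,
        pi=pi if pi is not None else np.full(K, 1.0 / K),
        mu=rng.normal(size=(K, R, 2)) * 0.5,
        sigma_comp=np.abs(rng.normal(size=(K, R, 2))) + 0.3,
        delta=rng.normal(size=(R, 2)) * 0.1,
        sigma_res=np.abs(rng.normal(size=R)) + 0.3,
    )


class TestMarginalLoglik:
    def test_matches_exact_multivariate_normal(self):
        """The Woodbury closed form equals the dense MVN density with
        covariance X diag(tau^2) X' + sigma^2 I, missing cells omitted."""
        rng = np.random.default_rng(0)
        man = toy_manifest(2)
        ages = [63.0, 65.5, 68.0]
        fa = [
            {"r00": 0.3, "r01": -0.2},
            {"r00": 0.5, "r01": 0.1},
            {"r00": np.nan, "r01": 0.4},
        ]
        subj = SubjectRecord("s0", 1, 0, {}, [VisitRecord("s0", a, f) for a, f in zip(ages, fa)])
        model = _model(2, 2, rng)
        ll = subject_marginal_loglik(model, subj, man)
        t = np.array(ages) - 60.0
        for k in range(2):
            expect = 0.0
            for r, rid in enumerate(man.region_ids):
                m = np.array([np.isfinite(f[rid]) for f in fa])
                X = np.column_stack([np.ones(m.sum()), t[m]])
                y = np.array([f[rid] for f in fa])[m]
                mean = X @ model.mu[k, r] + model.delta[r, 0] * subj.sex
                cov = X @ np.diag(model.sigma_comp[k, r] ** 2) @ X.T
                cov += model.sigma_res[r] ** 2 * np.eye(int(m.sum()))
                expect += multivariate_normal.logpdf(y, mean, cov)
            assert ll[k] == pytest.approx(expect, abs=1e-8)

    def test_agrees_with_monte_carlo_integration(self):
        """2-visit, 1-region case: integrate the trajectory numerically by
        simulation and compare within Monte-Carlo error."""
        rng = np.random.default_rng(1)
        man = toy_manifest(1)
        subj = SubjectRecord(
            "s0", 0, 0, {},
            [VisitRecord("s0", 64.0, {"r00": 0.2}), VisitRecord("s0", 66.5, {"r00": -0.1})],
        )
        model = _model(1, 1, rng, pi=np.array([1.0]))
        ll = subject_marginal_loglik(model, subj, man)[0]
        n = 1_000_000
        a = rng.normal(model.mu[0, 0, 0], model.sigma_comp[0, 0, 0], n)
        s = rng.normal(model.mu[0, 0, 1], model.sigma_comp[0, 0, 1], n)
        t = np.array([4.0, 6.5])
        y = np.array([0.2, -0.1])
        dens = np.ones(n)
        for j in range(2):
            resid = y[j] - (a + s * t[j])
            dens *= np.exp(-0.5 * (resid / model.sigma_res[0]) ** 2) / (
                np.sqrt(2 * np.pi) * model.sigma_res[0]
            )
        est = dens.mean()
        mc_se = dens.std() / np.sqrt(n)
        assert abs(np.exp(ll) - est) < 4 * mc_se

    def test_point_mass_limit_single_visit(self):
        """With the component covariance collapsed, the marginal is the plain
        Gaussian density of y at the cluster mean line."""
        man = toy_manifest(1)
        subj = SubjectRecord("s0", 0, 0, {}, [VisitRecord("s0", 70.0, {"r00": 0.7})])
        model = TrajectoryMixtureModel(
            K=1,
            pi=np.array([1.0]),
            mu=np.array([[[0.5, 0.01]]]),
            sigma_comp=np.full((1, 1, 2), 1e-9),
            delta=np.zeros((1, 2)),
            sigma_res=np.array([0.4]),
        )
        ll = subject_marginal_loglik(model, subj, man)[0]
        mean = 0.5 + 0.01 * 10.0
        expect = -0.5 * np.log(2 * np.pi * 0.4**2) - 0.5 * ((0.7 - mean) / 0.4) ** 2
        assert ll == pytest.approx(expect, abs=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        man = toy_manifest(1)
        mk = lambda y: SubjectRecord(
            "s0", 0, 0, {},
            [VisitRecord("s0", 63.0, {"r00": y[0]}), VisitRecord("s0", 66.0, {"r00": y[1]})],
        )
        model = _model(2, 1, rng)
        base = subject_marginal_loglik(model, mk([0.1, 0.3]), man)
        shifted_model = TrajectoryMixtureModel(
            K=2, pi=model.pi, mu=model.mu + np.array([5.0, 0.0]),
            sigma_comp=model.sigma_comp, delta=model.delta, sigma_res=model.sigma_res,
        )
        shifted = subject_marginal_loglik(shifted_model, mk([5.1, 5.3]), man)
        assert np.allclose(base, shifted, atol=1e-9)

    def test_all_missing_subject_rejected(self):
        man = toy_manifest(1)
        subj = SubjectRecord("s0", 0, 0, {}, [VisitRecord("s0", 63.0, {"r00": np.nan})])
        model = _model(1, 1, np.random.default_rng(0), pi=np.array([1.0]))
        with pytest.raises(ValueError, match="no observed"):
            subject_marginal_loglik(model, subj, man)


class TestFitMixture:
    def test_separable_limit_modal_allocations_equal_truth(self, separable_fit):
        zc, truth, chains = separable_fit
        modal = chains.allocation_means().argmax(axis=1) + 1
        # identical up to the global label permutation
        agree = (modal == truth.true_label).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_allocation_rows_sum_to_one(self, separable_fit):
        _, _, chains = separable_fit
        assert np.abs(chains.p.sum(axis=2) - 1.0).max() < 1e-10
        assert np.abs(chains.pi.sum(axis=1) - 1.0).max() < 1e-10

    def test_retained_draw_count(self, separable_fit):
        _, _, chains = separable_fit
        cfg = chains.config
        assert chains.n_draws == int(np.floor(cfg.n_iter * (1 - cfg.burn_in_frac) / cfg.thin))

    def test_fixed_seed_bit_reproducible(self, separable_cohort):
        cohort, truth, _ = separable_cohort
        zc = trajmix.zscore_regions(cohort)
        cfg = McmcConfig(n_iter=200, seed=5)
        a = fit_mixture(zc, 2, truth.true_label, cfg)
        b = fit_mixture(zc, 2, truth.true_label, cfg)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.z, b.z)

    def test_invalid_arguments(self, separable_cohort):
        cohort, _, _ = separable_cohort
        with pytest.raises(ValueError, match="K"):
            fit_mixture(cohort, 0)
        with pytest.raises(ValueError, match="fewer subjects"):
            fit_mixture(cohort, 99)
        with pytest.raises(ValueError, match="init_labels"):
            fit_mixture(cohort, 2, init_labels=np.full(cohort.n_subjects, 7))

    def test_single_cluster_matches_gls_oracle(self):
        """K=1 posterior means of region means and fixed effects agree with
        the closed-form generalized-least-squares fit at the generator's
        variances."""
        cfg = trajmix.well_separated_config(250, 3, 1, seed=21)
        cfg.fixed_effects[:, 0] = -0.15
        cfg.fixed_effects[:, 1] = 0.1
        cfg.covariate_prevalence = (0.5, 0.5)
        cohort, _ = trajmix.simulate_cohort(cfg)
        ch = fit_mixture(cohort, 1, mcmc=McmcConfig(n_iter=5000, seed=9))
        mu_hat = ch.mu.mean(0)[0]
        delta_hat = ch.delta.mean(0)
        arr = cohort.to_arrays()
        t, y, obs = arr["t"], arr["y"], arr["obs"]
        tau = cfg.within_cluster_sd[0, 0]
        for r in range(3):
            XtVX = np.zeros((4, 4))
            XtVy = np.zeros(4)
            for i in range(y.shape[0]):
                m = obs[i, :, r]
                ti = t[i][m]
                yi = y[i, :, r][m]
                X = np.column_stack([
                    np.ones_like(ti), ti,
                    np.full_like(ti, arr["sex"][i]), np.full_like(ti, arr["apoe4"][i]),
                ])
                V = (tau[0] ** 2 * np.ones((len(ti), len(ti)))
                     + tau[1] ** 2 * np.outer(ti, ti)
                     + cfg.noise_sd[r] ** 2 * np.eye(len(ti)))
                Vi = np.linalg.inv(V)
                XtVX += X.T @ Vi @ X
                XtVy += X.T @ Vi @ yi
            theta = np.linalg.solve(XtVX, XtVy)
            assert abs(mu_hat[r, 0] - theta[0]) < 0.05
            assert abs(mu_hat[r, 1] - theta[1]) < 0.05
            assert abs(delta_hat[r, 0] - theta[2]) < 0.05
            assert abs(delta_hat[r, 1] - theta[3]) < 0.05

    def test_prior_recovery_with_no_data(self):
        """All FA cells missing: the cluster-mean posterior reverts to its
        Normal(0, mean_prior_var) prior. The data-free chain moves mu only
        through the latent trajectories, so it decorrelates slowly; a long,
        heavily thinned chain keeps the moment check honest."""
        vals = [[[np.nan], [np.nan]]]
        cohort = make_cohort(vals, [[61, 63]])
        ch = fit_mixture(
            cohort, 1,
            mcmc=McmcConfig(n_iter=40000, burn_in_frac=0.25, thin=30, seed=2),
        )
        draws = ch.mu[:, 0, 0, 0]
        assert abs(draws.mean()) < 1.0
        assert abs(draws.var() - 10.0) < 4.0


class TestRelabel:
    def test_no_switching_is_identity(self, separable_fit):
        _, _, chains = separable_fit
        again = relabel_chains(chains)
        assert np.array_equal(again.mu, chains.mu)
        assert np.array_equal(again.z, chains.z)

    def test_constructed_swap_is_undone(self, separable_fit):
        _, _, chains = separable_fit
        swapped = permute_clusters(chains, np.array([1, 0]))
        # re-swap only the second half of the draws to fabricate switching
        half = chains.n_draws // 2
        mixed_mu = np.concatenate([chains.mu[:half], swapped.mu[half:]])
        mixed = trajmix.PosteriorChains(
            pi=np.concatenate([chains.pi[:half], swapped.pi[half:]]),
            mu=mixed_mu,
            sigma_comp=np.concatenate([chains.sigma_comp[:half], swapped.sigma_comp[half:]]),
            delta=chains.delta.copy(),
            sigma_res=chains.sigma_res.copy(),
            z=np.concatenate([chains.z[:half], swapped.z[half:]]),
            p=np.concatenate([chains.p[:half], swapped.p[half:]]),
            traj=None,
            config=chains.config,
            region_ids=chains.region_ids,
            subject_ids=chains.subject_ids,
        )
        fixed = relabel_chains(mixed)
        assert np.allclose(fixed.mu, chains.mu, atol=1e-12)
        assert np.array_equal(fixed.z, chains.z)
        assert np.allclose(fixed.p, chains.p, atol=1e-12)

    def test_deviance_invariant_under_relabeling(self, separable_fit):
        zc, _, chains = separable_fit
        swapped = permute_clusters(chains, np.array([1, 0]))
        assert deviance(chains, zc) == pytest.approx(deviance(swapped, zc), abs=1e-9)


class TestDeviance:
    def test_matches_direct_recomputation(self, separable_fit):
        zc, _, chains = separable_fit
        stats = _Stats(zc)
        devs = []
        for d in range(chains.n_draws):
            ll = _marginal_loglik_stats(
                stats, chains.pi[d], chains.mu[d], chains.sigma_comp[d],
                chains.delta[d], chains.sigma_res[d],
            )
            devs.append(-2.0 * logsumexp(np.log(chains.pi[d]) + ll, axis=1).sum())
        assert deviance(chains, zc) == pytest.approx(np.mean(devs), rel=1e-12)

    def test_duplicating_subjects_doubles_deviance(self, separable_fit):
        zc, _, chains = separable_fit
        doubled = trajmix.LongitudinalCohort(
            [
                trajmix.SubjectRecord(f"{s.subject_id}{tag}", s.sex, s.apoe4,
                                      dict(s.covariates), s.visits)
                for tag in ("a", "b")
                for s in zc.subjects
            ],
            zc.manifest,
            zscored=True,
        )
        assert deviance(chains, doubled) == pytest.approx(2 * deviance(chains, zc), rel=1e-10)


class TestEstimatorFacade:
    def test_sklearn_contract(self, separable_cohort):
        cohort, truth, _ = separable_cohort
        zc = trajmix.zscore_regions(cohort)
        est = TrajectoryMixture(K=2, n_iter=400, seed=3)
        params = est.get_params()
        assert params["K"] == 2
        est.set_params(n_iter=300)
        est.fit(zc, init_labels=truth.true_label)
        assert est.labels_.shape == (30,)
        assert est.allocation_probs_.shape == (30, 2)
        probs = est.predict_proba(zc)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9
        agree = (est.predict(zc) == truth.true_label).mean()
        assert max(agree, 1 - agree) > 0.95


class TestSerialization:
    def test_chain_archive_round_trip(self, separable_fit, tmp_path):
        _, _, chains = separable_fit
        chains.save(tmp_path / "chains.npz")
        back = trajmix.PosteriorChains.load(tmp_path / "chains.npz")
        assert np.array_equal(back.mu, chains.mu)
        assert np.array_equal(back.z, chains.z)
        assert back.config.n_iter == chains.config.n_iter
        assert back.subject_ids == chains.subject_ids
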