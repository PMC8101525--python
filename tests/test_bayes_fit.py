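import math

import numpy as np
import pytest

from curefrail import (
    CureModelParams,
    MCMCConfig,
    PriorSpec,
    diagnostics,
    log_posterior,
    mh_sample,
    posterior_summary,
)
from curefrail.bayes_fit import PosteriorChain, random_walk_metropolis
from curefrail.model_core import ParamTransform, log_likelihood


class TestLogPosterior:
    def test_flat_prior_limit_matches_likelihood_differences(self, toy_dataset):
        priors = PriorSpec(coefficient_sd=1e6, log_positive_sd=1e6)
        p1 = CureModelParams(b0=0.1, b=[], beta=[], shape=1.0, scale=0.4, theta=2.0)
        p2 = CureModelParams(b0=-0.3, b=[], beta=[], shape=1.2, scale=0.6, theta=1.0)
        dlp = (log_posterior(p1, toy_dataset, priors)
               - log_posterior(p2, toy_dataset, priors))
        dll = log_likelihood(toy_dataset, p1) - log_likelihood(toy_dataset, p2)
        assert dlp == pytest.approx(dll, abs=1e-4)

    def test_priors_only_target_equals_log_prior(self):
        priors = PriorSpec(coefficient_sd=2.0, log_positive_sd=1.5)
        p = CureModelParams(b0=0.5, b=[0.3], beta=[-0.2], shape=1.1, scale=0.7,
                            theta=2.0)
        tr = ParamTransform(1, 1)
        expected = priors.log_density(tr.pack(p), tr)
        assert log_posterior(p, None, priors) == pytest.approx(expected, abs=1e-10)

    def test_hand_computed_toy_posterior(self, toy_dataset, toy_params):
        priors = PriorSpec(coefficient_sd=10.0, log_positive_sd=10.0)
        # hand computation: likelihood term (see model_core toy test) plus
        # independent normal log densities
        th = toy_params.theta
        f1 = 0.5 * (1 + 0.5 / th) ** (-th - 1)
        s2 = (1 + 1.0 / th) ** (-th)
        loglik = math.log(0.5 * f1) + math.log(0.5 + 0.5 * s2)

        def norm_logpdf(x, sd):
            return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)

        logprior = (norm_logpdf(0.0, 10.0)                     # b0
                    + norm_logpdf(math.log(1.0), 10.0)         # log shape
                    + norm_logpdf(math.log(0.5), 10.0)         # log scale
                    + norm_logpdf(math.log(th), 10.0))         # log theta
        assert log_posterior(toy_params, toy_dataset, priors) == pytest.approx(
            loglik + logprior, abs=1e-6)

    def test_out_of_support_returns_minus_inf_not_raise(self, toy_dataset):
        # a parameter vector pushed outside the representable support
        target_value = log_posterior(
            CureModelParams(b0=np.inf if False else 0.0, b=[], beta=[],
                            shape=1.0, scale=1.0, theta=1.0),
            toy_dataset)
        assert np.isfinite(target_value)


class TestMHSample:
    def test_identical_seeds_give_identical_chains(self, registry_cohort):
        data = registry_cohort(n=150, seed=2)
        cfg = MCMCConfig(n_iter=600, burn_in=200, thin=2, n_chains=1, seed=9)
        c1 = mh_sample(data, config=cfg)[0]
        c2 = mh_sample(data, config=cfg)[0]
        np.testing.assert_array_equal(c1.draws, c2.draws)
        assert c1.acceptance_rate == c2.acceptance_rate

    def test_prior_recovery_with_likelihood_off(self, registry_cohort):
        import arviz as az

        data = registry_cohort(n=50, seed=2)
        priors = PriorSpec(coefficient_sd=2.0, log_positive_sd=1.5)
        cfg = MCMCConfig(n_iter=24_000, burn_in=4_000, thin=1, n_chains=1, seed=3)
        chain = mh_sample(data, priors, cfg, likelihood_off=True)[0]
        kept = chain.kept
        tr = ParamTransform.for_dataset(data)
        prior_sds = priors.sds(tr)
        for k, nm in enumerate(chain.param_names):
            ess = float(az.ess(kept[:, k][None, :]))
            mc_se = prior_sds[k] / math.sqrt(ess)
            assert abs(np.mean(kept[:, k])) < 3 * mc_se, nm
            assert abs(np.std(kept[:, k]) - prior_sds[k]) < 3 * prior_sds[k] / math.sqrt(ess), nm

    def test_zero_proposal_sd_rejected(self, registry_cohort):
        data = registry_cohort(n=100, seed=2)
        cfg = MCMCConfig(n_iter=200, burn_in=100, n_chains=1,
                         proposal_sds=np.zeros(10))
        with pytest.raises(ValueError, match="proposal"):
            mh_sample(data, config=cfg)

    def test_conjugate_normal_toy_matches_closed_form(self):
        """Detailed-balance smoke test: normal likelihood + normal prior
        has a closed-form posterior the sampler must reproduce."""
        import arviz as az

        rng_data = np.random.default_rng(5)
        y = rng_data.normal(1.3, 1.0, size=40)
        tau2, sigma2 = 4.0, 1.0
        post_var = 1.0 / (1.0 / tau2 + len(y) / sigma2)
        post_mean = post_var * (y.sum() / sigma2)

        def log_target(x):
            mu = x[0]
            return -0.5 * mu ** 2 / tau2 - 0.5 * np.sum((y - mu) ** 2) / sigma2

        rng = np.random.default_rng(11)
        draws, acc = random_walk_metropolis(
            log_target, np.array([0.0]), np.array([0.5]), 24_000, rng,
            burn_in=4_000)
        kept = draws[4_000:, 0]
        ess = float(az.ess(kept[None, :]))
        sd = math.sqrt(post_var)
        assert 0.1 < acc < 0.9
        assert abs(np.mean(kept) - post_mean) < 3 * sd / math.sqrt(ess)
        assert abs(np.std(kept) - sd) < 3 * sd / math.sqrt(2 * ess)


class TestPosteriorSummary:
    def _chain_from(self, draws, names=("a",)):
        return PosteriorChain(draws=np.asarray(draws, dtype=float),
                              param_names=list(names), burn_in=0, thin=1,
                              seed=0, acceptance_rate=0.5)

    def test_constant_chain_degenerates(self):
        chain = self._chain_from(np.full((200, 1), 3.14))
        summ = posterior_summary(chain)
        assert summ.mean["a"] == pytest.approx(3.14)
        assert summ.sd["a"] == 0.0
        assert summ.ci95["a"] == (pytest.approx(3.14), pytest.approx(3.14))

    def test_arithmetic_mean_of_sequence(self):
        chain = self._chain_from(np.arange(1, 101, dtype=float)[:, None])
        assert posterior_summary(chain).mean["a"] == pytest.approx(50.5)

    def test_short_chain_rejected(self):
        chain = self._chain_from(np.zeros((50, 1)))
        with pytest.raises(ValueError, match="draws"):
            posterior_summary(chain)

    def test_thinning_an_exchangeable_chain_preserves_summary(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(2.0, 1.0, size=(20_000, 1))
        full = posterior_summary(self._chain_from(draws))
        thinned = PosteriorChain(draws=draws, param_names=["a"], burn_in=0,
                                 thin=10, seed=0, acceptance_rate=0.5)
        thin_summ = posterior_summary(thinned)
        assert thin_summ.mean["a"] == pytest.approx(full.mean["a"], abs=0.05)
        assert thin_summ.sd["a"] == pytest.approx(full.sd["a"], abs=0.05)

    def test_natural_scale_back_transform(self):
        draws = np.log(np.full((200, 1), 2.5))
        chain = PosteriorChain(draws=draws, param_names=["shape"], burn_in=0,
                               thin=1, seed=0, acceptance_rate=0.4,
                               log_scale_idx=[0])
        assert posterior_summary(chain).mean["shape"] == pytest.approx(2.5)


class TestDiagnostics:
    def _chain_from(self, draws, acc=0.4):
        return PosteriorChain(draws=np.asarray(draws, dtype=float),
                              param_names=["a"], burn_in=0, thin=1, seed=0,
                              acceptance_rate=acc)

    def test_identical_chains_have_unit_rhat(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(2_000, 1))
        rep = diagnostics([self._chain_from(draws), self._chain_from(draws)])
        assert rep.rhat["a"] == pytest.approx(1.0, abs=0.01)

    def test_iid_draws_have_near_nominal_ess(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(10_000, 1))
        rep = diagnostics(self._chain_from(draws))
        assert rep.ess["a"] == pytest.approx(10_000, rel=0.2)

    def test_stuck_chain_warns(self):
        draws = np.full((500, 1), 1.0)
        with pytest.warns(UserWarning):
            rep = diagnostics(self._chain_from(draws, acc=0.0))
        assert rep.acceptance_rates == [0.0]
        assert rep.warnings


class TestChainPersistence:
    def test_round_trip(self, tmp_path, registry_cohort):
        from curefrail.bayes_fit import load_chain, save_chain

        data = registry_cohort(n=120, seed=2)
        cfg = MCMCConfig(n_iter=400, burn_in=100, thin=2, n_chains=1, seed=4)
        chain = mh_sample(data, config=cfg)[0]
        save_chain(chain, str(tmp_path / "chain"), priors=PriorSpec())
        loaded = load_chain(str(tmp_path / "chain"))
        np.testing.assert_allclose(loaded.draws, chain.draws)
        assert loaded.param_names == chain.param_names
        assert loaded.thin == chain.thin
        s1 = posterior_summary(chain)
        s2 = posterior_summary(loaded)
        for nm in s1.param_names:
            assert s2.mean[nm] == pytest.approx(s1.mean[nm], rel=1e-12)
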