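"""Posterior assembly, diagnostics, intervals, and small-scale sampler behavior."""

import numpy as np
import pytest

import erspcm as E
from erspcm.diagnostics import bulk_ess, credibility_interval, split_rhat
from erspcm.posterior import ConstraintError, ModelParameters, PriorSpec, log_posterior
from erspcm.scale import UnidentifiableERSError

from conftest import brute_force_probs, make_draws


def _empty_dataset(G=2, n=4, I=2, K=3):
    return E.ResponseDataset(
        responses=np.zeros((n, I), dtype=int),
        country=np.repeat(np.arange(G), n // G),
        K=K,
        x=np.array([-1.0, 1.0]) if G == 2 else E.generate_covariate(G, 0),
    )


def _params(G=2, n=4, I=2, K=3, ext=False, rng=None):
    rng = rng or np.random.default_rng(0)
    tau = rng.normal(size=(I, K - 1))
    tau -= tau.mean()
    kw = {}
    if ext:
        mu_eta = rng.normal(size=G)
        mu_eta -= mu_eta.mean()
        kw = dict(
            eta=rng.normal(size=n) * 0.3,
            mu_eta=mu_eta,
            sigma_eta=0.4,
            sigma_mu_eta=0.6,
        )
    return ModelParameters(
        beta=np.array([0.2, -0.1, 0.3]),
        sigma_u=0.5,
        mu_theta=rng.normal(size=G),
        tau=tau,
        theta=rng.normal(size=n),
        **kw,
    )


class TestLogPosterior:
    def test_empty_dataset_is_priors_plus_hierarchy(self):
        """With no observed cells the likelihood term vanishes."""
        ds = _empty_dataset()
        params = _params()
        priors = PriorSpec()
        lp = log_posterior(params, ds, priors, "pcm")
        # independent assembly of the non-likelihood terms
        from scipy import stats

        x = ds.x
        X = np.column_stack([np.ones(2), x, x**2])
        expected = (
            stats.norm.logpdf(params.theta, params.mu_theta[ds.country], 1).sum()
            + stats.norm.logpdf(params.mu_theta, X @ params.beta, params.sigma_u).sum()
            + stats.norm.logpdf(params.beta, 0, priors.beta_sd).sum()
            + stats.halfnorm.logpdf(params.sigma_u, scale=priors.sigma_u_scale)
            + stats.norm.logpdf(params.tau, 0, priors.tau_sd).sum()
        )
        assert np.isclose(lp, expected, atol=1e-10)

    def test_single_cell_adds_its_log_probability(self):
        ds0 = _empty_dataset()
        params = _params()
        priors = PriorSpec()
        base = log_posterior(params, ds0, priors, "pcm")
        responses = ds0.responses.copy()
        responses[1, 0] = 2
        ds1 = E.ResponseDataset(responses=responses, country=ds0.country, K=3, x=ds0.x)
        lp = log_posterior(params, ds1, priors, "pcm")
        cell = np.log(brute_force_probs(params.theta[1], params.tau[0])[1])
        assert np.isclose(lp - base, cell, atol=1e-10)

    def test_pcm_variant_rejects_ers_parameters(self):
        ds = _empty_dataset()
        params = _params(ext=True)
        with pytest.raises(ValueError, match="pcm"):
            log_posterior(params, ds, PriorSpec(), "pcm")

    def test_constraint_violations_are_named(self):
        ds = _empty_dataset()
        params = _params()
        params.tau = params.tau + 1.0  # breaks grand-sum zero
        with pytest.raises(ConstraintError, match="grand sum"):
            log_posterior(params, ds, PriorSpec(), "pcm")
        params = _params(ext=True)
        params.mu_eta = params.mu_eta + 0.5
        with pytest.raises(ConstraintError, match="ERS means"):
            log_posterior(params, ds, PriorSpec(), "ext_pcm")


class TestSplitRhat:
    def test_identical_chains_formula(self):
        """Hand-computable case: two copies of (1,2,3,4)."""
        chains = np.array([[1.0, 2, 3, 4], [1, 2, 3, 4]])
        # halves: (1,2),(3,4),(1,2),(3,4): W=0.5; B=2*var([1.5,3.5,1.5,3.5])
        W = 0.5
        B = 2 * np.var([1.5, 3.5, 1.5, 3.5], ddof=1)
        expected = np.sqrt(((1 / 2) * W + B / 2) / W)
        assert np.isclose(split_rhat(chains), expected)

    def test_constant_chains_converged(self):
        assert split_rhat(np.full((2, 100), 0.3)) == 1.0

    def test_diverged_constants_blow_up(self):
        chains = np.vstack([np.zeros(50), np.full(50, 100.0)])
        assert split_rhat(chains) > 1.1

    def test_agrees_with_reference_implementation(self, rng):
        """Cross-check against arviz's split R-hat on autocorrelated chains."""
        import arviz as az

        x = rng.standard_normal((4, 500))
        x = np.cumsum(x * 0.1, axis=1) + rng.standard_normal((4, 500))
        ours = split_rhat(x)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(x), method="split")["x"]))
        assert np.isclose(ours, theirs, atol=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.ones((1, 10)))


class TestCredibilityInterval:
    def test_percentile_convention(self):
        lo, hi = credibility_interval(np.arange(1.0, 101.0), level=0.5)
        assert (lo, hi) == (25.75, 75.25)

    def test_constant_draws(self):
        assert credibility_interval([2.0, 2.0, 2.0]) == (2.0, 2.0)

    def test_symmetric_draws(self, rng):
        x = rng.standard_normal(4000)
        x = np.concatenate([x, -x])
        lo, hi = credibility_interval(x)
        assert np.isclose(lo, -hi, atol=1e-12)

    def test_level_validated(self):
        with pytest.raises(ValueError):
            credibility_interval([1.0, 2.0], level=1.5)


class TestStandardizedCoefficients:
    def test_zero_coefficient_stays_zero(self):
        d = make_draws(beta1_ci=(0.0, 0.0), seed=1)
        d.params["beta1"][:] = 0.0
        out = E.standardized_coefficients(d, np.array([-1.0, 0, 1, 2, -2, 0.5]))
        assert np.allclose(out["beta1_std"], 0.0)

    def test_hand_computed_single_draw(self):
        from erspcm.draws import PosteriorDraws

        mu = np.array([0.1, 0.5, -0.2, 0.4])
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        params = {
            "beta1": np.full((2, 1), 0.3),
            "beta2": np.full((2, 1), -0.6),
            "mu_theta": np.tile(mu, (2, 1, 1)),
        }
        d = PosteriorDraws(params=params)
        out = E.standardized_coefficients(d, x)
        assert np.allclose(out["beta1_std"], 0.3 * x.std(ddof=1) / mu.std(ddof=1))
        assert np.allclose(out["beta2_std"], -0.6 * (x**2).std(ddof=1) / mu.std(ddof=1))

    def test_homogeneity_under_scaling(self):
        d = make_draws(seed=3)
        x = np.array([-1.0, 0.3, 1.0, 2.0, -2.0, 0.5])
        base = E.standardized_coefficients(d, x)
        d.params["mu_theta"] = 2 * d.params["mu_theta"]
        scaled = E.standardized_coefficients(d, x)
        assert np.allclose(scaled["beta1_std"], base["beta1_std"] / 2)
        assert np.allclose(scaled["beta2_std"], base["beta2_std"] / 2)

    def test_zero_variance_rejected(self):
        d = make_draws(seed=4)
        d.params["mu_theta"][:] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            E.standardized_coefficients(d, np.arange(6.0))


class TestBulkESS:
    def test_iid_chains_ess_near_sample_size(self, rng):
        x = rng.standard_normal((4, 500))
        assert bulk_ess(x) > 1000


class TestFitBehavior:
    def test_same_seed_reproduces_draws_exactly(self, tiny_fit):
        ds, _, est = tiny_fit
        est2 = E.MultigroupPCM(
            variant="ext_pcm", chains=2, warmup=150, draws=200, seed=7
        ).fit(ds)
        for name, arr in est.draws_.params.items():
            assert np.array_equal(arr, est2.draws_.params[name]), name

    def test_identification_constraints_hold_per_draw(self, tiny_fit):
        _, _, est = tiny_fit
        tau = est.draws_.params["tau"]
        assert np.abs(tau.sum(axis=(-2, -1))).max() < 1e-8
        mu_eta = est.draws_.params["mu_eta"]
        assert np.abs(mu_eta.sum(axis=-1)).max() < 1e-8

    def test_nonconvergence_is_flagged_not_raised(self, tiny_fit):
        """A deliberately short run reports converged_=False with diagnostics."""
        ds, _, _ = tiny_fit
        est = E.MultigroupPCM(
            variant="ext_pcm", chains=2, warmup=10, draws=12, seed=1
        ).fit(ds)
        assert est.converged_ is False
        assert set(est.diagnostics_["ess_bulk"]) >= {"beta1", "beta2"}

    def test_ext_variant_rejected_on_binary_scale(self):
        ds = E.ResponseDataset(
            responses=np.array([[1, 2], [2, 1], [1, 1], [2, 2]]),
            country=np.array([0, 0, 1, 1]),
            K=2,
            x=np.array([-1.0, 1.0]),
        )
        with pytest.raises(UnidentifiableERSError):
            E.MultigroupPCM(variant="ext_pcm", chains=2, warmup=10, draws=10).fit(ds)

    def test_sklearn_params_round_trip(self):
        est = E.MultigroupPCM(variant="pcm", chains=3)
        params = est.get_params()
        assert params["variant"] == "pcm"
        est.set_params(chains=5)
        assert est.chains == 5

    def test_posterior_pulls_toward_truth(self, tiny_fit):
        """Country-mean estimates correlate with the generating means."""
        _, rec, est = tiny_fit
        mu_hat = est.draws_.stacked("mu_theta").mean(axis=0)
        assert np.corrcoef(mu_hat, rec["mu_theta"])[0, 1] > 0.5
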