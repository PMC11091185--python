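"""Scikit-learn-style estimator for the multigroup PCM latent regression.

:class:`MultigroupPCM` wraps the Bayesian sampler behind the familiar
``fit`` / ``get_params`` / ``set_params`` interface so fits compose with
sklearn tooling; module-level functions (``fit``,
``standardized_coefficients``) stay thin wrappers for script use.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import ResponseDataset
from .diagnostics import (
    ESS_THRESHOLD,
    RHAT_THRESHOLD,
    bulk_ess,
    credibility_interval,
    split_rhat,
)
from .draws import PosteriorDraws
from .posterior import PriorSpec
from .sampler import SamplerConfig, sample_posterior
from .scale import RatingScaleSpec

__all__ = ["MultigroupPCM", "fit", "standardized_coefficients"]

#: parameters whose convergence gates the "converged" flag
_KEY_PARAMS = ("beta0", "beta1", "beta2", "sigma_u")


class MultigroupPCM(BaseEstimator):
    """Bayesian multigroup Partial Credit Model with latent country regression.

    Parameters
    ----------
    variant : {"ext_pcm", "pcm"}
        "pcm" assumes all countries use the rating scale identically;
        "ext_pcm" adds a country-varying extreme-response-style trait that
        symmetrically shifts the item thresholds.
    quadratic : bool
        Include the squared covariate in the country-mean regression.
    priors : PriorSpec, optional
    chains, warmup, draws : int
        Sampler settings (per chain).
    seed : int
        Root seed; all chains derive their streams from it.
    ers_weights : {"graded", "binary"}
        ERS scoring-weight family (see :func:`erspcm.scale.ers_scoring_weights`).
    fix_tau, fix_sigma_u :
        Calibration/testing hooks that clamp thresholds or the country
        residual SD at known values.

    Attributes
    ----------
    draws_ : PosteriorDraws
    summary_ : pandas.DataFrame
        Posterior mean, SD, 95% CI, R-hat and bulk ESS per scalar parameter.
    beta_ : dict
        Posterior means of the regression coefficients.
    ci_ : dict
        95% equal-tailed credibility intervals for the coefficients.
    standardized_beta_ : dict
        Posterior-mean standardized coefficients (beta1*, beta2*).
    diagnostics_ : dict
        R-hat / ESS for the key parameters plus the convergence flag.
    converged_ : bool
    """

    def __init__(
        self,
        variant: str = "ext_pcm",
        quadratic: bool = True,
        priors: Optional[PriorSpec] = None,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        ers_weights: str = "graded",
        fix_tau: Optional[np.ndarray] = None,
        fix_sigma_u: Optional[float] = None,
    ):
        self.variant = variant
        self.quadratic = quadratic
        self.priors = priors
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.ers_weights = ers_weights
        self.fix_tau = fix_tau
        self.fix_sigma_u = fix_sigma_u

    # ------------------------------------------------------------------
    def fit(self, X: ResponseDataset, y=None):
        """Sample the posterior for dataset ``X`` (must carry a covariate)."""
        if not isinstance(X, ResponseDataset):
            raise TypeError(
                "X must be a ResponseDataset (see erspcm.data.read_and_validate "
                "or erspcm.simulate)"
            )
        if self.variant not in ("pcm", "ext_pcm"):
            raise ValueError(f"unknown variant {self.variant!r}")
        scale = RatingScaleSpec(X.K, weight_kind=self.ers_weights)
        config = SamplerConfig(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.seed,
            fix_tau=self.fix_tau,
            fix_sigma_u=self.fix_sigma_u,
        )
        draws = sample_posterior(
            X,
            variant=self.variant,
            priors=self.priors or PriorSpec(),
            scale=scale,
            quadratic=self.quadratic,
            config=config,
        )
        self._assert_identification(draws)
        self.scale_ = scale
        self.x_ = X.x.copy()
        self.draws_ = draws
        self._finalize()
        return self

    def _assert_identification(self, draws: PosteriorDraws) -> None:
        tau = draws.params["tau"]
        if self.fix_tau is None:
            gs = np.abs(tau.sum(axis=(-2, -1))).max()
            if gs > 1e-8:
                raise AssertionError(f"threshold grand-sum constraint violated ({gs})")
        if "mu_eta" in draws.params:
            ms = np.abs(draws.params["mu_eta"].sum(axis=-1)).max()
            if ms > 1e-8:
                raise AssertionError(f"ERS-mean sum-zero constraint violated ({ms})")

    def _finalize(self) -> None:
        draws = self.draws_
        rows = []
        for name in draws.scalar_names():
            ch = draws.scalar(name)
            pooled = ch.reshape(-1)
            lo, hi = credibility_interval(pooled, 0.95)
            rows.append(
                {
                    "parameter": name,
                    "mean": pooled.mean(),
                    "sd": pooled.std(ddof=1),
                    "ci_low": lo,
                    "ci_high": hi,
                    "rhat": split_rhat(ch),
                }
            )
        summary = pd.DataFrame(rows).set_index("parameter")
        ess = {}
        for name in _KEY_PARAMS:
            if name in draws.params:
                ess[name] = bulk_ess(draws.scalar(name))
        summary["ess_bulk"] = pd.Series(ess)

        key = [p for p in _KEY_PARAMS if p in draws.params]
        rhat_ok = bool((summary.loc[key, "rhat"] < RHAT_THRESHOLD).all())
        ess_ok = bool(
            all(ess[p] > ESS_THRESHOLD for p in ("beta1", "beta2") if p in ess)
        )
        self.summary_ = summary
        self.diagnostics_ = {
            "rhat": {p: float(summary.loc[p, "rhat"]) for p in key},
            "ess_bulk": {p: float(v) for p, v in ess.items()},
            "rhat_threshold": RHAT_THRESHOLD,
            "ess_threshold": ESS_THRESHOLD,
            "converged": rhat_ok and ess_ok,
        }
        self.converged_ = rhat_ok and ess_ok
        draws.diagnostics = self.diagnostics_

        betas = [n for n in draws.params if n.startswith("beta")]
        self.beta_ = {n: float(draws.stacked(n).mean()) for n in betas}
        self.ci_ = {n: credibility_interval(draws.stacked(n)) for n in betas}
        std = standardized_coefficients(draws, self.x_)
        self.standardized_beta_ = {k: float(v.mean()) for k, v in std.items()}

    # ------------------------------------------------------------------
    def score(self, X: ResponseDataset, y=None) -> float:
        """Mean observed-cell log-likelihood at the posterior means."""
        from .pcm import response_loglik

        draws = self.draws_
        tau = draws.stacked("tau").mean(axis=0)
        mu_theta = draws.stacked("mu_theta").mean(axis=0)
        theta = mu_theta[X.country]
        if self.variant == "ext_pcm":
            eta = draws.stacked("mu_eta").mean(axis=0)[X.country]
            ll = response_loglik(
                X.responses, theta, tau, self.scale_, eta=eta, variant="ext_pcm"
            )
        else:
            ll = response_loglik(X.responses, theta, tau, self.scale_, variant="pcm")
        return ll / max(int((X.responses >= 1).sum()), 1)


def standardized_coefficients(
    draws: PosteriorDraws, x: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-draw standardized regression coefficients.

    For each posterior draw, beta1* = beta1 * SD(x) / SD(mu_theta) and
    beta2* = beta2 * SD(x^2) / SD(mu_theta), where SD(mu_theta) is the SD
    of the G country means in that draw (ddof=1 throughout).  Returns
    pooled per-draw arrays keyed ``beta1_std``, ``beta2_std``.
    """
    x = np.asarray(x, dtype=float)
    mu = draws.stacked("mu_theta")
    sd_mu = mu.std(axis=1, ddof=1)
    if np.any(sd_mu == 0):
        raise ValueError(
            "country means have zero variance in at least one draw; "
            "standardized coefficients are undefined"
        )
    out = {}
    if "beta1" in draws.params:
        out["beta1_std"] = draws.stacked("beta1") * x.std(ddof=1) / sd_mu
    if "beta2" in draws.params:
        out["beta2_std"] = draws.stacked("beta2") * (x**2).std(ddof=1) / sd_mu
    return out


def fit(
    data: ResponseDataset,
    covariates: Optional[np.ndarray] = None,
    variant: str = "ext_pcm",
    config: Optional[dict] = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Functional entry point: fit a variant and return its posterior draws.

    ``config`` may carry any :class:`MultigroupPCM` keyword (chains, warmup,
    draws, quadratic, priors, ...).
    """
    if covariates is not None:
        data = ResponseDataset(
            responses=data.responses,
            country=data.country,
            K=data.K,
            x=np.asarray(covariates, dtype=float),
            person_ids=data.person_ids,
            country_ids=data.country_ids,
            item_ids=data.item_ids,
        )
    est = MultigroupPCM(variant=variant, seed=seed, **(config or {}))
    est.fit(data)
    return est.draws_
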