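"""Joint posterior density for the multigroup PCM latent-regression models.

The hierarchical model, for person p in country g(p) with covariate x_g:

    y_pi            ~ PCM / ext-PCM(theta_p, [eta_p], tau_i)
    theta_p         ~ Normal(mu_theta_g, 1)            (sigma_theta = 1 fixed)
    mu_theta_g      = beta0 + beta1 x_g + beta2 x_g^2 + u_g,  u_g ~ N(0, sigma_u^2)
    eta_p           ~ Normal(mu_eta_g, sigma_eta^2)    (ext variant only)
    mu_eta_g        ~ Normal(0, sigma_mu_eta^2)  subject to  sum_g mu_eta_g = 0

Identification: sigma_theta = 1, grand sum of all item thresholds = 0, and
sum-zero country ERS means.  The country ERS-mean density is evaluated in
its restricted form on the sum-zero subspace (G-1 effective dimensions).

Priors (weakly informative): thresholds N(0, 3^2); regression coefficients
N(0, 5^2); half-Normal(2.5) on sigma_u, sigma_eta and the ERS-mean
hyper-SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import ResponseDataset
from .pcm import response_loglik
from .scale import RatingScaleSpec

__all__ = ["PriorSpec", "ModelParameters", "ConstraintError", "log_posterior"]

_LOG2PI = float(np.log(2.0 * np.pi))


class ConstraintError(ValueError):
    """An identification constraint is violated; the message names it."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales for the latent-regression PCM models."""

    tau_sd: float = 3.0
    beta_sd: float = 5.0
    sigma_u_scale: float = 2.5
    sigma_eta_scale: float = 2.5
    mu_eta_hyper_scale: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "tau_sd",
            "beta_sd",
            "sigma_u_scale",
            "sigma_eta_scale",
            "mu_eta_hyper_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be > 0")


@dataclass
class ModelParameters:
    """One point in parameter space (person latents included)."""

    beta: np.ndarray  # (P,) regression coefficients, P = 2 or 3
    sigma_u: float
    mu_theta: np.ndarray  # (G,)
    tau: np.ndarray  # (I, K-1)
    theta: np.ndarray  # (n_persons,)
    eta: Optional[np.ndarray] = None  # (n_persons,), ext variant
    mu_eta: Optional[np.ndarray] = None  # (G,)
    sigma_eta: Optional[float] = None
    sigma_mu_eta: Optional[float] = None


def _norm_logpdf(x, mu, sd):
    z = (np.asarray(x, dtype=float) - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI


def _halfnorm_logpdf(x, scale):
    if x < 0:
        return -np.inf
    return float(np.log(2.0) + _norm_logpdf(x, 0.0, scale))


def log_posterior(
    params: ModelParameters,
    data: ResponseDataset,
    priors: PriorSpec,
    variant: str,
    scale: Optional[RatingScaleSpec] = None,
    constraint_tol: float = 1e-8,
) -> float:
    """Unnormalized joint log posterior at ``params``.

    Raises :class:`ConstraintError` naming the violated identification
    constraint, and ``ValueError`` if ERS-specific parameters are supplied
    to the plain-PCM variant (or missing from the extended one).
    """
    if variant not in ("pcm", "ext_pcm"):
        raise ValueError(f"unknown variant {variant!r}")
    scale = scale if scale is not None else RatingScaleSpec(data.K)
    G = data.n_countries
    if data.x is None:
        raise ValueError("dataset has no covariate; latent regression needs x")
    x = data.x

    ers_fields = (params.eta, params.mu_eta, params.sigma_eta, params.sigma_mu_eta)
    if variant == "pcm":
        if any(f is not None for f in ers_fields):
            raise ValueError(
                "variant 'pcm' does not accept ERS parameters "
                "(eta, mu_eta, sigma_eta, sigma_mu_eta)"
            )
    else:
        if any(f is None for f in ers_fields):
            raise ValueError(
                "variant 'ext_pcm' requires eta, mu_eta, sigma_eta and "
                "sigma_mu_eta"
            )

    tau = np.atleast_2d(np.asarray(params.tau, dtype=float))
    if abs(tau.sum()) > constraint_tol * max(1, tau.size):
        raise ConstraintError(
            f"identification constraint violated: grand sum of item "
            f"thresholds must be 0 (got {tau.sum():.3g})"
        )
    if params.sigma_u < 0:
        raise ConstraintError("sigma_u must be >= 0")
    if variant == "ext_pcm":
        mu_eta = np.asarray(params.mu_eta, dtype=float)
        if abs(mu_eta.sum()) > constraint_tol * max(1, G):
            raise ConstraintError(
                f"identification constraint violated: country ERS means must "
                f"sum to 0 (got {mu_eta.sum():.3g})"
            )

    # response likelihood
    ll = response_loglik(
        data.responses,
        params.theta,
        tau,
        scale,
        eta=params.eta if variant == "ext_pcm" else None,
        variant=variant,
    )

    # hierarchical terms
    lp = ll
    lp += float(np.sum(_norm_logpdf(params.theta, np.asarray(params.mu_theta)[data.country], 1.0)))
    X = np.column_stack([np.ones(G), x, x**2])[:, : len(params.beta)]
    m = X @ np.asarray(params.beta, dtype=float)
    lp += float(np.sum(_norm_logpdf(params.mu_theta, m, params.sigma_u)))
    if variant == "ext_pcm":
        lp += float(
            np.sum(_norm_logpdf(params.eta, mu_eta[data.country], params.sigma_eta))
        )
        # restricted (sum-zero) Gaussian density: G-1 effective dimensions
        lp += float(
            -(G - 1) * np.log(params.sigma_mu_eta)
            - np.sum(mu_eta**2) / (2 * params.sigma_mu_eta**2)
            - 0.5 * (G - 1) * _LOG2PI
        )
        lp += _halfnorm_logpdf(params.sigma_eta, priors.sigma_eta_scale)
        lp += _halfnorm_logpdf(params.sigma_mu_eta, priors.mu_eta_hyper_scale)

    # priors
    lp += float(np.sum(_norm_logpdf(np.asarray(params.beta), 0.0, priors.beta_sd)))
    lp += _halfnorm_logpdf(params.sigma_u, priors.sigma_u_scale)
    lp += float(np.sum(_norm_logpdf(tau, 0.0, priors.tau_sd)))
    return lp
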