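"""Synthetic cross-country rating data with full ground truth.

The generator mirrors the hierarchical structure the analysis assumes:
persons nested in G countries; a target trait theta whose country means
follow a quadratic function of a standardized covariate,

    mu_theta_g = beta0 + beta1 * x_g + beta2 * x_g^2 + u_g,
    u_g ~ N(0, sigma_u^2),    theta_p ~ N(mu_theta_g(p), sigma_theta^2);

an ERS trait eta with country-specific means,

    eta_p ~ N(mu_eta_g(p), sigma_eta^2);

and responses drawn from the ERS-extended partial credit model on a
K-category scale.  Every generated latent quantity is returned, so recovery
tests can compare estimates against the exact truth.

The confound scenario implements the response-style trap the analysis is
designed to expose: no true trait-covariate relationship (beta1 = beta2 = 0)
while the country ERS means carry a quadratic covariate signal, so a naive
multigroup PCM sees a spurious quadratic trend in the trait means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .data import ResponseDataset
from .pcm import cumulative_logits
from .scale import RatingScaleSpec

__all__ = [
    "SimulationDesign",
    "TrueParameters",
    "generate_covariate",
    "simulate_dataset",
    "confound_scenario",
    "fig1_presets",
    "write_simulation",
]

# Defaults emulating the study conditions: 45 countries on a nine-point
# scale; per-country sample size and item count are not printed in the
# source analysis, so moderate survey-scale defaults are used.
DEFAULT_G = 45
DEFAULT_N_G = 100
DEFAULT_I = 6
DEFAULT_K = 9


@dataclass(frozen=True)
class SimulationDesign:
    """Dimensions and scale of a synthetic study."""

    G: int = DEFAULT_G
    n_g: int = DEFAULT_N_G
    I: int = DEFAULT_I
    scale: RatingScaleSpec = field(default_factory=lambda: RatingScaleSpec(DEFAULT_K))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError("need G >= 2 countries")
        if self.n_g < 1 or self.I < 1:
            raise ValueError("need n_g >= 1 persons per country and I >= 1 items")


@dataclass
class TrueParameters:
    """Ground-truth generating values; arrays sized to a SimulationDesign."""

    beta0: float = 1.0
    beta1: float = 0.0
    beta2: float = 0.0
    sigma_u: float = 0.2
    sigma_theta: float = 1.0
    sigma_eta: float = 0.5
    mu_eta: Optional[np.ndarray] = None  # (G,), defaults to zeros
    x: Optional[np.ndarray] = None  # (G,), standardized covariate
    tau: Optional[np.ndarray] = None  # (I, K-1), grand-sum centered

    def validate(self, design: SimulationDesign) -> None:
        for name in ("sigma_u", "sigma_theta", "sigma_eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu_eta is not None and np.shape(self.mu_eta) != (design.G,):
            raise ValueError(f"mu_eta must have shape ({design.G},)")
        if self.x is not None and np.shape(self.x) != (design.G,):
            raise ValueError(f"x must have shape ({design.G},)")
        if self.tau is not None and np.shape(self.tau) != (
            design.I,
            design.scale.K - 1,
        ):
            raise ValueError(
                f"tau must have shape ({design.I}, {design.scale.K - 1})"
            )


def generate_covariate(G: int, seed) -> np.ndarray:
    """Draw a country covariate and standardize to mean 0, SD 1 (ddof=1).

    The standardization is exact in-sample, matching how observed country
    covariates such as HDI are standardized before entering the regression.
    """
    if G < 2:
        raise ValueError("need G >= 2 countries to standardize a covariate")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(G)
    return (x - x.mean()) / x.std(ddof=1)


def _draw_tau(rng: np.random.Generator, I: int, J: int) -> np.ndarray:
    tau = rng.standard_normal((I, J))
    return tau - tau.mean()  # grand-sum zero, the estimation identification


def simulate_dataset(
    design: SimulationDesign,
    truth: Optional[TrueParameters] = None,
) -> tuple[ResponseDataset, dict]:
    """Generate responses plus a ground-truth record.

    Returns ``(dataset, truth_record)`` where the record carries every
    latent quantity used in generation (country means, person traits,
    thresholds, covariate), sufficient to recompute each response
    probability.
    """
    truth = truth if truth is not None else TrueParameters()
    truth.validate(design)
    G, n_g, I = design.G, design.n_g, design.I
    scale = design.scale
    K, J = scale.K, scale.K - 1
    rng = np.random.default_rng(design.seed)

    x = truth.x if truth.x is not None else generate_covariate(G, rng)
    tau = truth.tau if truth.tau is not None else _draw_tau(rng, I, J)
    mu_eta = (
        np.asarray(truth.mu_eta, dtype=float)
        if truth.mu_eta is not None
        else np.zeros(G)
    )

    u = rng.normal(0.0, truth.sigma_u, size=G)
    mu_theta = truth.beta0 + truth.beta1 * x + truth.beta2 * x**2 + u

    country = np.repeat(np.arange(G), n_g)
    n = G * n_g
    theta = rng.normal(mu_theta[country], truth.sigma_theta)
    eta = rng.normal(mu_eta[country], truth.sigma_eta)

    responses = np.empty((n, I), dtype=np.int64)
    uniforms = rng.random((n, I))
    for i in range(I):
        logits = cumulative_logits(theta, tau[i], eta=eta, s=scale.s)
        m = logits.max(axis=-1, keepdims=True)
        p = np.exp(logits - m)
        p /= p.sum(axis=-1, keepdims=True)
        cdf = np.cumsum(p, axis=-1)
        responses[:, i] = 1 + np.sum(uniforms[:, i : i + 1] > cdf[:, :-1], axis=-1)

    dataset = ResponseDataset(
        responses=responses,
        country=country,
        K=K,
        x=x,
        person_ids=[f"p{p:05d}" for p in range(n)],
        country_ids=[f"c{g:02d}" for g in range(G)],
        item_ids=[f"item{i + 1}" for i in range(I)],
        covariate_mean=0.0,
        covariate_sd=1.0,
    )
    record = {
        "beta0": truth.beta0,
        "beta1": truth.beta1,
        "beta2": truth.beta2,
        "sigma_u": truth.sigma_u,
        "sigma_theta": truth.sigma_theta,
        "sigma_eta": truth.sigma_eta,
        "x": x,
        "u": u,
        "mu_theta": mu_theta,
        "mu_eta": mu_eta,
        "theta": theta,
        "eta": eta,
        "tau": tau,
        "K": K,
        "seed": design.seed,
    }
    return dataset, record


def confound_scenario(
    design: SimulationDesign,
    gamma2: float = -0.5,
    truth: Optional[TrueParameters] = None,
) -> tuple[ResponseDataset, dict]:
    """Spurious-quadratic scenario: style differences mimic a trait trend.

    Sets beta1 = beta2 = 0 (no true trait-covariate relationship) and gives
    the country ERS means a quadratic covariate profile,

        mu_eta_g = gamma2 * (x_g^2 - mean(x^2)),

    centered so the ERS identification constraint holds in truth.  Any
    quadratic trend a naive PCM finds in the trait means is then an artifact
    of scale usage.
    """
    if not np.isfinite(gamma2):
        raise ValueError("gamma2 must be finite")
    base = truth if truth is not None else TrueParameters()
    x = base.x if base.x is not None else generate_covariate(
        design.G, np.random.default_rng(design.seed).integers(2**31)
    )
    mu_eta = gamma2 * (x**2 - np.mean(x**2))
    truth2 = TrueParameters(
        beta0=base.beta0,
        beta1=0.0,
        beta2=0.0,
        sigma_u=base.sigma_u,
        sigma_theta=base.sigma_theta,
        sigma_eta=base.sigma_eta,
        mu_eta=mu_eta,
        x=x,
        tau=base.tau,
    )
    dataset, record = simulate_dataset(design, truth2)
    record["gamma2"] = gamma2
    return dataset, record


def fig1_presets(case: str) -> TrueParameters:
    """Three-country scale-usage scenarios on the nine-point scale.

    Case A: baseline (no style differences, mu_eta = 0).
    Case B: middle-preference countries (mu_eta = -1): the medium
            categories cover wider trait intervals.
    Case C: extreme-preference countries (mu_eta = +1): the outermost
            categories cover wider intervals.
    """
    case = str(case).upper()
    shift = {"A": 0.0, "B": -1.0, "C": 1.0}
    if case not in shift:
        raise ValueError(f"unknown scenario {case!r}; expected one of A, B, C")
    G = 3
    return TrueParameters(
        beta0=0.0,
        sigma_u=0.0,
        sigma_eta=0.0,
        mu_eta=np.full(G, shift[case]),
        x=np.array([-1.0, 0.0, 1.0]),
    )


def write_simulation(
    dataset: ResponseDataset, record: dict, outdir: str | Path
) -> dict[str, Path]:
    """Write dataset + covariates as CSV and the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": outdir / "responses.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.json",
    }
    dataset.to_long().to_csv(paths["responses"], index=False)
    dataset.covariate_frame().to_csv(paths["covariates"], index=False)
    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in record.items()
    }
    paths["truth"].write_text(json.dumps(serializable, indent=1))
    return paths
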