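"""Canonical simulation studies for validating the pipeline.

Each function freezes one study design — the generating truth, the sample
sizes, and the sampler settings — and reruns the full pipeline from data
generation through posterior summaries, so results are reproducible from a
single seed.  They back both the test suite and ``scripts/acceptance.py``.

* :func:`equivalence_study` — maximum deviation between the scoring-weight
  and threshold-shift parameterizations over random parameter draws.
* :func:`recovery_study` — repeated-simulation check that the extended
  model's posterior recovers a known quadratic coefficient.
* :func:`spurious_effect_study` — the response-style trap: a confounded
  dataset with no true trait-covariate relationship is fit with and
  without ERS adjustment.
* :func:`grid_agreement_study` — MCMC versus a dense-grid quadrature
  posterior on a tiny two-country problem.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .data import ResponseDataset
from .model import MultigroupPCM
from .pcm import ext_pcm_category_probs, pcm_category_probs, shifted_thresholds
from .scale import RatingScaleSpec, ers_scoring_weights
from .simulate import SimulationDesign, TrueParameters, confound_scenario, simulate_dataset

__all__ = [
    "equivalence_study",
    "recovery_study",
    "spurious_effect_study",
    "grid_agreement_study",
    "grid_reference_posterior",
]


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2^31 derived from (seed, key)."""
    ss = np.random.SeedSequence([int(seed), *key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def equivalence_study(n_draws: int = 1000, seed: int = 0) -> dict:
    """Max |p_weight - p_shift| over random (K, theta, eta, tau) draws."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_draws):
        K = int(rng.integers(3, 12))
        s = ers_scoring_weights(K)
        theta, eta = rng.normal(size=2) * 2
        tau = rng.normal(size=K - 1) * 2
        a = ext_pcm_category_probs(theta, eta, tau, s)
        b = pcm_category_probs(theta, shifted_thresholds(tau, eta, s))
        max_dev = max(max_dev, float(np.abs(a - b).max()))
    return {"max_abs_deviation": max_dev, "n_draws": n_draws}


# --- parameter recovery ------------------------------------------------

RECOVERY_DESIGN = dict(G=30, n_g=200, I=8, K=9)
RECOVERY_TRUTH = dict(beta0=0.5, beta1=0.2, beta2=-0.3, sigma_u=0.2, sigma_eta=0.5)
RECOVERY_SAMPLER = dict(chains=2, warmup=500, draws=1000)
# datasets whose trait/style trade-off ridge mixes slowly get one rerun
# with much longer chains, triggered by the fit's own convergence flag;
# at most MAX_ESCALATIONS reruns per study keep the total runtime bounded
RECOVERY_ESCALATION = dict(chains=2, warmup=1000, draws=4800)
MAX_ESCALATIONS = 2


def recovery_study(
    n_reps: int = 10,
    seed: int = 0,
    sampler: Optional[dict] = None,
    max_escalations: int = MAX_ESCALATIONS,
) -> dict:
    """Repeated recovery of a known quadratic coefficient (beta2 = -0.3).

    Each replication draws fresh covariates, country effects, person traits
    and modest ERS heterogeneity (country ERS means ~ N(0, 0.3^2),
    centered), then fits the extended model and records whether the 95% CI
    covers the truth.  A replication whose fit is flagged non-converged is
    rerun once with longer chains rather than silently accepted.
    """
    sampler = sampler or RECOVERY_SAMPLER
    truth_beta2 = RECOVERY_TRUTH["beta2"]
    reps = []
    escalations_left = max_escalations
    for rep in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, 1, rep))
        mu_eta = rng.normal(0.0, 0.3, RECOVERY_DESIGN["G"])
        mu_eta -= mu_eta.mean()
        design = SimulationDesign(
            G=RECOVERY_DESIGN["G"],
            n_g=RECOVERY_DESIGN["n_g"],
            I=RECOVERY_DESIGN["I"],
            scale=RatingScaleSpec(RECOVERY_DESIGN["K"]),
            seed=_child_seed(seed, 2, rep),
        )
        ds, rec = simulate_dataset(
            design, TrueParameters(mu_eta=mu_eta, **RECOVERY_TRUTH)
        )
        est = MultigroupPCM(
            variant="ext_pcm", seed=_child_seed(seed, 3, rep), **sampler
        ).fit(ds)
        escalated = False
        if not est.converged_ and escalations_left > 0:
            escalated = True
            escalations_left -= 1
            est = MultigroupPCM(
                variant="ext_pcm",
                seed=_child_seed(seed, 4, rep),
                **RECOVERY_ESCALATION,
            ).fit(ds)
        lo, hi = est.ci_["beta2"]
        reps.append(
            {
                "beta2_mean": est.beta_["beta2"],
                "ci": (lo, hi),
                "covered": bool(lo <= truth_beta2 <= hi),
                "converged": est.converged_,
                "escalated": escalated,
                "ess_beta2": est.diagnostics_["ess_bulk"]["beta2"],
            }
        )
    means = np.array([r["beta2_mean"] for r in reps])
    return {
        "true_beta2": truth_beta2,
        "replications": reps,
        "coverage": int(sum(r["covered"] for r in reps)),
        "n_reps": n_reps,
        "mean_bias": float(means.mean() - truth_beta2),
    }


# --- spurious-effect demonstration -------------------------------------

SPURIOUS_DESIGN = dict(G=30, n_g=100, I=6, K=9)
SPURIOUS_GAMMA2 = -0.5
SPURIOUS_SAMPLER = dict(chains=2, warmup=500, draws=2500)


def spurious_effect_study(seed: int = 0, sampler: Optional[dict] = None) -> dict:
    """Fit both variants to confounded data with no true quadratic effect.

    The generating truth has beta1 = beta2 = 0 while country ERS means carry
    a quadratic covariate signal (gamma2 = -0.5); the naive multigroup PCM
    mistakes the style gradient for a trait trend, the adjusted model does
    not.
    """
    sampler = sampler or SPURIOUS_SAMPLER
    design = SimulationDesign(
        G=SPURIOUS_DESIGN["G"],
        n_g=SPURIOUS_DESIGN["n_g"],
        I=SPURIOUS_DESIGN["I"],
        scale=RatingScaleSpec(SPURIOUS_DESIGN["K"]),
        seed=_child_seed(seed, 10),
    )
    ds, rec = confound_scenario(design, gamma2=SPURIOUS_GAMMA2)
    out = {"true_beta2": rec["beta2"], "gamma2": rec["gamma2"]}
    for variant in ("pcm", "ext_pcm"):
        est = MultigroupPCM(
            variant=variant, seed=_child_seed(seed, 11), **sampler
        ).fit(ds)
        lo, hi = est.ci_["beta2"]
        out[variant] = {
            "beta2_mean": est.beta_["beta2"],
            "ci": (lo, hi),
            "ci_excludes_zero": bool(lo > 0 or hi < 0),
            "beta2_std": est.standardized_beta_["beta2_std"],
            "converged": est.converged_,
        }
    out["abs_attenuation"] = abs(out["pcm"]["beta2_mean"]) - abs(
        out["ext_pcm"]["beta2_mean"]
    )
    return out


# --- grid-posterior smoke test ------------------------------------------

GRID_TAU = np.array([[-0.5, 0.3], [0.4, -0.2]])
GRID_SIGMA_U = 0.3


def _grid_problem(seed: int) -> tuple[ResponseDataset, np.ndarray]:
    tau = GRID_TAU - GRID_TAU.mean()
    design = SimulationDesign(
        G=2, n_g=30, I=2, scale=RatingScaleSpec(3), seed=_child_seed(seed, 20)
    )
    truth = TrueParameters(
        beta0=0.4,
        beta1=0.3,
        sigma_u=GRID_SIGMA_U,
        sigma_eta=0.0,
        mu_eta=np.zeros(2),
        tau=tau,
    )
    ds, _ = simulate_dataset(design, truth)
    return ds, tau


def grid_reference_posterior(
    ds: ResponseDataset,
    tau: np.ndarray,
    sigma_u: float,
    beta_sd: float = 5.0,
    n_nodes: int = 31,
    n_grid: int = 81,
    span: float = 3.0,
) -> dict:
    """Quadrature/grid reference posterior for the linear tiny problem.

    Person traits are integrated out with Gauss-Hermite quadrature, country
    residuals with a second quadrature layer, and (beta0, beta1) live on a
    dense grid with the same N(0, beta_sd^2) priors the sampler uses.
    Independent of the MCMC code path.
    """
    K, y, x = ds.K, ds.responses, ds.x
    zh, wh = hermegauss(n_nodes)
    lwh = np.log(wh) - 0.5 * np.log(2 * np.pi)
    zl, wl = hermegauss(n_nodes)
    lwl = np.log(wl) - 0.5 * np.log(2 * np.pi)
    b0 = np.linspace(-span, span, n_grid)
    b1 = np.linspace(-span, span, n_grid)
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    logpost = np.zeros_like(B0)
    ct = np.concatenate(
        [np.zeros((tau.shape[0], 1)), np.cumsum(tau, axis=1)], axis=1
    )
    kk = np.arange(K)
    for g in range(ds.n_countries):
        yg = y[ds.country == g]
        m = B0 + B1 * x[g]
        theta = m[..., None, None] + sigma_u * zl[:, None] + zh[None, :]
        lp_items = []
        for i in range(tau.shape[0]):
            logits = theta[..., None] * kk - ct[i]
            logits -= logits.max(axis=-1, keepdims=True)
            lp = logits - np.log(np.exp(logits).sum(axis=-1, keepdims=True))
            lp_items.append(lp)
        pats, counts = np.unique(yg, axis=0, return_counts=True)
        log_inner = np.zeros(theta.shape[:3])
        for pat, c in zip(pats, counts):
            lp_pat = sum(lp_items[i][..., pat[i] - 1] for i in range(len(pat)))
            li = np.logaddexp.reduce(lp_pat + lwh, axis=-1)  # per-person integral
            log_inner += c * li
        logpost += np.logaddexp.reduce(log_inner + lwl, axis=-1)
    logpost += -0.5 * (B0**2 + B1**2) / beta_sd**2
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return {
        "beta0_mean": float((w * B0).sum()),
        "beta1_mean": float((w * B1).sum()),
    }


GRID_SAMPLER = dict(chains=2, warmup=500, draws=1500)


def grid_agreement_study(seed: int = 0, sampler: Optional[dict] = None) -> dict:
    """Posterior mean of beta0: MCMC vs the quadrature/grid reference.

    The tiny two-country problem uses the linear-only regression (the
    squared covariate is collinear with the intercept at G=2) with
    thresholds and sigma_u clamped at their generating values, so the grid
    stays two-dimensional and exact.
    """
    sampler = sampler or GRID_SAMPLER
    ds, tau = _grid_problem(seed)
    ref = grid_reference_posterior(ds, tau, GRID_SIGMA_U)
    est = MultigroupPCM(
        variant="pcm",
        quadratic=False,
        fix_tau=tau,
        fix_sigma_u=GRID_SIGMA_U,
        seed=_child_seed(seed, 21),
        **sampler,
    ).fit(ds)
    return {
        "mcmc_beta0": est.beta_["beta0"],
        "grid_beta0": ref["beta0_mean"],
        "abs_difference": abs(est.beta_["beta0"] - ref["beta0_mean"]),
        "mcmc_beta1": est.beta_["beta1"],
        "grid_beta1": ref["beta1_mean"],
    }
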