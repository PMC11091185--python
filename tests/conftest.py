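"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from erspcm.draws import PosteriorDraws


def brute_force_probs(theta, tau, eta=0.0, s=None):
    """Direct summation oracle for (ext-)PCM category probabilities.

    Evaluates the unnormalized terms one by one with plain Python floats —
    independent of the vectorized log-space implementation under test.
    """
    tau = list(tau)
    K = len(tau) + 1
    if s is None:
        s = [0.0] * K
    terms = []
    for k in range(1, K + 1):
        expo = (k - 1) * theta + s[k - 1] * eta
        for j in range(k - 1):
            expo -= tau[j]
        terms.append(np.exp(expo))
    total = sum(terms)
    return np.array([t / total for t in terms])


def affine_to_ci(base: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Rescale draws so their 95% equal-tailed CI is exactly (lo, hi)."""
    b_lo, b_hi = np.quantile(base, [0.025, 0.975])
    d = (hi - lo) / (b_hi - b_lo)
    return lo + d * (base - b_lo)


def make_draws(
    beta1_ci=(-0.2, 0.2),
    beta2_ci=(-0.2, 0.2),
    G=6,
    chains=2,
    T=500,
    seed=0,
    mu_scale=1.0,
    diagnostics=None,
) -> PosteriorDraws:
    """Synthetic PosteriorDraws with controlled coefficient CIs."""
    rng = np.random.default_rng(seed)
    base1 = rng.standard_normal((chains, T))
    base2 = rng.standard_normal((chains, T))
    params = {
        "beta0": rng.standard_normal((chains, T)) * 0.1,
        "beta1": affine_to_ci(base1, *beta1_ci),
        "beta2": affine_to_ci(base2, *beta2_ci),
        "mu_theta": mu_scale * rng.standard_normal((chains, T, G)),
        "sigma_u": np.abs(rng.standard_normal((chains, T))) + 0.1,
    }
    d = PosteriorDraws(params=params, meta={"variant": "synthetic"})
    if diagnostics is not None:
        d.diagnostics = diagnostics
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_fit():
    """A very small but genuine posterior fit, shared across tests."""
    import erspcm as E

    design = E.SimulationDesign(G=4, n_g=30, I=2, scale=E.RatingScaleSpec(5), seed=3)
    truth = E.TrueParameters(beta0=0.3, beta2=-0.2, sigma_u=0.2, sigma_eta=0.3)
    ds, rec = E.simulate_dataset(design, truth)
    est = E.MultigroupPCM(
        variant="ext_pcm", chains=2, warmup=150, draws=200, seed=7
    ).fit(ds)
    return ds, rec, est
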