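"""Convergence diagnostics and posterior interval utilities.

``split_rhat`` is the split-chain potential scale reduction factor: each
chain is halved, and R-hat is sqrt(var_plus / W) with
``var_plus = (n-1)/n W + B/n`` where W is the mean within-half variance and
B the between-half variance of the half means.  Bulk effective sample size
is delegated to arviz.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["split_rhat", "bulk_ess", "credibility_interval"]

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 400.0


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain R-hat for one scalar parameter.

    Parameters
    ----------
    chains : array of shape (n_chains, n_iterations)
        Requires >= 2 chains and >= 4 iterations per chain.  If every split
        half has zero within variance and the half means coincide, the
    statistic is defined as 1.0 (constant chains have trivially converged).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_iterations) array")
    m, n = chains.shape
    if m < 2:
        raise ValueError("split_rhat requires >= 2 chains")
    if n < 4:
        raise ValueError("split_rhat requires >= 4 iterations per chain")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    n_h = half
    W = float(np.mean(np.var(halves, axis=1, ddof=1)))
    B = n_h * float(np.var(np.mean(halves, axis=1), ddof=1))
    # relative guard: constant chains (up to float summation noise) converge
    scale2 = float(np.max(np.abs(halves))) ** 2
    tiny = 1e-28 * max(scale2, 1e-300)
    if W <= tiny:
        return 1.0 if B <= tiny else np.inf
    var_plus = (n_h - 1) / n_h * W + B / n_h
    return float(np.sqrt(var_plus / W))


def bulk_ess(chains: np.ndarray) -> float:
    """Bulk effective sample size (arviz implementation)."""
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("expected (n_chains >= 2, n_iterations) array")
    return float(np.asarray(az.ess(az.convert_to_dataset(chains))["x"]))


def credibility_interval(draws: Iterable[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed posterior interval, pooled across chains.

    Uses linear-interpolation percentiles (numpy's default quantile
    method), so e.g. draws 1..100 at level 0.5 give (25.75, 75.25).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    arr = np.asarray(list(draws) if not isinstance(draws, np.ndarray) else draws,
                     dtype=float).reshape(-1)
    if arr.size < 2:
        raise ValueError("credibility interval needs >= 2 draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
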