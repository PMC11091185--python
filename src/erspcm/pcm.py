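"""Category probabilities and likelihoods for the PCM and its ERS extension.

The Partial Credit Model (PCM) gives the probability of category k in 1..K as

    P(Y = k | theta) = exp(sum_{j<k} (theta - tau_j)) / normalizer,

where ``tau`` are the K-1 item thresholds on the logit scale and the empty
sum (k = 1) is zero.  The ERS-extended model adds a second person trait
``eta`` weighted by the scale's scoring weights ``s_k``:

    P(Y = k | theta, eta) propto exp((k-1) theta + s_k eta - sum_{j<k} tau_j).

With graded weights ``s_k = |k - (K+1)/2|`` this is algebraically identical
to a plain PCM whose thresholds are shifted symmetrically outward/inward by
``eta`` (see :func:`shifted_thresholds`), which is how category-width
differences between countries are represented.

All probability computations run in log space with max-subtraction, so they
remain finite and normalized for parameter magnitudes well beyond anything a
sampler visits.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .scale import RatingScaleSpec

__all__ = [
    "pcm_category_probs",
    "ext_pcm_category_probs",
    "shifted_thresholds",
    "cumulative_logits",
    "response_loglik",
]


def _check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr!r}")
    return arr


def cumulative_logits(theta, tau, eta=None, s=None) -> np.ndarray:
    """Unnormalized log-probabilities for categories 1..K.

    ``theta`` and ``eta`` may be scalars or arrays of a common broadcast
    shape; ``tau`` is the threshold vector of one item.  Returns an array
    with a trailing axis of length K.
    """
    theta = _check_finite("theta", theta)
    tau = _check_finite("tau", tau)
    if tau.ndim != 1:
        raise ValueError("tau must be a 1-d threshold vector")
    K = tau.size + 1
    # cumulative threshold sums: ct_k = sum_{j<k} tau_j, ct_1 = 0
    ct = np.concatenate([[0.0], np.cumsum(tau)])
    k = np.arange(K, dtype=float)  # (k-1) for categories 1..K
    logits = theta[..., None] * k - ct
    if eta is not None:
        eta = _check_finite("eta", eta)
        s = np.asarray(s, dtype=float)
        if s.shape != (K,):
            raise ValueError(
                f"ERS weight vector has shape {s.shape}, expected ({K},) to "
                f"match K={K} categories implied by {tau.size} thresholds"
            )
        logits = logits + eta[..., None] * s
    return logits


def _normalize(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    p = np.exp(logits - m)
    return p / p.sum(axis=-1, keepdims=True)


def pcm_category_probs(theta, tau) -> np.ndarray:
    """PCM category probabilities P(Y = k | theta), k = 1..K.

    Parameters
    ----------
    theta : float or array
        Person location(s) on the latent trait, logit scale.
    tau : array of shape (K-1,)
        Item thresholds (may be disordered; no reordering is applied).

    Returns
    -------
    array with trailing axis K; strictly positive, sums to 1.
    """
    return _normalize(cumulative_logits(theta, tau))


def ext_pcm_category_probs(theta, eta, tau, s) -> np.ndarray:
    """ERS-extended PCM category probabilities.

    ``eta`` is the person's extreme-response-style trait; ``s`` the scale's
    scoring weights (length K). Reduces exactly to the plain PCM at eta = 0
    or constant s.
    """
    return _normalize(cumulative_logits(theta, tau, eta=eta, s=s))


def shifted_thresholds(tau, eta, s) -> np.ndarray:
    """Thresholds of the plain PCM equivalent to the ERS-extended model.

    tau'_j = tau_j + d_j * eta with d_j = s_j - s_{j+1}.  For the default
    graded weights on K=9, d = (1,1,1,1,-1,-1,-1,-1): positive eta raises
    the lower four thresholds and lowers the upper four, widening the
    intervals of the outermost categories (extreme preference); negative
    eta widens the middle.

    For every (theta, eta, tau):
    ``pcm_category_probs(theta, shifted_thresholds(tau, eta, s))`` equals
    ``ext_pcm_category_probs(theta, eta, tau, s)`` to machine precision.
    """
    tau = _check_finite("tau", tau)
    s = np.asarray(s, dtype=float)
    if s.size != tau.size + 1:
        raise ValueError(
            f"weight vector length {s.size} does not match K={tau.size + 1}"
        )
    eta = _check_finite("eta", eta)
    d = -np.diff(s)
    return tau + np.asarray(eta)[..., None] * d


def response_loglik(
    responses: np.ndarray,
    theta: np.ndarray,
    tau: np.ndarray,
    scale: RatingScaleSpec,
    eta: Optional[np.ndarray] = None,
    variant: str = "pcm",
) -> float:
    """Log-likelihood of an ordinal response matrix.

    Parameters
    ----------
    responses : int array of shape (n_persons, n_items)
        Categories in 1..K; entries < 1 mark missing cells, which contribute
        zero (ignorable missingness).
    theta : array (n_persons,)
        Person trait values.
    tau : array (n_items, K-1)
        Item thresholds.
    scale : RatingScaleSpec
    eta : array (n_persons,), required for variant "ext_pcm".
    variant : {"pcm", "ext_pcm"}
    """
    responses = np.asarray(responses)
    theta = _check_finite("theta", np.atleast_1d(theta))
    tau = _check_finite("tau", np.atleast_2d(tau))
    K = scale.K
    if tau.shape[1] != K - 1:
        raise ValueError(f"tau has {tau.shape[1]} thresholds, expected K-1={K - 1}")
    if variant == "ext_pcm":
        if eta is None:
            raise ValueError("variant 'ext_pcm' requires eta")
        eta = _check_finite("eta", np.atleast_1d(eta))
    elif variant == "pcm":
        if eta is not None:
            raise ValueError("variant 'pcm' does not accept eta")
    else:
        raise ValueError(f"unknown variant {variant!r}")

    obs = responses >= 1
    bad = obs & (responses > K)
    if np.any(bad):
        p, i = np.argwhere(bad)[0]
        raise ValueError(
            f"response {responses[p, i]} outside 1..{K} at person index {p}, "
            f"item index {i}"
        )

    total = 0.0
    for i in range(tau.shape[0]):
        logits = cumulative_logits(
            theta, tau[i], eta=eta if variant == "ext_pcm" else None,
            s=scale.s if variant == "ext_pcm" else None,
        )
        m = logits.max(axis=-1)
        lse = m + np.log(np.exp(logits - m[..., None]).sum(axis=-1))
        y = responses[:, i]
        o = obs[:, i]
        if np.any(o):
            total += float(
                np.sum(logits[o, y[o] - 1] - lse[o])
            )
    return total
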