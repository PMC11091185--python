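"""MCMC for the multigroup PCM latent-regression models.

A seeded Metropolis-within-Gibbs scheme targeting the posterior defined in
:mod:`erspcm.posterior`:

* person traits theta_p (and eta_p in the extended variant): vectorized
  single-site random-walk Metropolis, proposal scales adapted during warmup;
* item thresholds: per-item blocked random-walk Metropolis;
* country trait means and regression coefficients: exact conjugate Gibbs;
* country ERS means: exact Gibbs draw of the Gaussian full conditional
  restricted to the sum-zero identification subspace;
* sigma_u, sigma_eta and the ERS-mean hyper-SD: univariate slice sampling
  on the log scale (half-Normal priors);
* two likelihood-invariant "shift" moves that traverse the weakly
  identified directions (overall location of thresholds vs. beta0, and the
  ERS-trait location vs. symmetric threshold shifts), accepted on the prior
  ratio alone.

The overall threshold location is softly identified by the priors during
sampling; every *stored* draw is projected exactly onto the grand-sum-zero
constraint along the invariance direction (tau -> tau - c,
beta0 -> beta0 - c, mu_theta -> mu_theta - c with c the grand threshold
mean), so saved draws satisfy all identification constraints to machine
precision while the likelihood value is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from ._kernels import cumulative_tau, fisher_tradeoff, loglik_item, loglik_matrix
from .data import ResponseDataset
from .draws import PosteriorDraws
from .posterior import PriorSpec
from .scale import RatingScaleSpec

__all__ = ["SamplerConfig", "sample_posterior"]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler settings; every random stream derives from ``seed``."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    fix_tau: Optional[np.ndarray] = None  # testing/calibration hook
    fix_sigma_u: Optional[float] = None  # testing/calibration hook

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.warmup < 10 or self.draws < 10:
            raise ValueError("warmup and draws must each be >= 10")


def _slice_sample(
    x0: float,
    logf: Callable[[float], float],
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampler with stepping-out and shrinkage."""
    f0 = logf(x0)
    level = f0 + np.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logf(lo) <= level:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= level:
            break
        hi += w
    for _ in range(200):
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > level:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # numerically degenerate slice; keep current value


def _halfnormal_log(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


@dataclass
class _ChainState:
    theta: np.ndarray
    eta: np.ndarray
    mu_theta: np.ndarray
    beta: np.ndarray
    sigma_u: float
    mu_eta: np.ndarray
    sigma_eta: float
    sigma_mu_eta: float
    tau: np.ndarray
    ctau: np.ndarray
    LL: np.ndarray


class _Problem:
    """Immutable per-fit data and settings shared by all chains."""

    def __init__(
        self,
        data: ResponseDataset,
        variant: str,
        scale: RatingScaleSpec,
        priors: PriorSpec,
        quadratic: bool,
        config: SamplerConfig,
    ):
        if variant not in ("pcm", "ext_pcm"):
            raise ValueError(f"unknown variant {variant!r}")
        if data.x is None:
            raise ValueError("latent regression needs a country covariate")
        self.variant = variant
        self.scale = scale
        self.priors = priors
        self.config = config
        self.y = np.ascontiguousarray(data.responses, dtype=np.int64)
        self.country = data.country
        self.G = data.n_countries
        self.n, self.I = self.y.shape
        self.K = scale.K
        self.J = self.K - 1
        self.n_g = np.bincount(self.country, minlength=self.G).astype(float)
        if np.any(self.n_g == 0):
            raise ValueError("every country index must have at least one person")
        self.x = data.x
        P = 3 if quadratic else 2
        self.X = np.column_stack([np.ones(self.G), self.x, self.x**2])[:, :P]
        self.P = P
        # ERS weights enter kernels; the plain PCM is the zero-weight case
        self.s = scale.s.copy() if variant == "ext_pcm" else np.zeros(self.K)
        self.d = scale.threshold_shift_directions()
        # cumulative shift direction: ctau offset when tau -> tau - d*c
        self.cum_d = np.concatenate([[0.0], np.cumsum(self.d)])
        self.obs_per_person = (self.y >= 1).sum(axis=1)


def _init_state(prob: _Problem, rng: np.random.Generator) -> _ChainState:
    n, I, G, J = prob.n, prob.I, prob.G, prob.J
    obs = prob.y >= 1
    with np.errstate(invalid="ignore"):
        pm = np.where(
            obs.any(axis=1),
            prob.y.sum(axis=1) / np.maximum(obs.sum(axis=1), 1),
            (prob.K + 1) / 2.0,
        )
    z = (pm - pm.mean()) / max(pm.std(), 1e-6)
    theta = z + 0.3 * rng.standard_normal(n)
    eta = 0.2 * rng.standard_normal(n)
    if prob.config.fix_tau is not None:
        tau = np.array(prob.config.fix_tau, dtype=float).reshape(I, J)
    else:
        tau = 0.1 * rng.standard_normal((I, J))
    mu_theta = np.bincount(prob.country, weights=theta, minlength=G) / prob.n_g
    beta = 0.1 * rng.standard_normal(prob.P)
    beta[0] += mu_theta.mean()
    sigma_u = float(
        prob.config.fix_sigma_u
        if prob.config.fix_sigma_u is not None
        else 0.5 * np.exp(0.3 * rng.standard_normal())
    )
    state = _ChainState(
        theta=theta,
        eta=eta if prob.variant == "ext_pcm" else np.zeros(n),
        mu_theta=mu_theta,
        beta=beta,
        sigma_u=sigma_u,
        mu_eta=np.zeros(G),
        sigma_eta=0.5 * float(np.exp(0.3 * rng.standard_normal())),
        sigma_mu_eta=0.5,
        tau=tau,
        ctau=cumulative_tau(tau),
        LL=np.empty((n, I)),
    )
    loglik_matrix(state.theta, state.eta, state.ctau, prob.s, prob.y, state.LL)
    return state


def _update_persons(
    prob: _Problem,
    st: _ChainState,
    rng: np.random.Generator,
    scale_theta: float,
    scale_eta: float,
    buf: np.ndarray,
    joint: bool,
) -> float:
    """Vectorized random-walk MH for the person latents.

    For the extended variant theta and eta are proposed jointly (one
    likelihood evaluation per sweep instead of two); the plain PCM updates
    theta alone.
    """
    prop_theta = st.theta + scale_theta * rng.standard_normal(prob.n)
    mu_t = st.mu_theta[prob.country]
    dlp = (-((prop_theta - mu_t) ** 2) + (st.theta - mu_t) ** 2) / 2.0
    if joint:
        prop_eta = st.eta + scale_eta * rng.standard_normal(prob.n)
        mu_e = st.mu_eta[prob.country]
        dlp += (-((prop_eta - mu_e) ** 2) + (st.eta - mu_e) ** 2) / (
            2.0 * st.sigma_eta**2
        )
    else:
        prop_eta = st.eta
    loglik_matrix(prop_theta, prop_eta, st.ctau, prob.s, prob.y, buf)
    dll = (buf - st.LL).sum(axis=1)
    accept = np.log(rng.random(prob.n)) < dll + dlp
    st.theta[accept] = prop_theta[accept]
    if joint:
        st.eta[accept] = prop_eta[accept]
    st.LL[accept] = buf[accept]
    return float(accept.mean())


def _update_tau(
    prob: _Problem,
    st: _ChainState,
    rng: np.random.Generator,
    scales: np.ndarray,
    buf: np.ndarray,
) -> float:
    acc = 0.0
    tau_var = prob.priors.tau_sd**2
    for i in range(prob.I):
        prop = st.tau[i] + scales[i] * rng.standard_normal(prob.J)
        ctau_i = np.concatenate([[0.0], np.cumsum(prop)])
        loglik_item(st.theta, st.eta, ctau_i, prob.s, prob.y[:, i], buf)
        dll = buf.sum() - st.LL[:, i].sum()
        dlp = float((-(prop**2) + st.tau[i] ** 2).sum()) / (2.0 * tau_var)
        if np.log(rng.random()) < dll + dlp:
            st.tau[i] = prop
            st.ctau[i] = ctau_i
            st.LL[:, i] = buf
            acc += 1.0
    return acc / prob.I


def _shift_location(
    prob: _Problem, st: _ChainState, rng: np.random.Generator, scale_prop: float
) -> float:
    """Likelihood-invariant move along (beta0, mu_theta, theta, tau) += c."""
    c = scale_prop * rng.standard_normal()
    tau_var = prob.priors.tau_sd**2
    beta_var = prob.priors.beta_sd**2
    dlp = (-((st.beta[0] + c) ** 2) + st.beta[0] ** 2) / (2 * beta_var)
    dlp += float((-((st.tau + c) ** 2) + st.tau**2).sum()) / (2 * tau_var)
    if np.log(rng.random()) < dlp:
        st.theta += c
        st.mu_theta += c
        st.beta[0] += c
        st.tau += c
        st.ctau += np.arange(prob.K) * c
        return 1.0
    return 0.0


def _shift_ers(
    prob: _Problem, st: _ChainState, rng: np.random.Generator, scale_prop: float
) -> float:
    """Likelihood-invariant move eta += c, tau_ij -= d_j c (symmetric shifts)."""
    c = scale_prop * rng.standard_normal()
    tau_var = prob.priors.tau_sd**2
    tau_prop = st.tau - prob.d * c
    mu = st.mu_eta[prob.country]
    dlp = float((-(st.eta + c - mu) ** 2 + (st.eta - mu) ** 2).sum()) / (
        2 * st.sigma_eta**2
    )
    dlp += float((-(tau_prop**2) + st.tau**2).sum()) / (2 * tau_var)
    if np.log(rng.random()) < dlp:
        st.eta += c
        st.tau = tau_prop
        st.ctau = st.ctau - prob.cum_d * c
        return 1.0
    return 0.0


def _ridge_move(
    prob: _Problem,
    st: _ChainState,
    rng: np.random.Generator,
    a_g: np.ndarray,
    direction: np.ndarray,
    scale_prop: float,
    buf: np.ndarray,
) -> float:
    """Country-level move along the trait/style trade-off ridge.

    Proposes eta_p += c_g(p), mu_eta_g += c_g with c = delta * direction
    (a fixed mean-zero country contrast, so the ERS sum-zero constraint is
    preserved), together with the Fisher-compensating trait shift
    theta_p += a_g c_g, mu_theta_g += a_g c_g.  Each contrast direction
    keeps its own adapted step size: the likelihood curvature along the
    linear and quadratic covariate contrasts can differ by orders of
    magnitude, and a shared scale would collapse to the stiffest one.  The within-country
    hierarchy terms are invariant; only the likelihood (nearly flat along
    the ridge), the ERS-mean prior and the latent-regression term enter
    the ratio.  ``a_g`` and the directions are frozen after warmup,
    keeping the proposal symmetric.

    Without this move the quadratic contrast of the country ERS means —
    the coordinate the confound scenario lives on — mixes only through
    person-level random walks and can have autocorrelation times in the
    hundreds; moving along the locally likelihood-flat direction restores
    ordinary mixing for the regression coefficients.
    """
    # occasional long jumps help traverse the full length of the ridge
    kick = 4.0 if rng.random() < 0.2 else 1.0
    c = (kick * scale_prop * rng.standard_normal()) * direction
    theta_p = st.theta + (a_g * c)[prob.country]
    eta_p = st.eta + c[prob.country]
    loglik_matrix(theta_p, eta_p, st.ctau, prob.s, prob.y, buf)
    dll = float((buf - st.LL).sum())
    mu_eta_p = st.mu_eta + c
    dlp = float((-(mu_eta_p**2) + st.mu_eta**2).sum()) / (2 * st.sigma_mu_eta**2)
    m_reg = prob.X @ st.beta
    mu_theta_p = st.mu_theta + a_g * c
    dlp += float(
        (-((mu_theta_p - m_reg) ** 2) + (st.mu_theta - m_reg) ** 2).sum()
    ) / (2 * st.sigma_u**2)
    if np.log(rng.random()) < dll + dlp:
        st.theta = theta_p
        st.eta = eta_p
        st.mu_theta = mu_theta_p
        st.mu_eta = mu_eta_p
        st.LL = buf.copy()
        return 1.0
    return 0.0


def _gibbs_mu_theta(prob: _Problem, st: _ChainState, rng: np.random.Generator) -> None:
    sums = np.bincount(prob.country, weights=st.theta, minlength=prob.G)
    m_reg = prob.X @ st.beta
    prec = prob.n_g + 1.0 / st.sigma_u**2
    mean = (sums + m_reg / st.sigma_u**2) / prec
    st.mu_theta = mean + rng.standard_normal(prob.G) / np.sqrt(prec)


def _gibbs_beta(prob: _Problem, st: _ChainState, rng: np.random.Generator) -> None:
    su2 = st.sigma_u**2
    V_inv = prob.X.T @ prob.X / su2 + np.eye(prob.P) / prob.priors.beta_sd**2
    L = np.linalg.cholesky(V_inv)
    rhs = prob.X.T @ st.mu_theta / su2
    mean = np.linalg.solve(V_inv, rhs)
    z = rng.standard_normal(prob.P)
    st.beta = mean + np.linalg.solve(L.T, z)


def _slice_sigma_u(prob: _Problem, st: _ChainState, rng: np.random.Generator) -> None:
    resid2 = float(((st.mu_theta - prob.X @ st.beta) ** 2).sum())
    G = prob.G
    scale = prob.priors.sigma_u_scale

    def logf(t: float) -> float:
        s = np.exp(t)
        return -G * t - resid2 / (2 * s * s) + _halfnormal_log(s, scale) + t

    st.sigma_u = float(np.exp(_slice_sample(np.log(st.sigma_u), logf, rng)))


def _gibbs_mu_eta(prob: _Problem, st: _ChainState, rng: np.random.Generator) -> None:
    """Exact Gibbs draw of mu_eta restricted to the sum-zero subspace."""
    sums = np.bincount(prob.country, weights=st.eta, minlength=prob.G)
    prec = prob.n_g / st.sigma_eta**2 + 1.0 / st.sigma_mu_eta**2
    mean = (sums / st.sigma_eta**2) / prec
    d = 1.0 / prec  # conditional variances
    z = mean + rng.standard_normal(prob.G) * np.sqrt(d)
    st.mu_eta = z - d * (z.sum() / d.sum())


def _slice_sigma_eta(prob: _Problem, st: _ChainState, rng: np.random.Generator) -> None:
    resid2 = float(((st.eta - st.mu_eta[prob.country]) ** 2).sum())
    n = prob.n
    scale = prob.priors.sigma_eta_scale

    def logf(t: float) -> float:
        s = np.exp(t)
        return -n * t - resid2 / (2 * s * s) + _halfnormal_log(s, scale) + t

    st.sigma_eta = float(np.exp(_slice_sample(np.log(st.sigma_eta), logf, rng)))


def _slice_sigma_mu_eta(prob: _Problem, st: _ChainState, rng: np.random.Generator) -> None:
    ss = float((st.mu_eta**2).sum())
    Gm1 = prob.G - 1  # restricted (sum-zero) dimension
    scale = prob.priors.mu_eta_hyper_scale

    def logf(t: float) -> float:
        s = np.exp(t)
        return -Gm1 * t - ss / (2 * s * s) + _halfnormal_log(s, scale) + t

    st.sigma_mu_eta = float(np.exp(_slice_sample(np.log(st.sigma_mu_eta), logf, rng)))


def _run_chain(
    prob: _Problem, chain: int, seed_seq: np.random.SeedSequence
) -> dict[str, np.ndarray]:
    cfg = prob.config
    rng = np.random.default_rng(seed_seq)
    st = _init_state(prob, rng)
    ext = prob.variant == "ext_pcm"
    free_tau = cfg.fix_tau is None
    free_su = cfg.fix_sigma_u is None

    buf = np.empty((prob.n, prob.I))
    buf_item = np.empty(prob.n)
    # adaptive proposal scales
    sc = {"theta": 0.6 if ext else 0.8, "eta": 0.45, "loc": 0.15, "ers": 0.08}
    sc_tau = np.full(prob.I, 0.15)
    targets = {"person": 0.35 if ext else 0.44, "loc": 0.44, "ers": 0.44}
    a_g = np.zeros(prob.G)  # trait/style trade-off slopes, frozen post-warmup
    # ridge-move directions: orthonormal mean-zero contrasts spanning the
    # regression covariates (where the style/trait confound lives)
    u1 = prob.x - prob.x.mean()
    u1 /= np.linalg.norm(u1)
    dirs = [u1]
    if prob.P == 3:
        u2 = prob.x**2 - (prob.x**2).mean()
        u2 -= (u2 @ u1) * u1
        norm = np.linalg.norm(u2)
        if norm > 1e-8:
            dirs.append(u2 / norm)
    ridge_dirs = np.vstack(dirs)
    sc_ridge = np.full(ridge_dirs.shape[0], 0.1)

    T = cfg.draws
    out = {
        "beta": np.empty((T, prob.P)),
        "sigma_u": np.empty(T),
        "mu_theta": np.empty((T, prob.G)),
        "tau": np.empty((T, prob.I, prob.J)),
    }
    if ext:
        out["mu_eta"] = np.empty((T, prob.G))
        out["sigma_eta"] = np.empty(T)
        out["sigma_mu_eta"] = np.empty(T)

    total = cfg.warmup + cfg.draws
    acc_log: dict[str, float] = {k: 0.0 for k in ("theta", "eta", "tau")}
    for t in range(total):
        adapting = t < cfg.warmup
        gamma = 0.06 if t < cfg.warmup // 2 else 0.02

        a = _update_persons(prob, st, rng, sc["theta"], sc["eta"], buf, joint=ext)
        if adapting:
            f = np.exp(gamma * (a - targets["person"]))
            sc["theta"] *= f
            sc["eta"] *= f
        elif t >= cfg.warmup:
            acc_log["theta"] += a
        if ext:
            if adapting and t % 50 == 10:
                tt, te = fisher_tradeoff(
                    st.theta, st.eta, st.ctau, prob.s, prob.y, prob.country, prob.G
                )
                a_g = -te / np.maximum(tt, 1e-12)
            for j in range(ridge_dirs.shape[0]):
                a = _ridge_move(prob, st, rng, a_g, ridge_dirs[j], sc_ridge[j], buf)
                if adapting:
                    sc_ridge[j] *= np.exp(gamma * (a - 0.2))
                elif t >= cfg.warmup:
                    acc_log["eta"] += a / ridge_dirs.shape[0]
        if free_tau:
            a = _update_tau(prob, st, rng, sc_tau, buf_item)
            if adapting:
                sc_tau *= np.exp(gamma * (a - 0.3))
            elif t >= cfg.warmup:
                acc_log["tau"] += a
            a = _shift_location(prob, st, rng, sc["loc"])
            if adapting:
                sc["loc"] *= np.exp(gamma * (a - targets["loc"]))
            if ext:
                a = _shift_ers(prob, st, rng, sc["ers"])
                if adapting:
                    sc["ers"] *= np.exp(gamma * (a - targets["ers"]))

        _gibbs_mu_theta(prob, st, rng)
        _gibbs_beta(prob, st, rng)
        if free_su:
            _slice_sigma_u(prob, st, rng)
        if ext:
            _gibbs_mu_eta(prob, st, rng)
            _slice_sigma_eta(prob, st, rng)
            _slice_sigma_mu_eta(prob, st, rng)

        if t >= cfg.warmup:
            k = t - cfg.warmup
            # exact projection onto the grand-sum-zero threshold constraint
            c = st.tau.mean() if free_tau else 0.0
            out["beta"][k] = st.beta
            out["beta"][k, 0] -= c
            out["sigma_u"][k] = st.sigma_u
            out["mu_theta"][k] = st.mu_theta - c
            out["tau"][k] = st.tau - c
            if ext:
                out["mu_eta"][k] = st.mu_eta
                out["sigma_eta"][k] = st.sigma_eta
                out["sigma_mu_eta"][k] = st.sigma_mu_eta

    logger.info(
        "chain %d done: acc theta=%.2f eta=%.2f tau=%.2f",
        chain,
        acc_log["theta"] / T,
        acc_log["eta"] / T if ext else float("nan"),
        acc_log["tau"] / T,
    )
    return out


def sample_posterior(
    data: ResponseDataset,
    variant: str = "ext_pcm",
    priors: Optional[PriorSpec] = None,
    scale: Optional[RatingScaleSpec] = None,
    quadratic: bool = True,
    config: Optional[SamplerConfig] = None,
) -> PosteriorDraws:
    """Draw from the posterior of the chosen model variant.

    Returns a :class:`PosteriorDraws` whose stored draws satisfy the
    identification constraints exactly (thresholds grand-sum zero; country
    ERS means sum zero; sigma_theta = 1 by construction).
    """
    priors = priors or PriorSpec()
    scale = scale or RatingScaleSpec(data.K)
    config = config or SamplerConfig()
    if variant == "ext_pcm" and not scale.ers_identified:
        from .scale import UnidentifiableERSError

        raise UnidentifiableERSError(
            "ext_pcm requires K >= 3 and non-constant ERS weights; the "
            "extreme-response-style dimension is unidentified on this scale"
        )
    prob = _Problem(data, variant, scale, priors, quadratic, config)

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.chains)
    chain_results = [
        _run_chain(prob, c, children[c]) for c in range(config.chains)
    ]

    params: dict[str, np.ndarray] = {}
    first = chain_results[0]
    for name in first:
        params[name] = np.stack([r[name] for r in chain_results], axis=0)
    # split regression coefficients into named scalars
    beta = params.pop("beta")
    for j in range(beta.shape[-1]):
        params[f"beta{j}"] = beta[..., j]
    meta = {
        "variant": variant,
        "chains": config.chains,
        "warmup": config.warmup,
        "draws": config.draws,
        "seed": config.seed,
        "quadratic": quadratic,
        "K": scale.K,
        "n_persons": prob.n,
        "n_items": prob.I,
        "n_countries": prob.G,
        "x": prob.x.tolist(),
    }
    return PosteriorDraws(params=params, meta=meta)
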