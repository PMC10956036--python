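"""The meta-d' observer model: type-2 sensitivity, efficiency and bias.

Meta-d' is the type-1 sensitivity that a metacognitively optimal observer —
holding the empirical type-1 criterion fixed — would need in order to produce
the observed confidence data.  The model places unit-variance normal evidence
distributions at ``±meta_d/2`` on a meta-level decision axis, keeps the
relative type-1 criterion where the data put it (``meta_c = c' · meta_d``),
and partitions each response region into K confidence bands with K-1 type-2
criteria per response side.  Confidence counts conditional on (stimulus,
response) are multinomial with the band probabilities renormalised within the
response region.

Fitting maximises that conditional multinomial likelihood over ``meta_d`` and
the two criteria ladders (MLE via L-BFGS with an analytic gradient, ordering
enforced by log-increment re-parameterisation), or samples the posterior with
an affine-invariant ensemble sampler.  Derived quantities:

* ``m_ratio = meta_d / d'`` — metacognitive efficiency (1 = ideal insight);
* ``log_efficiency = log(m_ratio)`` — the analysis-scale transform;
* ``confidence_criterion`` — mean |type-2 c' − type-1 c'| over the K-1
  criteria of each response side, then averaged over sides; larger values
  mean a bias towards *low* confidence.

Negative meta-d' (confidence anti-correlated with accuracy) is representable
in the MLE so that the ``m_ratio < 0`` exclusion screen can observe it; the
log transform and the public probability predictor refuse it.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .sdt import RatingCounts, Type1Estimates, type1_fit

__all__ = [
    "MetaDFit",
    "McmcParams",
    "predict_type2_probs",
    "fit_metad",
    "confidence_criterion",
    "efficiency",
    "type2_loglik",
]

_PHI = norm.cdf
_phi = norm.pdf
_TINY = 1e-300


@dataclass
class McmcParams:
    """Sampler settings (defaults follow the single-subject fitting recipe)."""

    nchains: int = 3
    nburnin: int = 1000
    nsamples: int = 10000
    nthin: int = 1
    seed: int = 0


@dataclass
class MetaDFit:
    """Fitted type-1 + type-2 parameters for one participant/task."""

    type1: Type1Estimates
    meta_d: float
    meta_c: float
    t2c_left: np.ndarray   # K-1 criteria, non-increasing away from meta_c
    t2c_right: np.ndarray  # K-1 criteria, non-decreasing away from meta_c
    m_ratio: float
    log_efficiency: float  # nan when m_ratio <= 0
    confidence_criterion: float
    loglik: float
    method: str
    K: int
    degenerate: bool = False
    posterior: Optional[dict] = None


def _band_probs(meta_d: float, meta_c: float, t2c_left: np.ndarray,
                t2c_right: np.ndarray, K: int) -> np.ndarray:
    """(2, 2, K) table of P(confidence = y | stimulus s, response r)."""
    mu = np.array([-meta_d / 2.0, meta_d / 2.0])  # stimulus left, right
    out = np.empty((2, 2, K))
    # response "right": ascending boundaries meta_c = b0 < b1 <= ... < inf
    b = np.concatenate([[meta_c], np.asarray(t2c_right, float), [np.inf]])
    cdf = _PHI(b[None, :] - mu[:, None])                       # (2, K+1)
    num = np.diff(cdf, axis=1)                                 # (2, K)
    den = 1.0 - cdf[:, 0]
    out[:, 1, :] = num / np.maximum(den, _TINY)[:, None]
    # response "left": descending boundaries meta_c = a0 > a1 >= ... > -inf
    a = np.concatenate([[meta_c], np.asarray(t2c_left, float), [-np.inf]])
    cdf = _PHI(a[None, :] - mu[:, None])
    num = -np.diff(cdf, axis=1)
    den = cdf[:, 0]
    out[:, 0, :] = num / np.maximum(den, _TINY)[:, None]
    return out


def predict_type2_probs(meta_d: float, meta_c: float, t2c_left: np.ndarray,
                        t2c_right: np.ndarray, K: int) -> np.ndarray:
    """Conditional confidence distribution P(y | stimulus, response).

    Returns an array indexed ``[stimulus, response, confidence-1]`` whose
    every (stimulus, response) slice sums to 1.
    """
    t2c_left = np.asarray(t2c_left, float)
    t2c_right = np.asarray(t2c_right, float)
    if meta_d < 0:
        raise ValueError("meta_d must be >= 0")
    if len(t2c_left) != K - 1 or len(t2c_right) != K - 1:
        raise ValueError(f"need K-1 = {K - 1} criteria per response side")
    if np.any(np.diff(t2c_right) < 0) or np.any(t2c_right < meta_c):
        raise ValueError("t2c_right must be >= meta_c and non-decreasing")
    if np.any(np.diff(t2c_left) > 0) or np.any(t2c_left > meta_c):
        raise ValueError("t2c_left must be <= meta_c and non-increasing")
    return _band_probs(meta_d, meta_c, t2c_left, t2c_right, K)


def type2_loglik(data: np.ndarray, meta_d: float, meta_c: float,
                 t2c_left: np.ndarray, t2c_right: np.ndarray, K: int) -> float:
    """Multinomial log-likelihood of a (2,2,K) count table under the model."""
    p = _band_probs(meta_d, meta_c, t2c_left, t2c_right, K)
    return float(np.sum(data * np.log(np.maximum(p, _TINY))))


# ---------------------------------------------------------------------------
# MLE with analytic gradient
#
# Parameter vector theta = [meta_d, zL_1..zL_{K-1}, zR_1..zR_{K-1}] with
#   t2c_right = meta_c + cumsum(exp(zR)),  t2c_left = meta_c - cumsum(exp(zL)),
#   meta_c    = c_rel * meta_d.
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, c_rel: float, K: int):
    m = theta[0]
    meta_c = c_rel * m
    incL = np.exp(theta[1:K])
    incR = np.exp(theta[K:2 * K - 1])
    t2c_left = meta_c - np.cumsum(incL)
    t2c_right = meta_c + np.cumsum(incR)
    return m, meta_c, t2c_left, t2c_right, incL, incR


def _negloglik_grad(theta: np.ndarray, data: np.ndarray, c_rel: float, K: int):
    m, meta_c, t2c_left, t2c_right, incL, incR = _unpack(theta, c_rel, K)
    mu = np.array([-m / 2.0, m / 2.0])
    musign = np.array([-0.5, 0.5])  # d mu_s / d m
    ll = 0.0
    g_m = 0.0
    gL = np.zeros(K - 1)
    gR = np.zeros(K - 1)

    for r, bounds, sign in ((1, np.concatenate([[meta_c], t2c_right]), 1.0),
                            (0, np.concatenate([[meta_c], t2c_left]), -1.0)):
        # `sign` = +1: upper-tail region (right responses); -1: lower tail.
        x = bounds[None, :] - mu[:, None]            # (2, K)
        cdf = _PHI(x)
        pdf = _phi(x)
        if sign > 0:
            full = np.concatenate([cdf, np.ones((2, 1))], axis=1)
            num = np.diff(full, axis=1)              # (2, K) band probs (unnorm)
            den = 1.0 - cdf[:, 0]
        else:
            full = np.concatenate([cdf, np.zeros((2, 1))], axis=1)
            num = -np.diff(full, axis=1)
            den = cdf[:, 0]
        num = np.maximum(num, _TINY)
        den = np.maximum(den, _TINY)
        n = data[:, r, :]                            # (2, K)
        n_tot = n.sum(axis=1)
        ll += float(np.sum(n * np.log(num)) - np.sum(n_tot * np.log(den)))

        # dLL/d(boundary_j) per stimulus s; boundary j = 0..K-1
        w = n / num                                  # (2, K)
        dB = np.zeros((2, K))
        if sign > 0:
            # d num_y / d b_j: +pdf_j at y=j, -pdf_j at y=j+1 (0-based: band j-1 / j)
            dB[:, 1:] = pdf[:, 1:] * (w[:, :-1] - w[:, 1:])
            dB[:, 0] = pdf[:, 0] * (-w[:, 0] + n_tot / den)
        else:
            dB[:, 1:] = pdf[:, 1:] * (-w[:, :-1] + w[:, 1:])
            dB[:, 0] = pdf[:, 0] * (w[:, 0] - n_tot / den)

        # chain rule: boundaries depend on meta_c (all), increments, and mu
        g_m += float(np.sum(dB) * c_rel)             # via meta_c = c_rel * m
        g_m += float(np.sum(-dB.sum(axis=1) * musign))  # via mu_s = ±m/2
        # increments: boundary j (j>=1) = meta_c ± cumsum(inc)_j
        tail = np.cumsum(dB[:, ::-1], axis=1)[:, ::-1].sum(axis=0)  # sum_{j>=i} dB_j
        if sign > 0:
            gR += incR * tail[1:]
        else:
            # a_j = meta_c - cumsum(incL)_j, so d a_j / d zL_i = -incL_i for i <= j
            gL += -incL * tail[1:]
    grad = np.concatenate([[g_m], gL, gR])
    return -ll, -grad


def fit_metad(counts: RatingCounts, method: str = "mle",
              mcmc: McmcParams | None = None, padding: float | None = None,
              n_starts: int = 3) -> MetaDFit:
    """Fit the meta-d' model to one participant's rating counts.

    Type-1 parameters are fixed at their closed-form estimates; ``meta_c`` is
    tied to ``c' * meta_d`` throughout.  ``method="mle"`` returns the
    maximum-likelihood point (meta_d unconstrained in sign); ``method="mcmc"``
    samples the posterior (meta_d > 0 via a log-Mratio parameterisation) and
    reports posterior means.
    """
    K = counts.K
    if padding is None:
        padding = 1.0 / (2 * K)
    t1 = type1_fit(counts, padding=padding)
    data = counts.counts + padding
    c_rel = t1.c_rel
    if not np.isfinite(c_rel):
        c_rel = 0.0

    conf_marg = counts.counts.sum(axis=(0, 1))
    degenerate = bool(np.count_nonzero(conf_marg) <= 1)

    if method == "mle":
        theta, ll = _fit_mle(data, c_rel, K, t1, n_starts)
        m, meta_c, t2c_left, t2c_right, _, _ = _unpack(theta, c_rel, K)
        posterior = None
    elif method == "mcmc":
        if mcmc is None:
            mcmc = McmcParams()
        m, meta_c, t2c_left, t2c_right, ll, posterior = _fit_mcmc(
            data, c_rel, K, t1, mcmc)
    else:
        raise ValueError(f"unknown method {method!r}")

    d = t1.d_prime
    m_ratio = m / d if d != 0 else float("nan")
    log_eff = float(np.log(m_ratio)) if m_ratio > 0 else float("nan")
    fit = MetaDFit(type1=t1, meta_d=float(m), meta_c=float(meta_c),
                   t2c_left=np.asarray(t2c_left), t2c_right=np.asarray(t2c_right),
                   m_ratio=float(m_ratio), log_efficiency=log_eff,
                   confidence_criterion=float("nan"), loglik=float(ll),
                   method=method, K=K, degenerate=degenerate,
                   posterior=posterior)
    fit.confidence_criterion = confidence_criterion(fit)
    return fit


def _fit_mle(data, c_rel, K, t1, n_starts):
    d = t1.d_prime
    starts = [max(d, 0.1), 0.25 * max(d, 0.1), -0.5 * max(d, 0.1)][:max(n_starts, 1)]
    bounds = [(-10.0, 10.0)] + [(-7.0, 3.0)] * (2 * K - 2)
    best = None
    for m0 in starts:
        theta0 = np.empty(2 * K - 1)
        theta0[0] = m0
        theta0[1:] = np.log(0.4)
        res = minimize(_negloglik_grad, theta0, args=(data, c_rel, K),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("meta-d' MLE failed to converge")
    return best.x, -best.fun


def _batch_loglik(data: np.ndarray, m: np.ndarray, meta_c: np.ndarray,
                  offL: np.ndarray, offR: np.ndarray, K: int) -> np.ndarray:
    """Type-2 log-likelihood for a batch of parameter sets (vectorised)."""
    W = len(m)
    mu = np.stack([-m / 2.0, m / 2.0], axis=1)            # (W, 2)
    ll = np.zeros(W)
    for r, off_sign in ((1, offR), (0, -offL)):
        b = np.concatenate([np.zeros((W, 1)), off_sign], axis=1) + meta_c[:, None]
        x = b[:, None, :] - mu[:, :, None]                # (W, 2, K)
        cdf = _PHI(x)
        if r == 1:
            full = np.concatenate([cdf, np.ones((W, 2, 1))], axis=2)
            num = np.diff(full, axis=2)
            den = 1.0 - cdf[:, :, 0]
        else:
            full = np.concatenate([cdf, np.zeros((W, 2, 1))], axis=2)
            num = -np.diff(full, axis=2)
            den = cdf[:, :, 0]
        n = data[:, r, :]                                 # (2, K)
        ll += np.einsum("sk,wsk->w", n, np.log(np.maximum(num, _TINY)))
        ll -= n.sum(axis=1) @ np.log(np.maximum(den, _TINY)).T
    return ll


def _fit_mcmc(data, c_rel, K, t1, mcmc: McmcParams):
    import emcee

    d = t1.d_prime
    if d <= 0:
        raise ValueError("MCMC fit requires d' > 0")
    ndim = 2 * K - 1
    prior_sd_lmr, prior_sd_z = 1.0, 2.0

    def log_prob(thetas):
        thetas = np.atleast_2d(thetas)
        lmr = thetas[:, 0]
        bad = (np.abs(lmr) > 10) | np.any(np.abs(thetas[:, 1:]) > 8, axis=1)
        m = np.exp(np.clip(lmr, -10, 10)) * d
        meta_c = c_rel * m
        offL = np.cumsum(np.exp(thetas[:, 1:K]), axis=1)
        offR = np.cumsum(np.exp(thetas[:, K:]), axis=1)
        ll = _batch_loglik(data, m, meta_c, offL, offR, K)
        lp = -0.5 * (lmr / prior_sd_lmr) ** 2 \
             - 0.5 * np.sum((thetas[:, 1:] / prior_sd_z) ** 2, axis=1)
        out = ll + lp
        out[bad] = -np.inf
        return out

    # nburnin/nsamples count ensemble steps; every walker contributes a draw
    # per step, so the retained draw total is nsamples/nthin * nwalkers.
    nwalkers = max(2 * ndim + 2, 24)
    rng = np.random.default_rng(mcmc.seed)
    p0 = np.concatenate([[0.0], np.full(ndim - 1, np.log(0.4))])
    p0 = p0 + 0.05 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
    sampler.run_mcmc(p0, mcmc.nburnin + mcmc.nsamples, progress=False)
    chain = sampler.get_chain(discard=mcmc.nburnin, thin=mcmc.nthin)  # (steps, walkers, dim)
    lmr_draws = chain[:, :, 0]
    meta_d_draws = np.exp(lmr_draws) * d
    flat = chain.reshape(-1, ndim)
    meta_d_hat = float(np.mean(np.exp(flat[:, 0]) * d))
    incL = np.exp(flat[:, 1:K]);  incR = np.exp(flat[:, K:])
    meta_c_hat = c_rel * meta_d_hat
    t2c_left = meta_c_hat - np.mean(np.cumsum(incL, axis=1), axis=0)
    t2c_right = meta_c_hat + np.mean(np.cumsum(incR, axis=1), axis=0)
    ll = type2_loglik(data, meta_d_hat, meta_c_hat, t2c_left, t2c_right, K)

    import arviz as az
    idata = az.convert_to_dataset({"log_mratio": lmr_draws.T})
    posterior = {
        "meta_d": meta_d_draws.reshape(-1),
        "log_mratio": lmr_draws.reshape(-1),
        "rhat": float(az.rhat(idata)["log_mratio"].values),
        "ess": float(az.ess(idata)["log_mratio"].values),
    }
    return meta_d_hat, meta_c_hat, t2c_left, t2c_right, ll, posterior


def confidence_criterion(fit: MetaDFit, reference: str = "meta_c") -> float:
    """Mean |type-2 c' − type-1 c'|, per response side then across sides.

    ``reference`` selects the type-1 anchor: the model's own meta-level
    criterion (default) or the raw type-1 ``c``.
    """
    ref = fit.meta_c if reference == "meta_c" else fit.type1.c
    left = float(np.mean(np.abs(fit.t2c_left - ref)))
    right = float(np.mean(np.abs(fit.t2c_right - ref)))
    return 0.5 * (left + right)


def efficiency(fit: MetaDFit) -> float:
    """log(meta_d / d'); refuses non-positive ratios (exclusion territory)."""
    if not fit.m_ratio > 0:
        raise ValueError(
            "efficiency undefined for m_ratio <= 0; participant subject to exclusion rule")
    return float(np.log(fit.m_ratio))
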