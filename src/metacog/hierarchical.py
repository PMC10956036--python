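"""Hierarchical Bayesian inference on metacognitive efficiency (log Mratio).

Model: each subject's log efficiency ``lmr_s = log(meta_d_s / d'_s)`` is drawn
from a group-level normal, optionally with covariates,

    lmr_s ~ Normal(mu + x_s' beta, sigma),
    mu ~ Normal(0, 1),  beta_k ~ Normal(0, 1),  sigma ~ HalfNormal(1),

and enters the subject's type-2 confidence likelihood through
``meta_d_s = exp(lmr_s) * d'_s``.  The subject-level likelihood is the
*profile* likelihood of meta-d': for each point on a log-Mratio grid the
type-2 criteria are maximised out (they are nuisance parameters with no
cross-subject structure), and the resulting curve is interpolated during
sampling.  This keeps the sampled space to one dimension per subject plus
the group parameters.

Sampling is blocked Metropolis-within-Gibbs: vectorised random-walk updates
of the subject effects (step sizes adapted during burn-in), an exact
conjugate draw of (mu, beta), and a random-walk update of log sigma.
Several independent chains are run; R-hat and effective sample size are
computed with arviz.  Significance follows the highest-density-interval
rule: an effect is called significant when the 95% HDI of its posterior
excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .metad import McmcParams, _negloglik_grad
from .sdt import RatingCounts, type1_fit

__all__ = [
    "HierarchicalFit",
    "HDIInterval",
    "hdi",
    "fit_group",
    "fit_regression",
    "compare_groups",
    "profile_loglik",
]


@dataclass(frozen=True)
class HDIInterval:
    """Narrowest contiguous interval holding ``mass`` of the posterior."""

    lower: float
    upper: float
    mass: float = 0.95

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hdi(samples: Sequence[float], mass: float = 0.95) -> HDIInterval:
    """Leftmost narrowest window containing ``ceil(mass * n)`` sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for an HDI")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the leftmost tie
    return HDIInterval(float(x[i]), float(x[i + m - 1]), mass)


@dataclass
class HierarchicalFit:
    """Posterior samples and diagnostics from a hierarchical Mratio fit."""

    group_mu: np.ndarray               # (chains, draws) log-Mratio group mean
    group_sigma: np.ndarray            # (chains, draws)
    subject_logMratio: np.ndarray      # (chains, draws, n_subjects)
    betas: Optional[np.ndarray]        # (chains, draws, p) or None
    covariate_names: Optional[list]
    diagnostics: pd.DataFrame          # parameter, rhat, ess
    subject_mle_logMratio: np.ndarray  # per-subject profile maxima
    d_primes: np.ndarray
    mcmc: McmcParams

    @property
    def mu_draws(self) -> np.ndarray:
        return self.group_mu.reshape(-1)

    def beta_hdi(self, mass: float = 0.95) -> pd.DataFrame:
        """Per-covariate posterior summary with the HDI significance rule."""
        if self.betas is None:
            raise ValueError("fit has no covariates")
        rows = []
        for k, name in enumerate(self.covariate_names):
            draws = self.betas[:, :, k].reshape(-1)
            iv = hdi(draws, mass)
            rows.append({"covariate": name, "mean": float(draws.mean()),
                         "hdi_low": iv.lower, "hdi_high": iv.upper,
                         "significant": not iv.contains(0.0)})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = [{"parameter": "mu", "mean": float(self.mu_draws.mean()),
                 **_hdi_cols(self.mu_draws)},
                {"parameter": "sigma", "mean": float(self.group_sigma.mean()),
                 **_hdi_cols(self.group_sigma.reshape(-1))}]
        if self.betas is not None:
            for k, name in enumerate(self.covariate_names):
                d = self.betas[:, :, k].reshape(-1)
                rows.append({"parameter": f"beta[{name}]", "mean": float(d.mean()),
                             **_hdi_cols(d)})
        return pd.DataFrame(rows)


def _hdi_cols(draws: np.ndarray) -> dict:
    iv = hdi(draws)
    return {"hdi_low": iv.lower, "hdi_high": iv.upper}


# ---------------------------------------------------------------------------
# Profile likelihood over the type-2 criteria
# ---------------------------------------------------------------------------

LMR_GRID = np.linspace(-4.0, 2.0, 49)


def profile_loglik(counts: RatingCounts, padding: float | None = None,
                   grid: np.ndarray = LMR_GRID) -> tuple[np.ndarray, np.ndarray, float]:
    """Type-2 log-likelihood maximised over criteria, per log-Mratio grid point.

    Returns ``(grid, loglik, d_prime)``; the curve is evaluated at
    ``meta_d = exp(grid) * d'`` with criteria warm-started along the grid.
    """
    K = counts.K
    if padding is None:
        padding = 1.0 / (2 * K)
    t1 = type1_fit(counts, padding=padding)
    if t1.d_prime <= 0:
        raise ValueError("profile likelihood requires d' > 0")
    data = counts.counts + padding
    c_rel = t1.c_rel if np.isfinite(t1.c_rel) else 0.0
    ll = np.empty(len(grid))
    z0 = np.full(2 * K - 2, np.log(0.4))
    bounds = [(-7.0, 3.0)] * (2 * K - 2)
    order = np.argsort(np.abs(grid))  # start near m_ratio = 1, walk outwards
    z_by_idx = {}
    for idx in order:
        m = float(np.exp(grid[idx]) * t1.d_prime)

        def nll_z(zeta, m=m):
            f, g = _negloglik_grad(np.concatenate([[m], zeta]), data, c_rel, K)
            return f, g[1:]

        near = min(z_by_idx, key=lambda j: abs(j - idx), default=None)
        start = z_by_idx.get(near, z0)
        res = minimize(nll_z, start, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200})
        z_by_idx[idx] = res.x
        ll[idx] = -res.fun
    return grid, ll, t1.d_prime


# ---------------------------------------------------------------------------
# Gibbs/Metropolis sampler
# ---------------------------------------------------------------------------

def _run_chain(ll_curves: np.ndarray, grid: np.ndarray, X: Optional[np.ndarray],
               mcmc: McmcParams, seed: int, mle_lmr: np.ndarray):
    n = ll_curves.shape[0]
    p = 0 if X is None else X.shape[1]
    D = np.ones((n, 1)) if X is None else np.hstack([np.ones((n, 1)), X])
    rng = np.random.default_rng(seed)

    def subject_ll(lmr: np.ndarray) -> np.ndarray:
        # vectorised linear interpolation of each subject's profile curve
        pos = np.clip((lmr - grid[0]) / (grid[1] - grid[0]), 0, len(grid) - 1 - 1e-9)
        i0 = pos.astype(int)
        w = pos - i0
        rows = np.arange(n)
        return (1 - w) * ll_curves[rows, i0] + w * ll_curves[rows, i0 + 1]

    lmr = np.clip(mle_lmr + 0.1 * rng.standard_normal(n), grid[0] + 0.1, grid[-1] - 0.1)
    coef = np.zeros(1 + p)
    coef[0] = float(np.mean(lmr))
    sigma = max(float(np.std(lmr)), 0.1)
    step = np.full(n, 0.3)
    step_s = 0.2
    step_nc = 0.3
    acc_sig = 0
    acc_nc = 0
    cur_ll = subject_ll(lmr)

    niter = mcmc.nburnin + mcmc.nsamples * mcmc.nthin
    keep_mu = np.empty(mcmc.nsamples)
    keep_sig = np.empty(mcmc.nsamples)
    keep_beta = np.empty((mcmc.nsamples, p)) if p else None
    keep_lmr = np.empty((mcmc.nsamples, n))
    kept = 0
    prior_prec = np.eye(1 + p)  # N(0,1) priors on mu and each beta

    for it in range(niter):
        mean_s = D @ coef
        # --- subject effects: vectorised random-walk MH ---
        prop = lmr + step * rng.standard_normal(n)
        inside = (prop > grid[0]) & (prop < grid[-1])
        prop_c = np.clip(prop, grid[0], grid[-1])
        prop_ll = subject_ll(prop_c)
        logr = (prop_ll - cur_ll
                - 0.5 * ((prop_c - mean_s) ** 2 - (lmr - mean_s) ** 2) / sigma ** 2)
        acc = inside & (np.log(rng.random(n)) < logr)
        lmr = np.where(acc, prop_c, lmr)
        cur_ll = np.where(acc, prop_ll, cur_ll)
        # --- (mu, beta): conjugate normal draw ---
        A = D.T @ D / sigma ** 2 + prior_prec
        b = D.T @ lmr / sigma ** 2
        cho = np.linalg.cholesky(A)
        mean_coef = np.linalg.solve(A, b)
        coef = mean_coef + np.linalg.solve(cho.T, rng.standard_normal(1 + p))
        # --- sigma: random-walk MH on log sigma (half-normal(1) prior) ---
        resid = lmr - D @ coef
        ls = np.log(sigma)
        ls_p = ls + step_s * rng.standard_normal()
        sig_p = np.exp(ls_p)

        def sig_logpost(s):
            return (-n * np.log(s) - 0.5 * np.sum(resid ** 2) / s ** 2
                    - 0.5 * s ** 2 + np.log(s))  # last terms: prior + Jacobian

        if np.log(rng.random()) < sig_logpost(sig_p) - sig_logpost(sigma):
            sigma = sig_p
            acc_sig += 1
        # --- interweaved non-centered sigma update (ASIS) ---
        # re-express lmr = mean + sigma * u with u held fixed, so the type-2
        # likelihood informs sigma directly; cures the boundary sticking of
        # the centered update when sigma is small.
        mean_s = D @ coef
        u = (lmr - mean_s) / sigma
        ls_p = np.log(sigma) + step_nc * rng.standard_normal()
        sig_p = np.exp(ls_p)
        lmr_p = mean_s + sig_p * u
        if np.all((lmr_p > grid[0]) & (lmr_p < grid[-1])):
            ll_p = subject_ll(lmr_p)
            logr = (ll_p.sum() - cur_ll.sum()
                    - 0.5 * (sig_p ** 2 - sigma ** 2)      # half-normal(1) prior
                    + np.log(sig_p) - np.log(sigma))       # Jacobian of log step
            if np.log(rng.random()) < logr:
                sigma = sig_p
                lmr = lmr_p
                cur_ll = ll_p
                acc_nc += 1
        # --- adaptation during burn-in ---
        if it < mcmc.nburnin and (it + 1) % 50 == 0:
            step *= np.exp(0.5 * (acc.mean() - 0.44))
            step = np.clip(step, 0.02, 2.0)
            step_s = float(np.clip(step_s * np.exp(0.5 * (acc_sig / 50 - 0.44)),
                                   0.02, 2.0))
            step_nc = float(np.clip(step_nc * np.exp(0.5 * (acc_nc / 50 - 0.44)),
                                    0.02, 2.0))
            acc_sig = 0
            acc_nc = 0
        if it >= mcmc.nburnin and (it - mcmc.nburnin) % mcmc.nthin == 0 and kept < mcmc.nsamples:
            keep_mu[kept] = coef[0]
            keep_sig[kept] = sigma
            if p:
                keep_beta[kept] = coef[1:]
            keep_lmr[kept] = lmr
            kept += 1
    return keep_mu, keep_sig, keep_beta, keep_lmr


def _diagnostics(arrays: dict) -> pd.DataFrame:
    import arviz as az

    idata = az.convert_to_dataset(arrays)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in arrays:
        r = np.atleast_1d(rhat[name].values)
        e = np.atleast_1d(ess[name].values)
        for i, (ri, ei) in enumerate(zip(r.ravel(), e.ravel())):
            label = name if r.size == 1 else f"{name}[{i}]"
            rows.append({"parameter": label, "rhat": float(ri), "ess": float(ei)})
    df = pd.DataFrame(rows)
    bad = df[df["rhat"] > 1.1]
    if len(bad):
        warnings.warn(f"R-hat > 1.1 for: {', '.join(bad['parameter'])}",
                      RuntimeWarning, stacklevel=3)
    return df


def _fit_hierarchical(counts_list: Sequence[RatingCounts],
                      X: Optional[np.ndarray], names: Optional[list],
                      mcmc: McmcParams, grid: np.ndarray) -> HierarchicalFit:
    if len(counts_list) < 2:
        raise ValueError("need at least 2 subjects")
    curves = []
    dps = []
    for counts in counts_list:
        g, ll, dp = profile_loglik(counts, grid=grid)
        curves.append(ll)
        dps.append(dp)
    ll_curves = np.asarray(curves)
    mle_lmr = grid[np.argmax(ll_curves, axis=1)]

    mus, sigs, betas, lmrs = [], [], [], []
    for chain in range(mcmc.nchains):
        m, s, b, l = _run_chain(ll_curves, grid, X, mcmc, mcmc.seed + chain, mle_lmr)
        mus.append(m); sigs.append(s); lmrs.append(l)
        if b is not None:
            betas.append(b)
    group_mu = np.asarray(mus)
    group_sigma = np.asarray(sigs)
    beta_arr = np.asarray(betas) if betas else None
    diag_arrays = {"mu": group_mu, "sigma": group_sigma}
    if beta_arr is not None:
        diag_arrays["beta"] = beta_arr
    diagnostics = _diagnostics(diag_arrays)
    return HierarchicalFit(group_mu=group_mu, group_sigma=group_sigma,
                           subject_logMratio=np.asarray(lmrs), betas=beta_arr,
                           covariate_names=names, diagnostics=diagnostics,
                           subject_mle_logMratio=mle_lmr, d_primes=np.asarray(dps),
                           mcmc=mcmc)


def fit_group(counts_list: Sequence[RatingCounts], mcmc: McmcParams | None = None,
              grid: np.ndarray = LMR_GRID) -> HierarchicalFit:
    """Group-level hierarchical fit of log Mratio (no covariates)."""
    return _fit_hierarchical(counts_list, None, None, mcmc or McmcParams(), grid)


def fit_regression(counts_list: Sequence[RatingCounts], covariates,
                   mcmc: McmcParams | None = None, standardize: bool = True,
                   grid: np.ndarray = LMR_GRID) -> HierarchicalFit:
    """Hierarchical regression of log Mratio on subject-level covariates.

    Covariates are z-scored by default (recorded in the returned fit's
    names); the design must be full rank with no missing values.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = [f"x{k}" for k in range(X.shape[1])]
    if X.ndim != 2 or len(X) != len(counts_list):
        raise ValueError("covariates must be an n_subjects x p matrix")
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance covariate(s): {bad}")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    if np.linalg.matrix_rank(np.hstack([np.ones((len(X), 1)), X])) < X.shape[1] + 1:
        raise ValueError("rank-deficient covariate matrix")
    return _fit_hierarchical(counts_list, X, names, mcmc or McmcParams(), grid)


def compare_groups(fit_high: HierarchicalFit, fit_low: HierarchicalFit,
                   mass: float = 0.95) -> tuple[HDIInterval, bool]:
    """High-minus-low difference of group log Mratio, judged by the HDI rule."""
    a, b = fit_high.mu_draws, fit_low.mu_draws
    if a.shape != b.shape:
        raise ValueError("fits have mismatched sample counts")
    diff = a - b
    iv = hdi(diff, mass)
    return iv, not iv.contains(0.0)
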