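"""Posterior samplers for the package's Gaussian linear models.

Both models used here — the direction-matching regression and the dyadic
rank model — are Gaussian linear models with Normal shrinkage priors on the
coefficients and half-Normal priors on scale parameters.  Conditional on the
scales the coefficient posteriors are exactly Normal, so a Gibbs sweep
(conjugate block draw for the coefficients, 1-D slice sampling for each
scale) mixes essentially perfectly and is deterministic given a seed.

All draws are returned post-warmup, chains concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings: per-chain retained draws, warmup sweeps, chains."""

    draws: int = 1000
    warmup: int = 1000
    chains: int = 2


#: short settings for replicate-heavy recovery studies
FAST_MCMC = MCMCSettings(draws=500, warmup=300, chains=1)


def hpdi(samples: np.ndarray, prob: float = 0.99) -> tuple[float, float]:
    """Highest posterior density interval of a unimodal 1-D sample.

    The minimal-width window containing ``prob`` of the sorted draws.
    """
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least two draws for an HPDI")
    m = max(int(np.ceil(prob * n)), 2)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def slice_sample_1d(
    logpdf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One update of Neal's slice sampler (stepping-out + shrinkage)."""
    logy = logpdf(x0) + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logpdf(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logpdf(hi) < logy:
            break
        hi += w
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep current state


def _sigma_logpdf(log_sigma: float, sse: float, n_obs: int, prior_scale: float) -> float:
    # residual sd under half-Normal(prior_scale), parameterised on log sigma
    sigma = np.exp(log_sigma)
    return (
        -n_obs * log_sigma
        - 0.5 * sse / sigma**2
        - 0.5 * (sigma / prior_scale) ** 2
        + log_sigma  # Jacobian of the log transform
    )


def sample_linear_model(
    X: np.ndarray,
    y: np.ndarray,
    prior_sd: float,
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    sigma_prior_scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """No-intercept Bayesian linear regression y = X b + e.

    Priors: b_k ~ Normal(0, prior_sd); residual sd ~ half-Normal(sigma_prior_scale).
    Returns ``{"beta": (S, p), "sigma": (S,)}`` with S = draws * chains.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    prior_prec = np.eye(p) / prior_sd**2
    ss = np.random.SeedSequence(seed)
    beta_out, sigma_out = [], []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        beta = np.zeros(p)
        log_sigma = 0.0
        for it in range(settings.warmup + settings.draws):
            sigma2 = np.exp(2 * log_sigma)
            prec = XtX / sigma2 + prior_prec
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Xty / sigma2)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)
            sse = yty - 2 * beta @ Xty + beta @ XtX @ beta
            sse = max(sse, 1e-300)
            log_sigma = slice_sample_1d(
                lambda ls: _sigma_logpdf(ls, sse, n, sigma_prior_scale), log_sigma, rng, w=0.5
            )
            if it >= settings.warmup:
                beta_out.append(beta)
                sigma_out.append(np.exp(log_sigma))
    return {"beta": np.array(beta_out), "sigma": np.array(sigma_out)}


def gaussian_pointwise_loglik(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Pointwise Gaussian log-likelihood matrix (draws x observations)."""
    mu = beta @ X.T  # (S, n)
    resid2 = (y[None, :] - mu) ** 2
    s2 = sigma[:, None] ** 2
    return -0.5 * np.log(2 * np.pi * s2) - resid2 / (2 * s2)


def _scale_logpdf(log_s: float, ss_terms: float, n_terms: int, prior_scale: float) -> float:
    s = np.exp(log_s)
    return -n_terms * log_s - 0.5 * ss_terms / s**2 - 0.5 * (s / prior_scale) ** 2 + log_s


def sample_varying_intercept_model(
    x: np.ndarray,
    group_idx: np.ndarray,
    y: np.ndarray,
    n_groups: int,
    prior_sd: float,
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    scale_prior: float = 1.0,
) -> dict[str, np.ndarray]:
    """y = b * x + g[group] + e with hierarchical group intercepts.

    Priors: b ~ Normal(0, prior_sd); g_i ~ Normal(0, sigma_g);
    sigma_g and the residual sd ~ half-Normal(scale_prior).
    Returns draws for ``beta``, ``g`` (S, n_groups), ``sigma_g``, ``sigma``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    group_idx = np.asarray(group_idx, int)
    n = len(y)
    counts = np.bincount(group_idx, minlength=n_groups).astype(float)
    xx = float(x @ x)
    ss = np.random.SeedSequence(seed)
    out = {k: [] for k in ("beta", "g", "sigma_g", "sigma")}
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        beta, g = 0.0, np.zeros(n_groups)
        log_sigma, log_sigma_g = np.log(np.std(y) + 1e-3), np.log(scale_prior / 10)
        for it in range(settings.warmup + settings.draws):
            sigma2 = np.exp(2 * log_sigma)
            sigma_g2 = np.exp(2 * log_sigma_g)
            # beta | g, sigma
            r = y - g[group_idx]
            prec = xx / sigma2 + 1.0 / prior_sd**2
            mean = (x @ r / sigma2) / prec
            beta = mean + rng.standard_normal() / np.sqrt(prec)
            # g | beta, scales
            r = y - beta * x
            sums = np.bincount(group_idx, weights=r, minlength=n_groups)
            prec_g = counts / sigma2 + 1.0 / sigma_g2
            mean_g = (sums / sigma2) / prec_g
            g = mean_g + rng.standard_normal(n_groups) / np.sqrt(prec_g)
            # scales
            resid = r - g[group_idx]
            log_sigma = slice_sample_1d(
                lambda ls: _scale_logpdf(ls, float(resid @ resid), n, scale_prior),
                log_sigma, rng, w=0.5,
            )
            log_sigma_g = slice_sample_1d(
                lambda ls: _scale_logpdf(ls, float(g @ g), n_groups, scale_prior),
                log_sigma_g, rng, w=0.5,
            )
            if it >= settings.warmup:
                out["beta"].append(beta)
                out["g"].append(g.copy())
                out["sigma_g"].append(np.exp(log_sigma_g))
                out["sigma"].append(np.exp(log_sigma))
    return {k: np.array(v) for k, v in out.items()}
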