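"""MCMC convergence and goodness-of-fit diagnostics.

``gelman_rubin`` implements the classic potential-scale-reduction statistic
from between- and within-chain variances. ``dunn_smyth_residuals`` gives
randomized quantile residuals for Bernoulli (or binomial) observations,
which are standard normal when the fitted probabilities are the true ones —
the only usable residual check for binary detection data, where Pearson or
deviance residuals are degenerate.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtri

__all__ = ["gelman_rubin", "dunn_smyth_residuals", "residual_normality_pvalue"]


def gelman_rubin(chains, split: bool = False) -> float:
    """Potential scale reduction R-hat for one scalar parameter.

    Parameters
    ----------
    chains : array-like, shape (n_chains, n_draws)
        Post-burn-in draws. Requires >= 2 chains of >= 2 draws.
    split : bool
        If True, each chain is split in half first (requires >= 4 draws).

    Returns
    -------
    float
        sqrt(((n-1)/n * W + B/n) / W); NaN when every chain is constant
        (the statistic is undefined — flagged rather than guessed).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = x.shape
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * x.mean(axis=1).var(ddof=1)
    if W == 0:
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def dunn_smyth_residuals(y, prob, rng=None, mode: str = "randomized"):
    """Randomized quantile residuals for Bernoulli observations.

    r = ndtri(u), u ~ Uniform(F(y-1), F(y)) under Bernoulli(prob); in
    ``mode="midpoint"`` u is the interval midpoint (deterministic, used for
    exact tests). A fitted probability of exactly 0 or 1 that contradicts y
    yields an infinite residual, left in place for the caller to flag.
    """
    y = np.asarray(y)
    prob = np.asarray(prob, dtype=float)
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    lower = np.where(y > 0, 1.0 - prob, 0.0)  # F(y - 1)
    upper = np.where(y > 0, 1.0, 1.0 - prob)  # F(y)
    if mode == "midpoint":
        u = 0.5 * (lower + upper)
    elif mode == "randomized":
        rng = np.random.default_rng(rng)
        u = lower + rng.random(np.shape(y)) * (upper - lower)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(divide="ignore"):
        return ndtri(u)


def residual_normality_pvalue(residuals) -> float:
    """Kolmogorov-Smirnov p-value of residuals against the standard normal."""
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    return float(stats.kstest(r, "norm").pvalue)
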