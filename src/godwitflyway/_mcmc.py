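"""Shared MCMC plumbing: emcee driver, split-walker R-hat, posterior summaries.

All hierarchical models in this package expose a vectorised log-posterior
``f(theta) -> float per row`` over a 2-D parameter array and are sampled with
the affine-invariant ensemble sampler (emcee).  Convergence is judged by the
split-R-hat statistic computed over groups of walkers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import emcee

RHAT_THRESHOLD = 1.05


@dataclass
class PosteriorDraws:
    """Flattened posterior draws with per-parameter names and diagnostics."""

    names: list[str]
    chain: np.ndarray          # (draws, walkers, ndim), post burn-in
    rhat: np.ndarray           # (ndim,)
    converged: bool
    log_prob: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        """Draws flattened to (draws * walkers, ndim)."""
        return self.chain.reshape(-1, self.chain.shape[-1])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    def mean(self, name: str) -> float:
        return float(self[name].mean())

    def sd(self, name: str) -> float:
        return float(self[name].std(ddof=1))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self[name], [a, 1.0 - a])
        return float(lo), float(hi)

    def summary(self):
        import pandas as pd

        flat = self.flat
        q = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "rhat": self.rhat,
            },
            index=self.names,
        )


def split_rhat(chain: np.ndarray, n_groups: int = 4) -> np.ndarray:
    """Gelman-Rubin R-hat treating groups of walkers as chains.

    ``chain`` has shape (draws, walkers, ndim).  Walkers are split into
    ``n_groups`` groups and each group's draws pooled into one pseudo-chain;
    each pseudo-chain is then split in half (split-R-hat).
    """
    draws, walkers, ndim = chain.shape
    g = max(2, n_groups)
    per = walkers // g
    if per == 0:
        g, per = walkers, 1
    chains = []
    for i in range(g):
        block = chain[:, i * per:(i + 1) * per, :].reshape(-1, ndim)
        m = len(block) // 2
        chains.append(block[:m])
        chains.append(block[m:2 * m])
    arr = np.stack(chains)                     # (2g, m, ndim)
    m = arr.shape[1]
    cmeans = arr.mean(axis=1)                  # (2g, ndim)
    cvars = arr.var(axis=1, ddof=1)            # (2g, ndim)
    W = cvars.mean(axis=0)
    B = m * cmeans.var(axis=0, ddof=1)
    var_hat = (m - 1) / m * W + B / m
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat[~np.isfinite(rhat)] = 1.0
    return rhat


def sample_posterior(
    log_prob,
    start: np.ndarray,
    scales: np.ndarray | float,
    names: list[str],
    *,
    draws: int = 1000,
    walkers: int | None = None,
    burn: int | None = None,
    seed: int = 0,
    thin: int = 1,
) -> PosteriorDraws:
    """Run the ensemble sampler on a vectorised log-posterior.

    ``log_prob`` must accept a (walkers, ndim) array and return (walkers,)
    log densities (−inf allowed).  ``start`` is the initialisation centre;
    walkers are scattered around it with the given per-parameter scales.
    ``draws`` counts post-burn-in steps; ``burn`` defaults to ``draws``.
    """
    start = np.asarray(start, float)
    ndim = start.size
    if walkers is None:
        walkers = max(2 * ndim + 2, 24)
        walkers += walkers % 2
    if burn is None:
        burn = draws
    rng = np.random.default_rng(seed)
    scales = np.broadcast_to(np.asarray(scales, float), (ndim,))
    p0 = start[None, :] + scales[None, :] * rng.standard_normal((walkers, ndim))
    # keep the initial ensemble inside the support
    lp0 = log_prob(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 200:
        p0[bad] = start[None, :] + 0.1 * scales[None, :] * rng.standard_normal((int(bad.sum()), ndim))
        lp0 = log_prob(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if bad.any():
        raise ValueError("could not initialise sampler inside the posterior support")

    sampler = emcee.EnsembleSampler(walkers, ndim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed % (2**32 - 1)).get_state()
    sampler.run_mcmc(p0, burn + draws, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=burn, thin=thin)
    lp = sampler.get_log_prob(discard=burn, thin=thin)
    rhat = split_rhat(chain)
    return PosteriorDraws(
        names=list(names),
        chain=chain,
        rhat=rhat,
        converged=bool(np.all(rhat <= RHAT_THRESHOLD)),
        log_prob=lp,
    )


# -- common log-prior building blocks (all vectorised over the first axis) --

def normal_logpdf(x, mu, sigma):
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def half_cauchy_logpdf(x, scale):
    """log density of |Cauchy(0, scale)|; x must be positive."""
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def half_normal_logpdf(x, scale):
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


def expon_logpdf(x, rate):
    return np.log(rate) - rate * x
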