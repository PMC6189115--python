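"""State-space population trend from multi-site winter roost counts.

The latent process is deterministic exponential growth with a single,
time-independent multiplier shared across sites:

    N_{i,k+1} = N_{i,k} * lambda

Observed counts are negative binomial around the latent abundance with a
site-specific size r_i (p_ik = r_i / (r_i + N_ik), so the mean is N_ik);
counts at high-tide roosts come in large flocks, hence the overdispersed
observation model.  The quantity of interest is the posterior P(lambda < 1),
the probability of decline.  Missing site-years simply contribute nothing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from ._mcmc import (
    PosteriorDraws,
    expon_logpdf,
    normal_logpdf,
    sample_posterior,
)


@dataclass
class PopGrowthFit:
    """Posterior for lambda, initial site abundances and NB sizes."""

    posterior: PosteriorDraws
    sites: list
    years: list

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def lambda_draws(self) -> np.ndarray:
        return np.exp(self.posterior["log_lambda"])

    @property
    def p_decline(self) -> float:
        """P(lambda < 1) over the posterior draws."""
        return float((self.lambda_draws < 1.0).mean())

    def summary(self) -> dict:
        lam = self.lambda_draws
        lo, hi = np.quantile(lam, [0.025, 0.975])
        return {
            "lambda_mean": float(lam.mean()),
            "lambda_sd": float(lam.std(ddof=1)),
            "lambda_q2.5": float(lo),
            "lambda_q97.5": float(hi),
            "p_lambda_lt_1": self.p_decline,
            "converged": self.converged,
        }


def forecast(n0: float, lam: float, horizon: int) -> np.ndarray:
    """Latent abundances n0 * lam^h for h = 0..horizon."""
    return n0 * lam ** np.arange(horizon + 1, dtype=float)


def fit_popgrowth(
    counts: pd.DataFrame,
    *,
    draws: int = 1000,
    walkers: int | None = None,
    seed: int = 0,
) -> PopGrowthFit:
    """Posterior for the shared growth rate from a (site_id, year, count)
    table; counts may be missing (rows absent or count NaN)."""
    obs = counts.dropna(subset=["count"]).copy()
    obs["count"] = obs["count"].astype(int)
    years = sorted(obs["year"].unique().tolist())
    sites = sorted(obs["site_id"].unique().tolist())
    if len(years) < 2:
        raise ValueError("need counts from at least two years")
    if obs["count"].max() == 0:
        raise ValueError("all counts zero: growth rate unidentifiable")
    year_idx = (obs["year"] - years[0]).to_numpy(float)  # calendar offsets; gaps allowed
    site_idx = obs["site_id"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    y = obs["count"].to_numpy(int)
    n_sites = len(sites)

    first_counts = np.array([
        max(float(obs.loc[obs["site_id"] == s_].sort_values("year")["count"].iloc[0]), 1.0)
        for s_ in sites])
    log_first = np.log(first_counts)

    def log_post(theta):
        theta = np.atleast_2d(theta)
        log_lam = theta[:, 0]
        log_n1 = theta[:, 1:1 + n_sites]
        log_r = theta[:, 1 + n_sites:1 + 2 * n_sites]
        r = np.exp(log_r)
        log_n = log_n1[:, site_idx] + log_lam[:, None] * year_idx[None, :]
        log_n = np.clip(log_n, -20.0, 25.0)
        n_lat = np.exp(log_n)
        p = r[:, site_idx] / (r[:, site_idx] + n_lat)
        ll = st.nbinom.logpmf(y[None, :], r[:, site_idx], p).sum(axis=1)
        prior = (
            normal_logpdf(log_lam, 0.0, 0.5)
            + normal_logpdf(log_n1, log_first[None, :], 1.0).sum(axis=1)
            + (expon_logpdf(r, 0.01) + log_r).sum(axis=1)
        )
        out = ll + prior
        out[~np.isfinite(out)] = -np.inf
        return out

    names = (["log_lambda"] + [f"log_N1[{s_}]" for s_ in sites]
             + [f"log_r[{s_}]" for s_ in sites])
    start = np.concatenate([[0.0], log_first, np.full(n_sites, np.log(10.0))])
    scales = np.concatenate([[0.05], np.full(n_sites, 0.2), np.full(n_sites, 0.3)])
    post = sample_posterior(log_post, start, scales, names,
                            draws=draws, walkers=walkers, seed=seed)
    return PopGrowthFit(posterior=post, sites=sites, years=years)
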