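"""Breeding-ground phenology: linear trends and the path-analysis SEM.

Two kinds of fit operate on an annual phenology table (day-of-year dates for
snowmelt, crane-fly emergence, arrival on the Arctic breeding grounds,
clutch initiation, and arrival at the temperate staging site):

* ``fit_trend`` / ``fit_covariate`` — ordinary least squares of one annual
  series on year or on another series, reported with the model-comparison F
  test (with vs. without the term, 1 df).
* ``fit_sem`` — a recursive path analysis in which time drives staging-site
  arrival and snowmelt; snowmelt (and staging-site arrival) drive Arctic
  arrival and crane-fly emergence; and clutch initiation responds to time,
  snowmelt, Arctic arrival and crane-fly emergence.  All variables are
  centred, errors are variable-specific Gaussian, and each structural
  equation is fitted on its complete cases by MCMC.  The evidence for a
  path is P(|coef| > 0) = max(P(coef > 0), P(coef < 0)) over the posterior.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from ._mcmc import half_cauchy_logpdf, normal_logpdf, sample_posterior

#: columns of the annual phenology table, besides ``year``
PHENOLOGY_COLUMNS = [
    "snowmelt_doy",
    "cranefly_doy",
    "arrival_taimyr_doy",
    "clutch_doy",
    "arrival_ws_doy",
]

#: structural equations in causal order: response -> predictors
SEM_STRUCTURE = {
    "arrival_ws_doy": ["time"],
    "snowmelt_doy": ["time"],
    "arrival_taimyr_doy": ["time", "snowmelt_doy", "arrival_ws_doy"],
    "cranefly_doy": ["time", "snowmelt_doy"],
    "clutch_doy": ["time", "snowmelt_doy", "arrival_taimyr_doy", "cranefly_doy"],
}

#: conventional short names b<eq>.<term> for the path coefficients
SEM_COEF_NAMES = {
    ("arrival_ws_doy", "time"): "b1.1",
    ("snowmelt_doy", "time"): "b2.1",
    ("arrival_taimyr_doy", "time"): "b3.1",
    ("arrival_taimyr_doy", "snowmelt_doy"): "b3.2",
    ("arrival_taimyr_doy", "arrival_ws_doy"): "b3.3",
    ("cranefly_doy", "time"): "b4.1",
    ("cranefly_doy", "snowmelt_doy"): "b4.2",
    ("clutch_doy", "time"): "b5.1",
    ("clutch_doy", "snowmelt_doy"): "b5.2",
    ("clutch_doy", "arrival_taimyr_doy"): "b5.3",
    ("clutch_doy", "cranefly_doy"): "b5.4",
}

SEM_SIGMA_NAMES = {
    "arrival_ws_doy": "sigma_arrWS",
    "snowmelt_doy": "sigma_snowmelt",
    "arrival_taimyr_doy": "sigma_arrivalT",
    "cranefly_doy": "sigma_cranefly",
    "clutch_doy": "sigma_clutch",
}


@dataclass(frozen=True)
class TrendFit:
    """OLS slope with the 1-df model-comparison F test."""

    slope: float
    se: float
    intercept: float
    n: int
    f_stat: float
    p_value: float
    resid_ss: float

    def __str__(self):
        return (f"slope = {self.slope:.2f} ± {self.se:.2f}, N = {self.n}, "
                f"F = {self.f_stat:.2f}, P = {self.p_value:.3g}")


def _paired(y, x):
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ok = np.isfinite(y) & np.isfinite(x)
    return y[ok], x[ok]


def fit_trend(y, x) -> TrendFit:
    """OLS of an annual series on a predictor (year, or another series).

    The F statistic compares the model with the slope against the
    intercept-only model (1 df), matching the convention of reporting
    regressions as "model with vs. without the term".
    """
    y, x = _paired(y, x)
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 paired non-missing points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: singular design")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ssr1 = float(res.ssr)
    ssr0 = float(np.sum((y - y.mean()) ** 2))
    f = (ssr0 - ssr1) / (ssr1 / (n - 2)) if ssr1 > 0 else np.inf
    p = float(st.f.sf(f, 1, n - 2)) if np.isfinite(f) else 0.0
    return TrendFit(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        intercept=float(res.params[0]),
        n=n,
        f_stat=float(f),
        p_value=p,
        resid_ss=ssr1,
    )


def fit_covariate(y, x) -> TrendFit:
    """OLS of one phenology series on another (alias of :func:`fit_trend`)."""
    return fit_trend(y, x)


def centre(table: pd.DataFrame) -> pd.DataFrame:
    """Centre every numeric column to zero mean over its non-missing entries."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_numeric_dtype(out[col]):
            out[col] = out[col] - out[col].mean()
    return out


@dataclass
class SEMFit:
    """Posterior for the path-analysis coefficients and residual sds."""

    draws: dict                      # name -> 1-D array of posterior draws
    p_direction: dict                # coef name -> P(|coef| > 0)
    rhat: dict
    converged: bool
    equations: dict = field(default_factory=dict)   # response -> PosteriorDraws

    def mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def sd(self, name: str) -> float:
        return float(self.draws[name].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in self.draws.items():
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({
                "coefficient": name,
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "q2.5": lo,
                "q97.5": hi,
                "p_direction": self.p_direction.get(name, np.nan),
                "rhat": self.rhat.get(name, np.nan),
            })
        return pd.DataFrame(rows).set_index("coefficient")


def _equation_logpost(X: np.ndarray, y: np.ndarray,
                      b_prior_sd: float, sigma_scale: float):
    n, p = X.shape

    def log_post(theta):
        theta = np.atleast_2d(theta)
        b = theta[:, :p]
        log_s = theta[:, p]
        s = np.exp(log_s)
        resid = y[None, :] - b @ X.T
        ll = (-n * log_s - 0.5 * n * np.log(2 * np.pi)
              - 0.5 * np.sum(resid ** 2, axis=1) / s ** 2)
        prior = (np.sum(normal_logpdf(b, 0.0, b_prior_sd), axis=1)
                 + half_cauchy_logpdf(s, sigma_scale) + log_s)  # log-scale Jacobian
        return ll + prior

    return log_post


def fit_sem(
    table: pd.DataFrame,
    *,
    draws: int = 1500,
    walkers: int = 24,
    seed: int = 0,
    b_prior_sd: float = 100.0,
    sigma_prior_scale: float = 5.0,
) -> SEMFit:
    """Fit the recursive path model by per-equation MCMC.

    The table is centred internally (dates and year).  Each structural
    equation is Gaussian-linear and fitted on its own complete cases, so
    unequal series lengths are handled by equation-wise deletion.  Priors:
    Normal(0, ``b_prior_sd``²) on coefficients, half-Cauchy on residual sds.
    """
    work = table.copy()
    work["time"] = work["year"].astype(float)
    work = centre(work[["time"] + [c for c in PHENOLOGY_COLUMNS if c in work.columns]])

    all_draws, pdir, rhats, eqs = {}, {}, {}, {}
    converged = True
    for j, (resp, preds) in enumerate(SEM_STRUCTURE.items()):
        if resp not in work.columns:
            continue
        cols = [resp] + preds
        sub = work[cols].dropna()
        if len(sub) < len(preds) + 2:
            raise ValueError(f"too few complete cases for equation of {resp}")
        y = sub[resp].to_numpy(float)
        X = sub[preds].to_numpy(float)
        names = [SEM_COEF_NAMES[(resp, p_)] for p_ in preds] + [SEM_SIGMA_NAMES[resp]]
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ ols
        s0 = max(float(np.sqrt(np.mean(resid ** 2))), 1e-3)
        start = np.concatenate([ols, [np.log(s0)]])
        scales = np.concatenate([np.full(len(preds), 0.1 * s0 + 0.01), [0.1]])
        post = sample_posterior(
            _equation_logpost(X, y, b_prior_sd, sigma_prior_scale),
            start, scales, names,
            draws=draws, walkers=walkers, seed=seed * 101 + j,
        )
        eqs[resp] = post
        flat = post.flat
        for i, name in enumerate(names):
            d = flat[:, i]
            if name.startswith("sigma"):
                d = np.exp(d)
            all_draws[name] = d
            rhats[name] = float(post.rhat[i])
            if not name.startswith("sigma"):
                pdir[name] = float(max((d > 0).mean(), (d < 0).mean()))
        converged &= post.converged
    return SEMFit(draws=all_draws, p_direction=pdir, rhat=rhats,
                  converged=converged, equations=eqs)
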