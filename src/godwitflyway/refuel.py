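"""Arrival mass, refuelling rates, refuelling time, and compensation arithmetic.

Staging birds are captured twice over: "arrival" captures taken immediately
on landfall give annual, sex-specific mean arrival masses W0_ks with
sex-level residual sd sigmaW0_s; "refuelling" captures taken through the
staging period give body masses that grow linearly from a latent individual
arrival mass and arrival date:

    W_i = W0_i + alpha_ks (T_i - T0_i),
    W0_i ~ Norm(W0_ks, sigmaW0_s^2),  T0_i ~ Norm(T0_k, sigmaT0_k^2)

Both latents are Gaussian and enter linearly given alpha, so they are
integrated out exactly: W_i | alpha_ks is Normal with mean
W0_ks + alpha_ks (T_i - T0_k) and variance sigmaW0_s^2 + alpha_ks^2
sigmaT0_k^2.  Annual rates are exchangeable around a sex-specific linear
function of prey (lugworm) density:

    mu_alpha_ks = intercept_s + slope_s * density_k,  alpha_ks ~
    Norm(mu_alpha_ks, sigma_alpha_s^2)

Years without a density measurement draw their rate from a sex-level
exchangeable mean instead.

Refuelling time RT_k is the span between staging arrival T0_k and departure,
where departure is Arctic arrival minus a fixed migration lag (default 5.5
days).  The compensation arithmetic inverts the survival model's linear
predictor: holding beta_RT log RT + beta_alpha log alpha constant gives the
rate alpha_new = alpha_old * (RT_old / RT_new)^(beta_RT / beta_alpha) needed
to offset a change in refuelling time.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import (
    PosteriorDraws,
    half_normal_logpdf,
    normal_logpdf,
    sample_posterior,
)

SEXES = ("female", "male")
DEFAULT_MIGRATION_LAG_DAYS = 5.5
MASS_WINDOW_G = (100.0, 700.0)


@dataclass(frozen=True)
class ArrivalMass:
    """Annual sex-specific mean arrival masses and sex-level residual sds."""

    w0: pd.DataFrame        # index (year, sex) -> mean mass (g)
    sigma_w0: dict          # sex -> residual sd (g)
    n: pd.DataFrame         # index (year, sex) -> cell count


def estimate_arrival_mass(records: pd.DataFrame,
                          mass_window: tuple = MASS_WINDOW_G) -> ArrivalMass:
    """Cell means of arrival-capture mass by year and sex.

    The residual sd is pooled within cells per sex:
    sqrt(sum residual^2 / (n_s - cells_s)).  Cells with fewer than 2 records
    are flagged by NaN mean being absent — they simply do not appear.
    """
    rec = records[records["capture_type"] == "arrival"].copy()
    lo, hi = mass_window
    rec = rec[(rec["mass_g"] > lo) & (rec["mass_g"] < hi)]
    sizes = rec.groupby(["year", "sex"])["mass_g"].size()
    rec = rec.set_index(["year", "sex"]).loc[sizes[sizes >= 2].index].reset_index()
    grp = rec.groupby(["year", "sex"])["mass_g"]
    w0 = grp.mean().rename("w0_g").to_frame()
    n = grp.size().rename("n").to_frame()
    sigma = {}
    for sex in SEXES:
        sub = rec[rec["sex"] == sex]
        if sub.empty:
            continue
        resid_ss = 0.0
        cells = 0
        for _, cell in sub.groupby("year"):
            resid_ss += float(((cell["mass_g"] - cell["mass_g"].mean()) ** 2).sum())
            cells += 1
        dof = len(sub) - cells
        sd = float(np.sqrt(resid_ss / dof)) if dof > 0 else 0.0
        if sd == 0.0:
            warnings.warn(f"zero residual sd of arrival mass for sex {sex}",
                          stacklevel=2)
        sigma[sex] = sd
    return ArrivalMass(w0=w0, sigma_w0=sigma, n=n)


def refuelling_time(t0_staging: float, arrival_breeding: float,
                    lag_days: float = DEFAULT_MIGRATION_LAG_DAYS) -> float:
    """RT_k = (Arctic arrival − migration lag) − staging arrival."""
    rt = (arrival_breeding - lag_days) - t0_staging
    if rt <= 0:
        raise ValueError(f"non-positive refuelling time {rt:.2f} d")
    return rt


@dataclass
class RefuelFit:
    """Posterior for annual sex-specific refuelling rates and prey effects."""

    posterior: PosteriorDraws
    cells: list                       # (year, sex) cells fitted
    density_years: list
    unidentifiable: list

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def alpha_draws(self, year, sex) -> np.ndarray:
        return self.posterior[f"alpha[{year},{sex}]"]

    def alpha_summary(self) -> pd.DataFrame:
        rows = []
        for year, sex in self.cells:
            d = self.alpha_draws(year, sex)
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({"year": year, "sex": sex, "alpha_mean": d.mean(),
                         "alpha_sd": d.std(ddof=1), "q2.5": lo, "q97.5": hi})
        return pd.DataFrame(rows)


def _refuel_logpost(mass, dt, cell_idx, sex_of_cell, dens_of_cell, has_dens,
                    sigma_w0_cell, sigma_t0_cell, w0_cell):
    """Parameters: alpha[C], then per sex: intercept, slope, mean_nodens,
    log sigma_alpha."""
    n_cells = len(sex_of_cell)
    n_sex = 2

    def log_post(theta):
        theta = np.atleast_2d(theta)
        alpha = theta[:, :n_cells]
        rest = theta[:, n_cells:]
        intercept = rest[:, 0:n_sex]
        slope = rest[:, n_sex:2 * n_sex]
        mean_nodens = rest[:, 2 * n_sex:3 * n_sex]
        log_sig_a = rest[:, 3 * n_sex:4 * n_sex]
        sig_a = np.exp(log_sig_a)

        mu = w0_cell[None, cell_idx] + alpha[:, cell_idx] * dt[None, :]
        var = (sigma_w0_cell[cell_idx][None, :] ** 2
               + alpha[:, cell_idx] ** 2 * sigma_t0_cell[cell_idx][None, :] ** 2)
        ll = (-0.5 * np.log(2 * np.pi * var)
              - 0.5 * (mass[None, :] - mu) ** 2 / var).sum(axis=1)

        mu_alpha = np.where(
            has_dens[None, :],
            intercept[:, sex_of_cell] + slope[:, sex_of_cell] * dens_of_cell[None, :],
            mean_nodens[:, sex_of_cell],
        )
        prior = (
            normal_logpdf(alpha, mu_alpha, sig_a[:, sex_of_cell]).sum(axis=1)
            + normal_logpdf(intercept, 0.0, 10.0).sum(axis=1)
            + normal_logpdf(slope, 0.0, 5.0).sum(axis=1)
            + normal_logpdf(mean_nodens, 0.0, 10.0).sum(axis=1)
            + (half_normal_logpdf(sig_a, 10.0) + log_sig_a).sum(axis=1)
        )
        out = ll + prior
        out[~np.isfinite(out)] = -np.inf
        return out

    return log_post


def fit_refuel(
    records: pd.DataFrame,
    arrival_mass: ArrivalMass,
    t0: dict,
    sigma_t0: dict,
    lugworm_density: dict,
    *,
    draws: int = 1000,
    walkers: int | None = None,
    seed: int = 0,
) -> RefuelFit:
    """Posterior for alpha_ks and the sex-specific lugworm regression.

    ``t0`` and ``sigma_t0`` map year -> staging arrival mean/sd (from the
    arrival model); ``lugworm_density`` maps year -> worms per m² for the
    years that were sampled.  Refuelling-type records in cells lacking an
    arrival-mass estimate are dropped.
    """
    rec = records[records["capture_type"] == "refuelling"].copy()
    rec = rec[rec["year"].isin(t0.keys())]
    w0 = arrival_mass.w0["w0_g"]
    keep = rec.apply(lambda r: (r["year"], r["sex"]) in w0.index, axis=1)
    rec = rec[keep].reset_index(drop=True)
    if rec.empty:
        raise ValueError("no refuelling captures with arrival-mass and T0 inputs")

    cells = sorted({(int(y), s) for y, s in zip(rec["year"], rec["sex"])})
    unident = []
    for year, sex in cells:
        days = rec.loc[(rec["year"] == year) & (rec["sex"] == sex), "day"]
        if days.nunique() < 2:
            unident.append((year, sex))
    if unident:
        warnings.warn(f"single-day cells, alpha unidentifiable: {unident}",
                      stacklevel=2)

    cell_pos = {c: i for i, c in enumerate(cells)}
    cell_idx = np.array([cell_pos[(int(y), s)] for y, s in zip(rec["year"], rec["sex"])])
    sex_of_cell = np.array([SEXES.index(s) for _, s in cells])
    dens_of_cell = np.array([lugworm_density.get(y, 0.0) for y, _ in cells])
    has_dens = np.array([y in lugworm_density for y, _ in cells])
    w0_cell = np.array([w0.loc[(y, s)] for y, s in cells])
    sigma_w0_cell = np.array([max(arrival_mass.sigma_w0.get(s, 1.0), 1e-3)
                              for _, s in cells])
    sigma_t0_cell = np.array([max(sigma_t0[y], 1e-3) for y, _ in cells])
    t0_cell = np.array([t0[y] for y, _ in cells])
    dt = rec["day"].to_numpy(float) - t0_cell[cell_idx]
    mass = rec["mass_g"].to_numpy(float)

    # per-cell OLS slopes as start values
    alpha0 = np.zeros(len(cells))
    for i, c in enumerate(cells):
        m = cell_idx == i
        x, yv = dt[m], mass[m] - w0_cell[i]
        alpha0[i] = (np.sum(x * yv) / np.sum(x * x)) if np.sum(x * x) > 0 else 5.0
    names = ([f"alpha[{y},{s}]" for y, s in cells]
             + [f"lugworm_intercept[{s}]" for s in SEXES]
             + [f"lugworm_slope[{s}]" for s in SEXES]
             + [f"mean_nodens[{s}]" for s in SEXES]
             + [f"log_sigma_alpha[{s}]" for s in SEXES])
    start = np.concatenate([
        alpha0, [np.median(alpha0)] * 2, [0.1, 0.1],
        [np.median(alpha0)] * 2, [np.log(1.0)] * 2,
    ])
    scales = np.concatenate([
        np.full(len(cells), 0.3), [0.5, 0.5], [0.05, 0.05], [0.5, 0.5], [0.2, 0.2],
    ])
    post = sample_posterior(
        _refuel_logpost(mass, dt, cell_idx, sex_of_cell, dens_of_cell, has_dens,
                        sigma_w0_cell, sigma_t0_cell, w0_cell),
        start, scales, names, draws=draws, walkers=walkers, seed=seed,
    )
    return RefuelFit(posterior=post, cells=cells,
                     density_years=sorted(lugworm_density),
                     unidentifiable=unident)


def required_density(target_rate: float, intercept: float, slope: float) -> float:
    """Prey density needed for a target refuelling rate (inverts the linear
    density-rate relation)."""
    if slope <= 0:
        raise ValueError("non-positive density slope: required density undefined")
    return (target_rate - intercept) / slope


def compensation_rate(alpha_old: float, rt_old: float, rt_new: float,
                      beta_alpha: float, beta_rt: float) -> float:
    """Refuelling rate keeping the survival linear predictor constant.

    Solves beta_rt log RT_old + beta_alpha log alpha_old =
    beta_rt log RT_new + beta_alpha log alpha_new.
    """
    if min(alpha_old, rt_old, rt_new) <= 0:
        raise ValueError("rates and times must be positive")
    return alpha_old * (rt_old / rt_new) ** (beta_rt / beta_alpha)
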