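"""Cormack-Jolly-Seber apparent survival with year-level staging covariates.

Apparent survival Phi over the interval following occasion k is modelled on
the logit scale from time-since-marking class (first interval after marking
vs. later), sex, and year-level covariates — the natural logs of the annual
refuelling rate alpha_ks and refuelling time RT_k — with optional pairwise
interactions.  Resighting probability p is year-specific (or constant).
The likelihood conditions on first capture and uses the chi recursion
(probability of never being seen again).

Note on interpretation: apparent survival equals true survival only in the
absence of permanent emigration; for staging populations with a single
refuelling site the two coincide.

Model selection uses quasi-likelihood AICc with an externally supplied
variance-inflation factor c-hat (overdispersion); the default 1.118 is a
typical median-c-hat estimate for large colour-ring resighting datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as opt
from statsmodels.tools.numdiff import approx_hess1

DEFAULT_CHAT = 1.118

BASE_VARS = ("tsm", "sex", "time", "log_rt", "log_alpha")


def parse_formula(formula: str) -> list:
    """Expand a '+'-separated formula with '*' and ':' into term tuples.

    ``a*b`` expands to ``a + b + a:b``; a term tuple is a sorted tuple of
    base variable names (singletons for main effects).  The intercept is
    implicit and always included.
    """
    terms: list = []

    def add(t):
        if t not in terms:
            terms.append(t)

    for raw in formula.split("+"):
        raw = raw.strip()
        if not raw or raw == "1":
            continue
        if "*" in raw:
            a, b = [s.strip() for s in raw.split("*")]
            add((a,)); add((b,)); add(tuple(sorted((a, b))))
        elif ":" in raw:
            a, b = [s.strip() for s in raw.split(":")]
            add(tuple(sorted((a, b))))
        else:
            add((raw,))
    for t in terms:
        for v in t:
            if v not in BASE_VARS:
                raise ValueError(f"unknown model variable {v!r}; known: {BASE_VARS}")
    return terms


def term_name(term: tuple) -> str:
    return ":".join(term)


@dataclass
class CaptureHistories:
    """Detection matrix with marking occasion and sex per individual."""

    detections: np.ndarray      # (n, T) of 0/1
    first: np.ndarray           # (n,) 0-based marking occasion
    sex: np.ndarray             # (n,) strings "female"/"male"
    years: list                 # calendar year per occasion
    ids: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(self.detections[np.arange(len(self.first)), self.first] == 1):
            raise ValueError("detection at the marking occasion must be 1")

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CaptureHistories":
        """Build from a table (id, sex, first_year, one 0/1 column per year)."""
        year_cols = [c for c in df.columns if str(c).lstrip("y").isdigit()]
        years = [int(str(c).lstrip("y")) for c in year_cols]
        order = np.argsort(years)
        years = [years[i] for i in order]
        year_cols = [year_cols[i] for i in order]
        det = df[year_cols].to_numpy(int)
        first = np.array([years.index(int(fy)) for fy in df["first_year"]])
        return cls(detections=det, first=first,
                   sex=df["sex"].to_numpy(), years=years,
                   ids=df["id"].to_numpy() if "id" in df else None)


def _design(histories: CaptureHistories, covariates: pd.DataFrame | None,
            terms: list) -> tuple[np.ndarray, list]:
    """Design tensor X of shape (n, T-1, P) for logit(Phi); P includes the
    intercept as column 0."""
    n, t = histories.detections.shape
    ni = t - 1
    base: dict[str, np.ndarray] = {}
    base["tsm"] = (np.arange(ni)[None, :] == histories.first[:, None]).astype(float)
    base["sex"] = np.broadcast_to(
        (histories.sex == "female").astype(float)[:, None], (n, ni)).copy()
    base["time"] = np.broadcast_to(
        np.arange(ni, dtype=float)[None, :], (n, ni)).copy()
    needed = {v for term in terms for v in term}
    if needed & {"log_rt", "log_alpha"}:
        if covariates is None:
            raise ValueError("formula uses staging covariates but none were given")
        cov = covariates.set_index("year")
        for k in range(ni):
            year = histories.years[k]
            if year not in cov.index:
                raise ValueError(f"covariates missing for year {year}")
        rt = np.array([cov.loc[histories.years[k], "rt"] for k in range(ni)])
        base["log_rt"] = np.broadcast_to(np.log(rt)[None, :], (n, ni)).copy()
        a_f = np.array([cov.loc[histories.years[k], "alpha_female"] for k in range(ni)])
        a_m = np.array([cov.loc[histories.years[k], "alpha_male"] for k in range(ni)])
        female = (histories.sex == "female")[:, None]
        base["log_alpha"] = np.where(female, np.log(a_f)[None, :], np.log(a_m)[None, :])
    cols = [np.ones((n, ni))]
    names = ["phi_intercept"]
    for term in terms:
        col = np.ones((n, ni))
        for v in term:
            col = col * base[v]
        cols.append(col)
        names.append("phi_" + term_name(term))
    return np.stack(cols, axis=-1), names


def _logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def cjs_loglik_matrices(det: np.ndarray, first: np.ndarray,
                        phi: np.ndarray, p: np.ndarray) -> float:
    """Exact CJS log-likelihood from per-individual Phi and p matrices.

    ``phi[i, k]`` is survival over interval k -> k+1; ``p[i, k]`` is the
    resighting probability at occasion k+1.  Conditions on first capture;
    the chi recursion handles the never-seen-again tail.
    """
    n, t = det.shape
    ni = t - 1
    occ = np.arange(t)
    last = np.max(np.where(det == 1, occ[None, :], -1), axis=1)
    chi = np.ones((n, t))
    for k in range(t - 2, -1, -1):
        chi[:, k] = (1.0 - phi[:, k]) + phi[:, k] * (1.0 - p[:, k]) * chi[:, k + 1]
    ivals = np.arange(ni)[None, :]
    active = (ivals >= first[:, None]) & (ivals < last[:, None])
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log_p = np.log(p)
        log_q = np.log1p(-p)
    y_next = det[:, 1:]
    contrib = log_phi + np.where(y_next == 1, log_p, log_q)
    ll = np.where(active, contrib, 0.0).sum()
    ll += np.log(chi[np.arange(n), last]).sum()
    return float(ll)


def cjs_loglik(histories: CaptureHistories, phi_beta: np.ndarray,
               p_logit: np.ndarray, terms: list,
               covariates: pd.DataFrame | None = None) -> float:
    """CJS log-likelihood for logit-scale survival coefficients and
    year-specific logit resighting probabilities (length T-1, for
    occasions 2..T)."""
    x, _ = _design(histories, covariates, terms)
    eta = np.tensordot(x, np.asarray(phi_beta, float), axes=([2], [0]))
    phi = _logit(eta)
    n = len(histories.first)
    p = _logit(np.broadcast_to(np.asarray(p_logit, float)[None, :],
                               (n, histories.n_occasions - 1)))
    return cjs_loglik_matrices(histories.detections, histories.first, phi, p)


@dataclass
class CJSFit:
    """Maximum-likelihood CJS fit with observed-information standard errors."""

    names: list
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray | None
    loglik: float
    n_releases: int
    converged: bool
    formula: str
    p_formula: str
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.estimates)

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.estimates, "se": self.se},
                            index=self.names)


def fit_cjs(
    histories: CaptureHistories,
    formula: str = "tsm",
    covariates: pd.DataFrame | None = None,
    *,
    p_formula: str = "year",
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 2000,
) -> CJSFit:
    """Fit the CJS model by numerical maximum likelihood.

    ``formula`` gives the logit-survival terms over {tsm, sex, time,
    log_rt, log_alpha} with ``*``/``:`` interactions; resighting is
    year-specific (``p_formula="year"``) or constant (``"1"``).
    Optimisation restarts from ``n_starts`` seeded random points; standard
    errors come from the inverse observed information.
    """
    terms = parse_formula(formula)
    x, phi_names = _design(histories, covariates, terms)
    n, t = histories.detections.shape
    ni = t - 1
    n_phi = x.shape[-1]
    if p_formula == "year":
        p_names = [f"p[{histories.years[k + 1]}]" for k in range(ni)]
        n_p = ni
    elif p_formula in ("1", "constant"):
        p_names = ["p_intercept"]
        n_p = 1
    else:
        raise ValueError("p_formula must be 'year' or '1'")
    names = phi_names + p_names
    det, first = histories.detections, histories.first

    def unpack(theta):
        eta = np.tensordot(x, theta[:n_phi], axes=([2], [0]))
        phi = _logit(eta)
        p_par = theta[n_phi:]
        p_row = p_par if n_p == ni else np.repeat(p_par, ni)
        p = _logit(np.broadcast_to(p_row[None, :], (n, ni)))
        return phi, p

    def nll(theta):
        phi, p = unpack(theta)
        return -cjs_loglik_matrices(det, first, phi, p)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        theta0 = np.zeros(n_phi + n_p)
        if s > 0:
            theta0 += 0.5 * rng.standard_normal(theta0.size)
        res = opt.minimize(nll, theta0, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best.success)
    theta = best.x
    se = np.full(theta.size, np.nan)
    cov = None
    try:
        hess = approx_hess1(theta, nll)
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.any(d <= 0):
            converged = False
        else:
            se = np.sqrt(d)
    except np.linalg.LinAlgError:
        converged = False
    n_releases = int(det[:, :-1].sum())   # every detection before the final occasion
    return CJSFit(names=names, estimates=theta, se=se, cov=cov,
                  loglik=-float(best.fun), n_releases=n_releases,
                  converged=converged, formula=formula, p_formula=p_formula)


def qaicc(loglik: float, k: int, n_eff: int, c_hat: float = DEFAULT_CHAT) -> float:
    """Quasi-likelihood AICc: -2 logL / c-hat + 2K + 2K(K+1)/(n_eff-K-1)."""
    if c_hat < 1.0:
        raise ValueError("c-hat below 1 is not a valid overdispersion correction")
    if n_eff <= k + 1:
        raise ValueError("effective sample size too small for the AICc correction")
    return -2.0 * loglik / c_hat + 2.0 * k + 2.0 * k * (k + 1.0) / (n_eff - k - 1.0)


def qaicc_of(fit: CJSFit, c_hat: float = DEFAULT_CHAT) -> float:
    return qaicc(fit.loglik, fit.k, fit.n_releases, c_hat)


def compare(models: dict, c_hat: float = DEFAULT_CHAT) -> pd.DataFrame:
    """QAICc model-comparison table; delta_qaicc is relative to the best model."""
    rows = []
    for name, fit in models.items():
        q = qaicc_of(fit, c_hat)
        rows.append({"model": name, "K": fit.k,
                     "quasi_deviance": -2.0 * fit.loglik / c_hat,
                     "qaicc": q, "c_hat": c_hat})
    out = pd.DataFrame(rows).set_index("model")
    out["delta_qaicc"] = out["qaicc"] - out["qaicc"].min()
    return out.sort_values("qaicc")


def qaicc_contrast(simpler: CJSFit, complex_: CJSFit,
                   c_hat: float = DEFAULT_CHAT) -> float:
    """QAICc(simpler) - QAICc(complex): positive favours the complex model."""
    return qaicc_of(simpler, c_hat) - qaicc_of(complex_, c_hat)
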