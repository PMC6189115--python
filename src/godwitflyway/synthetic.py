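"""Synthetic data generator for every input stream of the pipeline.

Each generator forward-simulates the corresponding model at known
ground-truth parameters, so every downstream fit has a parameter-recovery
surface without external data.  The default configuration emulates the
study system: a ~25-year flyway monitoring programme with

* annual breeding-ground phenology driven causally by time and snowmelt
  (Gaussian structural equations),
* staging-site count sessions with a Gaussian arrival pulse, log-hours
  effort offset and negative-binomial observation error,
* arrival-type and refuelling-type body-mass captures with linear mass
  gain from latent individual arrival mass and date,
* capture-resighting histories from Bernoulli survival/resighting with
  survival driven by log refuelling rate and time,
* winter roost counts from deterministic exponential decline with
  negative-binomial observation error,
* a piecewise migration track with planted stopovers.

All streams are tied together through one simulated "annual truth" table
(staging arrival dates, breeding arrival dates, refuelling times, lugworm
densities and realised refuelling rates), exactly as the models assume.
Every generator is deterministic under a fixed configuration seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrival import expected_count
from .phenology import SEM_COEF_NAMES, SEM_STRUCTURE, SEM_SIGMA_NAMES
from .refuel import DEFAULT_MIGRATION_LAG_DAYS, SEXES
from .survival import parse_formula, term_name


class ConfigError(ValueError):
    """A required ground-truth parameter is missing or invalid."""


# ---------------------------------------------------------------------------
# ground-truth parameter blocks (defaults are the study conditions)
# ---------------------------------------------------------------------------

def _default_b():
    return {
        "b1.1": -0.04,   # staging arrival ~ time (d/yr)
        "b2.1": -0.73,   # snowmelt ~ time
        "b3.1": -0.12, "b3.2": 0.22, "b3.3": 0.20,   # Arctic arrival eq.
        "b4.1": -0.12, "b4.2": 0.38,                 # crane-fly eq.
        "b5.1": -0.35, "b5.2": 0.25, "b5.3": 0.50, "b5.4": 0.05,  # clutch eq.
    }


def _default_sigma():
    return {
        "arrival_ws_doy": 2.0,
        "snowmelt_doy": 5.4,
        "arrival_taimyr_doy": 2.5,
        "cranefly_doy": 4.0,
        "clutch_doy": 2.5,
    }


def _default_means():
    return {
        "arrival_ws_doy": 122.0,
        "snowmelt_doy": 160.0,
        "arrival_taimyr_doy": 152.0,
        "cranefly_doy": 175.0,
        "clutch_doy": 162.0,
    }


@dataclass
class SEMTruth:
    b: dict = field(default_factory=_default_b)
    sigma: dict = field(default_factory=_default_sigma)
    means: dict = field(default_factory=_default_means)


@dataclass
class ArrivalTruth:
    a0: float = 6.0
    sigma_t0: float = 6.0          # spread of the arrival pulse (days)
    r: float = 1.5                 # NB size of session counts
    sigma_total: float = 0.3       # year random-effect sd (log scale)
    sigma_site: float = 0.5        # site random-effect sd (log scale)
    sessions_per_site_year: int = 13
    effort_hours: tuple = (1.0, 8.0)   # log-uniform support
    window: tuple = (100, 145)         # 10 Apr .. 25 May


@dataclass
class RefuelTruth:
    w0: dict = field(default_factory=lambda: {"female": 320.0, "male": 250.0})
    sigma_w0: dict = field(default_factory=lambda: {"female": 22.0, "male": 18.0})
    lugworm_intercept: dict = field(
        default_factory=lambda: {"female": 3.36, "male": 2.60})
    lugworm_slope: dict = field(
        default_factory=lambda: {"female": 0.21, "male": 0.18})
    sigma_alpha: dict = field(default_factory=lambda: {"female": 0.6, "male": 0.6})
    density_mean: float = 14.0     # lugworms per m^2
    density_sd: float = 4.0
    arrivals_per_year_sex: int = 55
    refuels_per_year_sex: int = 125
    migration_lag_days: float = DEFAULT_MIGRATION_LAG_DAYS


@dataclass
class CJSTruth:
    formula: str = "tsm + sex + log_rt*sex + log_alpha"
    beta: dict = field(default_factory=lambda: {
        "phi_intercept": -3.6,
        "phi_tsm": -0.7,
        "phi_sex": -4.78,
        "phi_log_rt": 1.43,
        "phi_log_rt:sex": 1.43,
        "phi_log_alpha": 0.98,
    })
    p_logit_mean: float = -0.62    # resighting probability ~ 0.35
    p_logit_sd: float = 0.3


@dataclass
class PopTruth:
    lam: float = 0.96
    n1: tuple = (3000.0, 2500.0, 2000.0, 1500.0, 1000.0, 800.0)
    r: tuple = (8.0,) * 6


@dataclass
class TrackTruth:
    """Waypoints (lon, lat, dwell_h, jitter_km) joined by timed flight legs."""

    waypoints: tuple = (
        (-16.3, 19.8, 6.0, 1.0),      # wintering roost
        (5.3, 53.4, 588.0, 1.0),      # staging site, ~24.5 d dwell
        (102.5, 72.0, 48.0, 1.0),     # breeding grounds
    )
    leg_hours: tuple = (91.2, 132.0)  # ~3.8 d and ~5.5 d nonstop legs
    fix_interval_h: float = 2.0
    speed_kmh: float = 55.0           # nominal; geometry is waypoint-driven


@dataclass
class SnowTruth:
    n_cells: int = 2
    melt_doy_mean: float = 160.0
    melt_doy_trend: float = -0.73     # d per year
    melt_doy_sd: float = 4.0
    first_week_start: int = 1
    n_weeks: int = 40                 # Jan .. early Oct


@dataclass
class SyntheticConfig:
    """Full ground truth plus design sizes for all generated streams."""

    years: tuple = tuple(range(1992, 2017))
    n_sites_counts: int = 7
    n_individuals: int = 3995
    seed: int = 0
    sem: SEMTruth = field(default_factory=SEMTruth)
    arrival: ArrivalTruth = field(default_factory=ArrivalTruth)
    refuel: RefuelTruth = field(default_factory=RefuelTruth)
    cjs: CJSTruth = field(default_factory=CJSTruth)
    pop: PopTruth = field(default_factory=PopTruth)
    track: TrackTruth = field(default_factory=TrackTruth)
    snow: SnowTruth = field(default_factory=SnowTruth)
    count_years: tuple = tuple(range(2002, 2017))   # winter-count span
    cjs_years: tuple | None = None                  # resighting occasions

    def __post_init__(self):
        years = list(self.years)
        if self.cjs_years is None:
            self.cjs_years = tuple(y for y in self.years if y >= 2002) or self.years
        if not set(self.cjs_years) <= set(self.years):
            raise ConfigError("cjs_years must be a subset of years")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigError("years must be strictly increasing")
        for name in ("n_sites_counts", "n_individuals"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for resp, preds in SEM_STRUCTURE.items():
            for p in preds:
                key = SEM_COEF_NAMES[(resp, p)]
                if key not in self.sem.b:
                    raise ConfigError(f"missing SEM coefficient {key}")
            if resp not in self.sem.sigma:
                raise ConfigError(f"missing SEM residual sd for {resp}")
        if self.arrival.r <= 0:
            raise ConfigError("NB size r must be positive")
        for sex in SEXES:
            for block, label in ((self.refuel.lugworm_intercept, "lugworm_intercept"),
                                 (self.refuel.lugworm_slope, "lugworm_slope"),
                                 (self.refuel.w0, "w0"),
                                 (self.refuel.sigma_w0, "sigma_w0")):
                if sex not in block:
                    raise ConfigError(f"missing refuel truth {label}[{sex}]")
        terms = parse_formula(self.cjs.formula)
        names = ["phi_intercept"] + ["phi_" + term_name(t) for t in terms]
        for nm in names:
            if nm not in self.cjs.beta:
                raise ConfigError(f"missing CJS coefficient {nm}")


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a plain (e.g. YAML-loaded)
    mapping; nested blocks map onto the truth dataclasses."""
    blocks = {"sem": SEMTruth, "arrival": ArrivalTruth, "refuel": RefuelTruth,
              "cjs": CJSTruth, "pop": PopTruth, "track": TrackTruth,
              "snow": SnowTruth}
    kwargs = {}
    for key, value in d.items():
        if key in blocks:
            kwargs[key] = blocks[key](**value)
        elif key in ("years", "count_years", "cjs_years") and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return SyntheticConfig(**kwargs)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible substream per generator."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# phenology (structural equations, causal order)
# ---------------------------------------------------------------------------

def gen_phenology(config: SyntheticConfig, *, centred: bool = False) -> pd.DataFrame:
    """Annual phenology table simulated from the path model.

    Variables are generated in causal order (time -> snowmelt / staging
    arrival -> Arctic arrival & crane-fly emergence -> clutch initiation)
    with variable-specific Gaussian errors around configured means.
    """
    rng = _rng(config, 1)
    years = np.asarray(config.years, float)
    time = years - years.mean()
    b, sig, means = config.sem.b, config.sem.sigma, config.sem.means
    values = {"time": time}
    out = {"year": np.asarray(config.years, int)}
    for resp, preds in SEM_STRUCTURE.items():
        eta = np.zeros_like(time)
        for p in preds:
            eta = eta + b[SEM_COEF_NAMES[(resp, p)]] * values[p]
        eps = rng.normal(0.0, sig[resp], size=len(time)) if sig[resp] > 0 else 0.0
        values[resp] = eta + eps
        out[resp] = values[resp] + (0.0 if centred else means[resp])
    return pd.DataFrame(out)


def annual_truth(config: SyntheticConfig) -> pd.DataFrame:
    """The simulated annual ground truth shared by all staging streams.

    Columns: year, t0 (staging arrival), arrival_taimyr, rt (refuelling
    time), density (lugworms per m^2), alpha_female, alpha_male,
    mu_alpha_*.  Deterministic for a given config.
    """
    phen = gen_phenology(config)
    rng = _rng(config, 2)
    t = phen.set_index("year")
    dens = np.clip(rng.normal(config.refuel.density_mean, config.refuel.density_sd,
                              size=len(phen)), 2.0, 40.0)
    rows = []
    for i, year in enumerate(phen["year"]):
        t0 = float(t.loc[year, "arrival_ws_doy"])
        taimyr = float(t.loc[year, "arrival_taimyr_doy"])
        rt = (taimyr - config.refuel.migration_lag_days) - t0
        row = {"year": int(year), "t0": t0, "arrival_taimyr": taimyr,
               "rt": rt, "density": float(dens[i])}
        for sex in SEXES:
            mu = (config.refuel.lugworm_intercept[sex]
                  + config.refuel.lugworm_slope[sex] * dens[i])
            alpha = mu + rng.normal(0.0, config.refuel.sigma_alpha[sex])
            row[f"mu_alpha_{sex}"] = mu
            row[f"alpha_{sex}"] = float(max(alpha, 0.5))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staging-site count sessions
# ---------------------------------------------------------------------------

def gen_count_sessions(config: SyntheticConfig,
                       annual: pd.DataFrame | None = None) -> pd.DataFrame:
    """Count sessions with NB error around the Gaussian arrival pulse."""
    if config.arrival.r <= 0:
        raise ConfigError("NB size r must be positive")
    rng = _rng(config, 3)
    if annual is None:
        annual = annual_truth(config)
    tr = config.arrival
    n_sites = config.n_sites_counts
    site_eff = rng.normal(0.0, tr.sigma_site, size=n_sites)
    site_eff -= site_eff.mean()
    year_eff = rng.normal(0.0, tr.sigma_total, size=len(annual))
    year_eff -= year_eff.mean()
    lo_h, hi_h = tr.effort_hours
    d0, d1 = tr.window
    rows = []
    for yi, row in annual.iterrows():
        for si in range(n_sites):
            days = rng.integers(d0, d1 + 1, size=tr.sessions_per_site_year)
            hours = np.exp(rng.uniform(np.log(lo_h), np.log(hi_h), size=len(days)))
            n_exp = expected_count(tr.a0, year_eff[yi], site_eff[si],
                                   days.astype(float), hours,
                                   row["t0"], tr.sigma_t0)
            p = tr.r / (tr.r + n_exp)
            counts = rng.negative_binomial(tr.r, p)
            for d, h, c in zip(days, hours, counts):
                rows.append({"site_id": f"S{si + 1:02d}", "year": int(row["year"]),
                             "day": int(d), "duration_h": float(h), "count": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# body-mass captures
# ---------------------------------------------------------------------------

def gen_captures(config: SyntheticConfig,
                 annual: pd.DataFrame | None = None) -> pd.DataFrame:
    """Arrival-type and refuelling-type capture records.

    Arrival captures: mass ~ Norm(W0_ks, sigmaW0_s^2) on the arrival day.
    Refuelling captures: latent individual arrival mass and date, then
    linear gain at the year-sex rate alpha_ks.
    """
    rng = _rng(config, 4)
    if annual is None:
        annual = annual_truth(config)
    tr = config.refuel
    rows = []
    uid = 0
    for _, row in annual.iterrows():
        year = int(row["year"])
        for sex in SEXES:
            if f"alpha_{sex}" not in row:
                raise ConfigError(f"missing alpha for ({year}, {sex})")
            w0, sw0 = tr.w0[sex], tr.sigma_w0[sex]
            alpha = row[f"alpha_{sex}"]
            for _ in range(tr.arrivals_per_year_sex):
                uid += 1
                rows.append({
                    "id": f"A{uid:06d}", "year": year, "sex": sex,
                    "day": int(round(row["t0"])),
                    "mass_g": float(rng.normal(w0, sw0)),
                    "capture_type": "arrival",
                })
            span = max(int(np.floor(row["rt"])), 5)
            for _ in range(tr.refuels_per_year_sex):
                uid += 1
                w0_i = rng.normal(w0, sw0)
                t0_i = rng.normal(row["t0"], config.arrival.sigma_t0)
                day = int(rng.integers(int(np.ceil(row["t0"])),
                                       int(np.ceil(row["t0"])) + span + 1))
                rows.append({
                    "id": f"R{uid:06d}", "year": year, "sex": sex, "day": day,
                    "mass_g": float(w0_i + alpha * (day - t0_i)),
                    "capture_type": "refuelling",
                })
    return pd.DataFrame(rows)


def gen_lugworms(config: SyntheticConfig,
                 annual: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annual late-winter lugworm densities (one station mean per year)."""
    if annual is None:
        annual = annual_truth(config)
    return annual[["year", "density"]].copy()


# ---------------------------------------------------------------------------
# capture-resighting histories
# ---------------------------------------------------------------------------

def gen_histories(config: SyntheticConfig,
                  annual: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per marked individual: sex, marking year, 0/1 per occasion.

    Survival each interval is Bernoulli with logit(Phi) from the configured
    formula over (tsm, sex, time, log refuelling rate, log refuelling
    time); resighting is Bernoulli with year-specific p.  Individuals are
    marked uniformly over all occasions but the last.
    """
    rng = _rng(config, 5)
    if annual is None:
        annual = annual_truth(config)
    years = list(config.cjs_years)
    t = len(years)
    ann = annual.set_index("year")
    terms = parse_formula(config.cjs.formula)
    beta = config.cjs.beta
    p_logit = rng.normal(config.cjs.p_logit_mean, config.cjs.p_logit_sd, size=t - 1)
    p_year = 1.0 / (1.0 + np.exp(-p_logit))

    n = config.n_individuals
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    first = rng.integers(0, t - 1, size=n)
    det = np.zeros((n, t), dtype=int)
    det[np.arange(n), first] = 1

    # logit(Phi) per (sex, interval)
    phi = {}
    for s in SEXES:
        sex_val = 1.0 if s == "female" else 0.0
        for k in range(t - 1):
            year = years[k]
            base = {
                "tsm": None,  # handled per individual
                "sex": sex_val,
                "time": float(k),
                "log_rt": np.log(ann.loc[year, "rt"]),
                "log_alpha": np.log(ann.loc[year, f"alpha_{s}"]),
            }
            for tsm in (0.0, 1.0):
                base["tsm"] = tsm
                eta = beta["phi_intercept"]
                for term in terms:
                    v = 1.0
                    for var in term:
                        v *= base[var]
                    eta += beta["phi_" + term_name(term)] * v
                phi[(s, k, tsm)] = 1.0 / (1.0 + np.exp(-eta))

    for i in range(n):
        alive = True
        for k in range(first[i], t - 1):
            tsm = 1.0 if k == first[i] else 0.0
            if alive and rng.random() < phi[(sex[i], k, tsm)]:
                if rng.random() < p_year[k]:
                    det[i, k + 1] = 1
            else:
                alive = False
                break
    out = pd.DataFrame({"id": [f"B{i + 1:05d}" for i in range(n)],
                        "sex": sex, "first_year": [years[f] for f in first]})
    for j, year in enumerate(years):
        out[f"y{year}"] = det[:, j]
    return out


def cjs_covariates(config: SyntheticConfig,
                   annual: pd.DataFrame | None = None) -> pd.DataFrame:
    """Year-level covariate table (rt, alpha per sex) for the survival model."""
    if annual is None:
        annual = annual_truth(config)
    cov = annual[["year", "rt", "alpha_female", "alpha_male"]].copy()
    return cov[cov["year"].isin(config.cjs_years)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# winter counts
# ---------------------------------------------------------------------------

def gen_winter_counts(config: SyntheticConfig) -> pd.DataFrame:
    """Winter roost counts: exponential latent decline, NB observation."""
    rng = _rng(config, 6)
    tr = config.pop
    years = list(config.count_years)
    rows = []
    for si, (n1, r_i) in enumerate(zip(tr.n1, tr.r)):
        for k, year in enumerate(years):
            n_lat = n1 * tr.lam ** k
            if np.isinf(r_i):
                c = int(round(n_lat))
            else:
                p = r_i / (r_i + n_lat)
                c = int(rng.negative_binomial(r_i, p))
            rows.append({"site_id": f"W{si + 1}", "year": int(year), "count": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# migration track
# ---------------------------------------------------------------------------

def gen_track(config: SyntheticConfig, bird_id: str = "T01") -> pd.DataFrame:
    """Piecewise track: dwells with jitter at waypoints, timed flight legs."""
    rng = _rng(config, 7)
    tr = config.track
    if len(tr.leg_hours) != len(tr.waypoints) - 1:
        raise ConfigError("need one leg duration per consecutive waypoint pair")
    fixes = []
    t_h = 0.0
    km_per_deg = 111.19
    for w, (lon, lat, dwell_h, jitter_km) in enumerate(tr.waypoints):
        n_fix = max(int(dwell_h / tr.fix_interval_h) + 1, 1)
        for _ in range(n_fix):
            jlon = rng.normal(0, jitter_km / (km_per_deg * np.cos(np.radians(lat))))
            jlat = rng.normal(0, jitter_km / km_per_deg)
            fixes.append((t_h, lon + jlon, lat + jlat))
            t_h += tr.fix_interval_h
        t_h -= tr.fix_interval_h
        if w < len(tr.leg_hours):
            leg_h = tr.leg_hours[w]
            lon2, lat2, _, _ = tr.waypoints[w + 1]
            n_leg = max(int(leg_h / tr.fix_interval_h), 1)
            for j in range(1, n_leg):
                frac = j / n_leg
                fixes.append((t_h + frac * leg_h,
                              lon + frac * (lon2 - lon), lat + frac * (lat2 - lat)))
            t_h += leg_h
    t0 = pd.Timestamp("2016-04-20 00:00:00")
    return pd.DataFrame({
        "id": bird_id,
        "timestamp": [t0 + pd.Timedelta(hours=h) for h, _, _ in fixes],
        "lon": [x for _, x, _ in fixes],
        "lat": [y for _, _, y in fixes],
    })


# ---------------------------------------------------------------------------
# weekly snow-cover series
# ---------------------------------------------------------------------------

def gen_snow(config: SyntheticConfig) -> pd.DataFrame:
    """Weekly binary snow-cover series per grid cell with a melt trend."""
    rng = _rng(config, 8)
    tr = config.snow
    years = np.asarray(config.years, float)
    time = years - years.mean()
    rows = []
    for ci in range(tr.n_cells):
        melts = (tr.melt_doy_mean + tr.melt_doy_trend * time
                 + rng.normal(0, tr.melt_doy_sd, size=len(years)))
        for year, melt in zip(config.years, melts):
            for w in range(tr.n_weeks):
                start = tr.first_week_start + 7 * w
                covered = int(start + 7 <= melt)   # week fully before the melt day
                rows.append({"cell_id": f"C{ci + 1}", "year": int(year),
                             "week_start_doy": start, "covered": covered})
    return pd.DataFrame(rows)


def gen_all(config: SyntheticConfig) -> dict:
    """All streams at once, sharing a single annual-truth draw."""
    annual = annual_truth(config)
    return {
        "phenology": gen_phenology(config),
        "annual_truth": annual,
        "sessions": gen_count_sessions(config, annual),
        "captures": gen_captures(config, annual),
        "lugworms": gen_lugworms(config, annual),
        "histories": gen_histories(config, annual),
        "covariates": cjs_covariates(config, annual),
        "winter_counts": gen_winter_counts(config),
        "track": gen_track(config),
        "snow": gen_snow(config),
    }
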