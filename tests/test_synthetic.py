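"""Generators: determinism, generative-model moment checks, config errors."""
import numpy as np
import pandas as pd
import pytest

from godwitflyway import phenology as ph
from godwitflyway import synthetic as syn


class TestDeterminism:
    def test_every_generator_repeats_under_fixed_seed(self, small_config):
        a = syn.gen_all(small_config)
        b = syn.gen_all(small_config)
        assert set(a) == set(b)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_different_seeds_differ(self, small_config):
        other = syn.SyntheticConfig(seed=small_config.seed + 1,
                                    years=small_config.years,
                                    n_sites_counts=small_config.n_sites_counts,
                                    n_individuals=small_config.n_individuals)
        a = syn.gen_phenology(small_config)
        b = syn.gen_phenology(other)
        assert not a.drop(columns="year").equals(b.drop(columns="year"))


class TestGenPhenology:
    def test_noise_free_trend_is_exact(self):
        cfg = syn.SyntheticConfig(seed=1, years=tuple(range(1993, 2017)))
        cfg.sem.sigma = {k: 0.0 for k in cfg.sem.sigma}
        cfg.sem.b["b2.1"] = -0.73
        table = syn.gen_phenology(cfg)
        fit = ph.fit_trend(table["snowmelt_doy"], table["year"])
        assert fit.slope == pytest.approx(-0.73, abs=1e-10)
        assert fit.resid_ss == pytest.approx(0.0, abs=1e-12)

    def test_zero_effects_give_constant_series(self):
        cfg = syn.SyntheticConfig(seed=2)
        cfg.sem.b = {k: 0.0 for k in cfg.sem.b}
        cfg.sem.sigma = {k: 0.0 for k in cfg.sem.sigma}
        table = syn.gen_phenology(cfg)
        for col, mean in cfg.sem.means.items():
            np.testing.assert_allclose(table[col], mean)

    def test_long_run_slope_recovery(self):
        cfg = syn.SyntheticConfig(seed=3, years=tuple(range(1, 10001)))
        cfg.sem.b["b2.1"] = -0.5
        cfg.sem.sigma["snowmelt_doy"] = 2.0
        table = syn.gen_phenology(cfg)
        fit = ph.fit_trend(table["snowmelt_doy"], table["year"])
        assert abs(fit.slope - (-0.5)) < 3 * fit.se

    def test_missing_coefficient_named_in_error(self):
        cfg_kwargs = dict(seed=4, years=(2000, 2001, 2002))
        cfg = syn.SyntheticConfig(**cfg_kwargs)
        bad = dict(cfg.sem.b)
        del bad["b3.2"]
        with pytest.raises(syn.ConfigError, match="b3.2"):
            syn.SyntheticConfig(sem=syn.SEMTruth(b=bad), **cfg_kwargs)


class TestGenCountSessions:
    def _fixed_design_config(self, r, n_sessions=4000):
        cfg = syn.SyntheticConfig(seed=5, years=(2010,), n_sites_counts=1)
        cfg.arrival.r = r
        cfg.arrival.sessions_per_site_year = n_sessions
        cfg.arrival.effort_hours = (4.0, 4.0)
        cfg.arrival.window = (120, 120)     # one day: sessions share one N
        return cfg

    def test_poisson_limit_at_huge_r(self):
        cfg = self._fixed_design_config(r=1e9)
        annual = syn.annual_truth(cfg).assign(t0=120.0)
        sess = syn.gen_count_sessions(cfg, annual)
        ratio = sess["count"].var(ddof=1) / sess["count"].mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_overdispersion_at_small_r(self):
        cfg = self._fixed_design_config(r=1.0)
        annual = syn.annual_truth(cfg).assign(t0=120.0)
        sess = syn.gen_count_sessions(cfg, annual)
        assert sess["count"].var(ddof=1) / sess["count"].mean() > 5.0

    def test_effort_offset_doubles_mean_count(self):
        means = {}
        for hours in (2.0, 4.0):
            cfg = self._fixed_design_config(r=5.0)
            cfg.arrival.effort_hours = (hours, hours)
            annual = syn.annual_truth(cfg).assign(t0=120.0)
            means[hours] = syn.gen_count_sessions(cfg, annual)["count"].mean()
        assert means[4.0] / means[2.0] == pytest.approx(2.0, abs=0.1)

    def test_count_weighted_day_centres_on_t0(self):
        cfg = syn.SyntheticConfig(seed=6, years=(2010,), n_sites_counts=2)
        cfg.arrival.sessions_per_site_year = 4000
        annual = syn.annual_truth(cfg).assign(t0=120.0)
        sess = syn.gen_count_sessions(cfg, annual)
        wmean = np.average(sess["day"], weights=sess["count"])
        assert abs(wmean - 120.0) < 0.5

    def test_invalid_r_rejected(self):
        cfg = syn.SyntheticConfig(seed=7, years=(2010,))
        cfg.arrival.r = -1.0
        with pytest.raises(syn.ConfigError):
            syn.gen_count_sessions(cfg)


class TestGenCaptures:
    def test_noise_free_linear_gain(self):
        cfg = syn.SyntheticConfig(seed=8, years=(2010,))
        cfg.refuel.sigma_w0 = {"female": 0.0, "male": 0.0}
        cfg.refuel.sigma_alpha = {"female": 0.0, "male": 0.0}
        cfg.refuel.lugworm_slope = {"female": 0.0, "male": 0.0}
        cfg.refuel.lugworm_intercept = {"female": 10.0, "male": 10.0}
        cfg.refuel.w0 = {"female": 250.0, "male": 250.0}
        cfg.arrival.sigma_t0 = 0.0
        annual = syn.annual_truth(cfg).assign(t0=120.0)
        caps = syn.gen_captures(cfg, annual)
        ref = caps[caps["capture_type"] == "refuelling"]
        expect = 250.0 + 10.0 * (ref["day"] - 120.0)
        np.testing.assert_allclose(ref["mass_g"], expect, atol=1e-9)
        # a bird captured 5 days in weighs exactly 300 g
        five = ref[ref["day"] == 125]
        assert (five["mass_g"] == 300.0).all() and len(five) > 0

    def test_capture_at_t0_matches_arrival_mass_distribution(self):
        cfg = syn.SyntheticConfig(seed=9, years=(2010,))
        cfg.arrival.sigma_t0 = 0.0
        annual = syn.annual_truth(cfg).assign(t0=120.0)
        caps = syn.gen_captures(cfg, annual)
        ref = caps[(caps["capture_type"] == "refuelling") & (caps["day"] == 120)]
        arrv = caps[caps["capture_type"] == "arrival"]
        # same Normal(W0, sigmaW0): compare moments per sex
        for sex in ("female", "male"):
            a = arrv[arrv["sex"] == sex]["mass_g"]
            r = ref[ref["sex"] == sex]["mass_g"]
            if len(r) >= 5:
                pooled_se = np.sqrt(a.var() / len(a) + r.var() / len(r))
                assert abs(a.mean() - r.mean()) < 4 * pooled_se

    def test_mass_day_regression_recovers_rate(self):
        cfg = syn.SyntheticConfig(seed=10, years=(2010,))
        cfg.refuel.refuels_per_year_sex = 4000
        cfg.refuel.sigma_alpha = {"female": 0.0, "male": 0.0}
        cfg.refuel.lugworm_slope = {"female": 0.0, "male": 0.0}
        cfg.refuel.lugworm_intercept = {"female": 8.0, "male": 8.0}
        annual = syn.annual_truth(cfg).assign(t0=120.0)
        caps = syn.gen_captures(cfg, annual)
        ref = caps[(caps["capture_type"] == "refuelling") & (caps["sex"] == "male")]
        fit = ph.fit_trend(ref["mass_g"], ref["day"])
        assert abs(fit.slope - 8.0) < 3 * fit.se


class TestGenHistories:
    def _config(self, phi_logit, p_logit, years, n):
        cfg = syn.SyntheticConfig(seed=11, years=years, n_individuals=n)
        cfg.cjs.formula = "1"
        cfg.cjs.beta = {"phi_intercept": phi_logit}
        cfg.cjs.p_logit_mean = p_logit
        cfg.cjs.p_logit_sd = 0.0
        return cfg

    def test_certain_survival_and_resighting(self):
        cfg = self._config(50.0, 50.0, tuple(range(2010, 2015)), 40)
        hist = syn.gen_histories(cfg)
        ycols = [c for c in hist.columns if c.startswith("y")]
        for _, row in hist.iterrows():
            first = int(row["first_year"])
            seen = [int(row[f"y{y}"]) for y in range(first, 2015)]
            assert all(v == 1 for v in seen)

    def test_zero_survival_means_no_resightings(self):
        cfg = self._config(-50.0, 2.0, tuple(range(2010, 2015)), 40)
        hist = syn.gen_histories(cfg)
        ycols = [c for c in hist.columns if c.startswith("y")]
        assert (hist[ycols].sum(axis=1) == 1).all()

    def test_two_occasion_resighting_fraction(self):
        phi, p = 0.8, 0.6
        cfg = self._config(np.log(phi / (1 - phi)), np.log(p / (1 - p)),
                           (2010, 2011), 20000)
        cfg.cjs_years = (2010, 2011)
        hist = syn.gen_histories(cfg)
        frac = hist["y2011"].mean()
        mc_se = np.sqrt(0.48 * 0.52 / 20000)
        assert abs(frac - phi * p) < 4 * mc_se


class TestGenWinterCounts:
    def test_infinite_dispersion_constant_at_lambda_one(self):
        cfg = syn.SyntheticConfig(seed=12)
        cfg.pop = syn.PopTruth(lam=1.0, n1=(500.0,), r=(np.inf,))
        counts = syn.gen_winter_counts(cfg)
        assert (counts["count"] == 500).all()

    def test_halving_latent_series_closed_form(self):
        cfg = syn.SyntheticConfig(seed=13, count_years=(2010, 2011, 2012))
        cfg.pop = syn.PopTruth(lam=0.5, n1=(1000.0,), r=(np.inf,))
        counts = syn.gen_winter_counts(cfg)
        assert counts["count"].tolist() == [1000, 500, 250]


class TestConfigValidation:
    def test_years_must_increase(self):
        with pytest.raises(syn.ConfigError, match="increasing"):
            syn.SyntheticConfig(years=(2001, 2000))

    def test_counts_at_least_one(self):
        with pytest.raises(syn.ConfigError):
            syn.SyntheticConfig(n_individuals=0)

    def test_missing_cjs_coefficient_named(self):
        cfg_kwargs = dict(seed=1, years=(2010, 2011, 2012))
        with pytest.raises(syn.ConfigError, match="phi_log_alpha"):
            syn.SyntheticConfig(
                cjs=syn.CJSTruth(beta={"phi_intercept": -3.0, "phi_tsm": 0.0,
                                       "phi_sex": 0.0, "phi_log_rt": 1.0,
                                       "phi_log_rt:sex": 1.0}),
                **cfg_kwargs)
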