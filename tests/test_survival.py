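"""CJS likelihood, fitting and QAICc model comparison."""
import itertools

import numpy as np
import pandas as pd
import pytest

from godwitflyway import survival as sv
from godwitflyway import synthetic as syn


def enumeration_loglik(det, first, phi, p):
    """Independent CJS oracle: sum over all latent death-time fates.

    ``phi[i, k]``: survival over interval k; ``p[i, k]``: detection at
    occasion k+1.  For each individual, sums the probability of the
    observed post-marking detection vector over every possible last-alive
    occasion.
    """
    n, t = det.shape
    total = 0.0
    for i in range(n):
        f = first[i]
        dets = np.where(det[i] == 1)[0]
        last = dets.max()
        prob = 0.0
        for m in range(f, t):           # m = last occasion alive
            if m < last:
                continue
            pr = 1.0
            for k in range(f, m):
                pr *= phi[i, k]
            if m < t - 1:
                pr *= 1.0 - phi[i, m]
            for occ in range(f + 1, m + 1):
                pk = p[i, occ - 1]
                pr *= pk if det[i, occ] == 1 else 1.0 - pk
            if det[i, m + 1:].any():
                pr = 0.0
            prob += pr
        total += np.log(prob)
    return total


def random_histories(rng, n, t):
    det = np.zeros((n, t), dtype=int)
    first = rng.integers(0, t - 1, size=n)
    det[np.arange(n), first] = 1
    for i in range(n):
        det[i, first[i] + 1:] = rng.integers(0, 2, size=t - first[i] - 1)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    return sv.CaptureHistories(det, first, sex, list(range(2000, 2000 + t)))


class TestCJSLoglik:
    def test_three_occasion_hand_example(self):
        # history 1 1 0 with Phi = 0.5, p = 1: survive+seen (0.5), then
        # never seen again: (1 - 0.5) + 0.5 * 0 = 0.5 -> likelihood 0.25
        h = sv.CaptureHistories(np.array([[1, 1, 0]]), np.array([0]),
                                np.array(["male"]), [2000, 2001, 2002])
        ll = sv.cjs_loglik(h, [0.0], np.array([50.0, 50.0]),
                           sv.parse_formula("1"))
        assert np.exp(ll) == pytest.approx(0.25, abs=1e-9)

    def test_certain_survival_and_detection(self):
        h = sv.CaptureHistories(np.array([[1, 1, 1, 1]]), np.array([0]),
                                np.array(["female"]), list(range(2000, 2004)))
        ll = sv.cjs_loglik(h, [50.0], np.full(3, 50.0), sv.parse_formula("1"))
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("t", [2, 3, 4])
    def test_matches_exhaustive_enumeration(self, t):
        rng = np.random.default_rng(100 + t)
        for rep in range(5):
            h = random_histories(rng, 12, t)
            # drop histories with detections 'after death' impossible:
            # all detection vectors are valid CJS observations
            phi = rng.uniform(0.2, 0.95, size=(12, t - 1))
            p = rng.uniform(0.1, 0.9, size=(12, t - 1))
            ll = sv.cjs_loglik_matrices(h.detections, h.first, phi, p)
            oracle = enumeration_loglik(h.detections, h.first, phi, p)
            assert ll == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("t", [2, 3, 4])
    def test_probabilities_sum_to_one_over_detection_vectors(self, t):
        rng = np.random.default_rng(200 + t)
        phi = rng.uniform(0.1, 0.95, size=(1, t - 1))
        p = rng.uniform(0.05, 0.95, size=(1, t - 1))
        total = 0.0
        for tail in itertools.product([0, 1], repeat=t - 1):
            det = np.array([[1] + list(tail)])
            ll = sv.cjs_loglik_matrices(det, np.array([0]), phi, p)
            total += np.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_permuting_individuals(self):
        rng = np.random.default_rng(5)
        h = random_histories(rng, 30, 5)
        phi = rng.uniform(0.3, 0.9, size=(30, 4))
        p = rng.uniform(0.2, 0.8, size=(30, 4))
        perm = rng.permutation(30)
        a = sv.cjs_loglik_matrices(h.detections, h.first, phi, p)
        b = sv.cjs_loglik_matrices(h.detections[perm], h.first[perm],
                                   phi[perm], p[perm])
        assert a == pytest.approx(b, abs=1e-10)

    def test_missing_covariate_year_raises(self):
        h = random_histories(np.random.default_rng(1), 5, 3)
        cov = pd.DataFrame({"year": [2000], "rt": [24.0],
                            "alpha_female": [6.0], "alpha_male": [5.0]})
        with pytest.raises(ValueError, match="2001"):
            sv.fit_cjs(h, "log_rt", cov, n_starts=1)


class TestFitCJS:
    def test_two_occasion_closed_form_product(self):
        # with 2 occasions only the product Phi * p is identified and its
        # MLE is the resighted fraction
        rng = np.random.default_rng(8)
        n = 4000
        det = np.ones((n, 2), dtype=int)
        det[:, 1] = (rng.random(n) < 0.8 * 0.5).astype(int)
        h = sv.CaptureHistories(det, np.zeros(n, dtype=int),
                                np.where(rng.random(n) < 0.5, "female", "male"),
                                [2000, 2001])
        fit = sv.fit_cjs(h, "1", None, n_starts=1)
        phi = 1 / (1 + np.exp(-fit.coef("phi_intercept")))
        p = 1 / (1 + np.exp(-fit.coef("p[2001]")))
        assert phi * p == pytest.approx(det[:, 1].mean(), abs=1e-6)

    def test_constant_model_recovers_truth(self):
        cfg = syn.SyntheticConfig(seed=51, years=tuple(range(2005, 2013)),
                                  n_individuals=3000)
        cfg.cjs.formula = "1"
        cfg.cjs.beta = {"phi_intercept": np.log(0.8 / 0.2)}
        cfg.cjs.p_logit_mean = np.log(0.5 / 0.5)
        cfg.cjs.p_logit_sd = 0.0
        hist = sv.CaptureHistories.from_frame(syn.gen_histories(cfg))
        fit = sv.fit_cjs(hist, "1", None, p_formula="1", n_starts=2)
        phi = 1 / (1 + np.exp(-fit.coef("phi_intercept")))
        p = 1 / (1 + np.exp(-fit.coef("p_intercept")))
        assert phi == pytest.approx(0.8, abs=0.03)
        assert p == pytest.approx(0.5, abs=0.04)

    def test_covariate_slope_recovery(self):
        cfg = syn.SyntheticConfig(seed=52, years=tuple(range(2002, 2017)),
                                  n_individuals=5000)
        cfg.cjs.formula = "tsm + log_rt"
        cfg.cjs.beta = {"phi_intercept": -4.0, "phi_tsm": -0.5, "phi_log_rt": 2.0}
        annual = syn.annual_truth(cfg)
        hist = sv.CaptureHistories.from_frame(syn.gen_histories(cfg, annual))
        cov = syn.cjs_covariates(cfg, annual)
        fit = sv.fit_cjs(hist, "tsm + log_rt", cov, n_starts=2)
        est, se = fit.coef("phi_log_rt"), fit.coef_se("phi_log_rt")
        assert abs(est - 2.0) < 3 * se
        assert fit.converged


class TestQAICc:
    def test_chat_one_reduces_to_aicc(self):
        ll, k, n = -100.0, 4, 200
        aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert sv.qaicc(ll, k, n, 1.0) == pytest.approx(aicc)

    def test_identical_models_tie(self):
        fit = sv.CJSFit(names=["a"], estimates=np.array([0.0]),
                        se=np.array([1.0]), cov=None, loglik=-50.0,
                        n_releases=100, converged=True, formula="1",
                        p_formula="1")
        table = sv.compare({"m1": fit, "m2": fit}, c_hat=1.118)
        assert table["delta_qaicc"].max() == 0.0
        assert (table["delta_qaicc"] >= 0).all()

    def test_invalid_chat_raises(self):
        with pytest.raises(ValueError):
            sv.qaicc(-10.0, 2, 100, 0.9)

    def test_strong_effect_favours_complex_model(self):
        # simulated strong covariate effect: the pairwise contrast
        # (simpler - complex) should be clearly positive
        cfg = syn.SyntheticConfig(seed=53, years=tuple(range(2002, 2012)),
                                  n_individuals=1500)
        cfg.cjs.formula = "tsm + log_rt"
        cfg.cjs.beta = {"phi_intercept": -5.5, "phi_tsm": -0.5, "phi_log_rt": 2.5}
        annual = syn.annual_truth(cfg)
        hist = sv.CaptureHistories.from_frame(syn.gen_histories(cfg, annual))
        cov = syn.cjs_covariates(cfg, annual)
        simple = sv.fit_cjs(hist, "tsm", cov, n_starts=1)
        complex_ = sv.fit_cjs(hist, "tsm + log_rt", cov, n_starts=1)
        assert sv.qaicc_contrast(simple, complex_) > 2.0


class TestFormula:
    def test_star_expansion(self):
        terms = sv.parse_formula("tsm + sex + log_rt*sex + log_alpha")
        assert ("tsm",) in terms and ("log_alpha",) in terms
        assert tuple(sorted(("log_rt", "sex"))) in terms

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sv.parse_formula("tsm + wingspan")
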