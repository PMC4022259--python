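"""Nonlinear fitting, the log-log alternative, GOF criteria and ranking."""

import numpy as np
import pytest

from dissolvekit import (
    KineticCurveFit,
    fit_kp_linearized,
    fit_model,
    goodness_of_fit,
    predict_kp,
    rank_models,
)
from dissolvekit.model_fitting import check_plausibility
from dissolvekit.release_models import get_model

TIMES = np.array([5.0, 10, 20, 30, 45, 60])


class TestFitModel:
    def test_noise_free_power_law_recovered_exactly(self):
        y = predict_kp(TIMES, 5.0, 0.43)
        res = fit_model("korsmeyer_peppas", TIMES, y, seed=0)
        assert res.params["k"] == pytest.approx(5.0, abs=1e-4)
        assert res.params["n"] == pytest.approx(0.43, abs=1e-4)
        assert res.ss_res < 1e-8 and res.converged

    def test_burst_model_recovers_and_beats_nested_plain_fit(self):
        y = predict_kp(TIMES, 5.0, 0.43) + 10.0
        res_f0 = fit_model("kp_f0", TIMES, y, seed=0)
        res_kp = fit_model("korsmeyer_peppas", TIMES, y, seed=0)
        assert res_f0.ss_res < 1e-8
        assert res_f0.params["f0"] == pytest.approx(10.0, abs=1e-3)
        assert res_kp.ss_res > res_f0.ss_res

    def test_constant_observations_fit_without_crash(self):
        y = np.full(6, 42.0)
        res = fit_model("korsmeyer_peppas", TIMES, y, seed=0)
        assert res.ss_res >= 0 and np.isnan(res.r2)
        assert "undefined" in " ".join(res.gof_flags)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(9)
        y = predict_kp(TIMES, 5.0, 0.43) + rng.normal(0, 1, 6)
        a = fit_model("kp_tlag", TIMES, y, seed=123)
        b = fit_model("kp_tlag", TIMES, y, seed=123)
        assert a.params == b.params and a.ss_res == b.ss_res

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="identify"):
            fit_model("kp_f0", TIMES[:3], np.array([5.0, 10, 20]), seed=0)

    def test_nested_dominance_on_noisy_data(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            y = predict_kp(TIMES, 5.0, 0.43) + rng.normal(0, 1.5, 6)
            ss_kp = fit_model("korsmeyer_peppas", TIMES, y, seed=4).ss_res
            assert fit_model("kp_f0", TIMES, y, seed=4).ss_res <= ss_kp + 1e-6
            assert fit_model("kp_tlag", TIMES, y, seed=4).ss_res <= ss_kp + 1e-6


class TestEstimatorInterface:
    def test_sklearn_params_and_predict(self):
        est = KineticCurveFit(model="higuchi", random_state=7)
        assert est.get_params()["model"] == "higuchi"
        y = 8.0 * np.sqrt(TIMES)
        est.fit(TIMES, y)
        assert est.params_[0] == pytest.approx(8.0, abs=1e-6)
        assert np.allclose(est.predict(TIMES), y, atol=1e-5)
        # column-vector input, as sklearn pipelines would pass it
        est2 = KineticCurveFit(model="higuchi").fit(TIMES.reshape(-1, 1), y)
        assert est2.params_[0] == pytest.approx(8.0, abs=1e-6)

    def test_sample_weight_hook(self):
        """Zero weight on a corrupted point recovers the clean parameters."""
        y = predict_kp(TIMES, 5.0, 0.43)
        y_bad = y.copy()
        y_bad[-1] += 8.0
        w = np.ones_like(y)
        w[-1] = 0.0
        plain = KineticCurveFit(random_state=0).fit(TIMES, y_bad)
        weighted = KineticCurveFit(random_state=0).fit(TIMES, y_bad, sample_weight=w)
        assert abs(weighted.params_[1] - 0.43) < 1e-4
        assert abs(plain.params_[1] - 0.43) > 1e-3

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            KineticCurveFit().predict(TIMES)

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = KineticCurveFit(model="kp_f0", n_restarts=4, random_state=3)
        c = clone(est)
        assert c.get_params() == est.get_params()


class TestLinearized:
    def test_noise_free_matches_nonlinear(self):
        y = predict_kp(TIMES, 5.0, 0.43)
        k_lin, n_lin, r2 = fit_kp_linearized(TIMES, y)
        res = fit_model("korsmeyer_peppas", TIMES, y, seed=0)
        assert k_lin == pytest.approx(res.params["k"], abs=1e-6)
        assert n_lin == pytest.approx(res.params["n"], abs=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        k, n, r2 = fit_kp_linearized(np.array([10.0, 40.0]), np.array([20.0, 50.0]))
        assert r2 == pytest.approx(1.0)
        assert k * 10**n == pytest.approx(20.0, rel=1e-9)

    def test_noisy_data_gives_seed_stable_systematic_gap(self):
        """The log transform distorts additive errors, so the linearized
        exponent differs reproducibly from the nonlinear one."""
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.clip(predict_kp(TIMES, 5.0, 0.43) + rng.normal(0, 2.0, 6), 0.5, None)
            _, n_lin, _ = fit_kp_linearized(TIMES, y)
            n_nm = fit_model("korsmeyer_peppas", TIMES, y, seed=0).params["n"]
            gaps.append(n_lin - n_nm)
        assert np.any(np.abs(gaps) > 1e-3)
        again = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.clip(predict_kp(TIMES, 5.0, 0.43) + rng.normal(0, 2.0, 6), 0.5, None)
            _, n_lin, _ = fit_kp_linearized(TIMES, y)
            n_nm = fit_model("korsmeyer_peppas", TIMES, y, seed=0).params["n"]
            again.append(n_lin - n_nm)
        assert np.allclose(gaps, again)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_kp_linearized(np.array([10.0, 20]), np.array([0.0, 5]))


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([10.0, 20, 35, 50])
        g = goodness_of_fit(y, y, 2)
        assert g.r2 == 1.0 and g.r2_adj == 1.0
        assert g.aic == float("-inf") and g.msc == float("inf")

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([10.0, 20, 35, 50])
        g = goodness_of_fit(y, np.full(4, y.mean()), 1)
        assert g.r2 == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_never_exceeds_plain_r2(self):
        rng = np.random.default_rng(2)
        y = np.linspace(5, 80, 8) + rng.normal(0, 3, 8)
        pred = np.linspace(5, 80, 8)
        g = goodness_of_fit(y, pred, 3)
        assert g.r2_adj <= g.r2

    def test_msc_is_affine_in_aic_over_n(self):
        rng = np.random.default_rng(4)
        y = np.linspace(5, 80, 7) + rng.normal(0, 2, 7)
        for p in (1, 2, 3):
            pred = y + rng.normal(0, 1, 7)
            g = goodness_of_fit(y, pred, p)
            assert g.msc == pytest.approx(np.log(g.ss_tot) - g.aic / 7, abs=1e-10)

    def test_constant_observations_flagged(self):
        g = goodness_of_fit(np.full(5, 30.0), np.linspace(28, 32, 5), 1)
        assert np.isnan(g.r2) and g.flags


class TestRanking:
    def fits_on(self, y, models=("korsmeyer_peppas", "kp_tlag", "kp_f0"), seed=0):
        return [fit_model(m, TIMES, y, seed=seed) for m in models]

    def test_implausible_best_fit_demoted(self):
        """A fit with a grossly negative burst is demoted even when its
        criterion value beats every plausible competitor."""
        y = predict_kp(TIMES, 5.0, 0.43)
        fits = self.fits_on(y)
        f0_fit = next(f for f in fits if f.model == "kp_f0")
        f0_fit.params["f0"] = -199.0
        f0_fit.plausible = False
        f0_fit.plausibility_notes = ("F0 = -199 outside [0, 100)",)
        f0_fit.r2_adj = 0.9999
        ranked = rank_models(fits, criterion="r2_adj")
        assert ranked[-1].model == "kp_f0"
        assert all(f.plausible for f in ranked[:-1])

    def test_single_fit_trivially_first(self):
        y = predict_kp(TIMES, 5.0, 0.43)
        fits = self.fits_on(y, models=("korsmeyer_peppas",))
        assert rank_models(fits)[0].model == "korsmeyer_peppas"

    def test_aic_and_msc_orderings_coincide(self):
        rng = np.random.default_rng(8)
        y = predict_kp(TIMES, 5.0, 0.43) + rng.normal(0, 1, 6)
        fits = self.fits_on(y)
        by_aic = [f.model for f in rank_models(fits, criterion="aic")]
        by_msc = [f.model for f in rank_models(fits, criterion="msc")]
        assert by_aic == by_msc

    def test_differing_data_rejected(self):
        y1 = predict_kp(TIMES, 5.0, 0.43)
        y2 = y1 + 1.0
        f1 = fit_model("korsmeyer_peppas", TIMES, y1, seed=0)
        f2 = fit_model("korsmeyer_peppas", TIMES, y2, seed=0)
        with pytest.raises(ValueError, match="identical"):
            rank_models([f1, f2])


class TestPlausibility:
    def test_rule_catalogue(self):
        spec = get_model("kp_f0")
        ok, notes = check_plausibility(spec, [5.0, 0.4, 10.0], TIMES)
        assert ok and not notes
        bad, notes = check_plausibility(spec, [5.0, 0.4, -199.0], TIMES)
        assert not bad and "F0" in notes[0]
        spec_tl = get_model("kp_tlag")
        bad, notes = check_plausibility(spec_tl, [5.0, 0.4, 80.0], TIMES)
        assert not bad and "T_lag" in notes[0]
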