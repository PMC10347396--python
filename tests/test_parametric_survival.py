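"""Censored MLE, information-criterion selection and curve contracts."""

import numpy as np
import pandas as pd
import pytest
from lifelines import WeibullFitter

import psmcea
from psmcea import (ArmSpec, FitResult, HybridCurve, KMCurve, ParametricCurve,
                    fit_all, fit_mle, km_estimate, log_likelihood,
                    median_survival, select_best, simulate_arm, survival_at)
from psmcea.distributions import FAMILIES, InvalidParameterError, n_params


class TestLogLikelihood:
    def test_exponential_closed_form(self):
        # d events, total time T: l = d ln(rate) - rate * T
        ipd = pd.DataFrame({"time": [5, 5, 10, 10, 5, 5, 5, 2.5, 2.5],
                            "event": [1, 1, 1, 1, 1, 1, 1, 0, 0]})
        assert ipd["time"].sum() == 50 and ipd["event"].sum() == 7
        ll = log_likelihood("exponential", (0.14,), ipd)
        assert ll == pytest.approx(7 * np.log(0.14) - 7, abs=1e-12)

    def test_single_censored_record_is_log_survival(self):
        ipd = pd.DataFrame({"time": [10.0], "event": [0]})
        assert log_likelihood("exponential", (0.1,), ipd) == pytest.approx(-1.0)

    def test_weibull_shape_one_equals_exponential(self):
        rng = np.random.default_rng(1)
        ipd = pd.DataFrame({"time": rng.exponential(8, 30),
                            "event": rng.integers(0, 2, 30)})
        a = log_likelihood("weibull", (1.0, 12.5), ipd)
        b = log_likelihood("exponential", (1 / 12.5,), ipd)
        assert a == pytest.approx(b, abs=1e-10)

    def test_wrong_length_raises(self):
        ipd = pd.DataFrame({"time": [1.0], "event": [1]})
        with pytest.raises(InvalidParameterError):
            log_likelihood("weibull", (1.0,), ipd)


class TestFitMLE:
    def test_exponential_rate_is_events_over_time(self):
        ipd = pd.DataFrame({"time": [5, 5, 10, 10, 5, 5, 5, 2.5, 2.5],
                            "event": [1, 1, 1, 1, 1, 1, 1, 0, 0]})
        fit = fit_mle("exponential", ipd)
        assert fit.params[0] == 7 / 50  # exact closed-form MLE
        assert fit.converged

    def test_weibull_parameter_recovery(self, weibull_ipd):
        fit = fit_mle("weibull", weibull_ipd)
        rel = np.abs(np.array(fit.params) - np.array([1.4, 20.0])) / [1.4, 20.0]
        assert fit.converged and np.all(rel < 0.05)

    def test_agrees_with_lifelines_weibull(self, weibull_ipd):
        """Independent censored-MLE oracle on the same data."""
        sub = weibull_ipd.iloc[:800]
        lf = WeibullFitter().fit(sub["time"], sub["event"])
        ours = fit_mle("weibull", sub)
        assert ours.params[0] == pytest.approx(lf.rho_, rel=1e-4)
        assert ours.params[1] == pytest.approx(lf.lambda_, rel=1e-4)

    def test_aic_bic_formula_identities(self, weibull_ipd):
        sub = weibull_ipd.iloc[:400]
        for fit in fit_all(sub):
            k = n_params(fit.family)
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-9)
            assert fit.bic == pytest.approx(k * np.log(fit.n) - 2 * fit.loglik, abs=1e-9)
            assert fit.aic - fit.bic == pytest.approx(2 * k - k * np.log(fit.n), abs=1e-9)

    def test_all_events_censored_reports_nonconvergence(self):
        ipd = pd.DataFrame({"time": [3.0, 4.0], "event": [0, 0]})
        fit = fit_mle("exponential", ipd)
        assert not fit.converged


# printed AIC columns of the published fit-comparison table, family order:
# exponential, gamma, gen gamma, gompertz, weibull, loglogistic, lognormal
TABLE1_AIC = {
    "hr_tdxd_os": [1149.75, 1124.76, 1122.53, 1121.52, 1121.87, 1125.70, 1143.33],
    "hr_tdxd_pfs": [1493.30, 1479.33, 1477.94, 1489.99, 1481.73, 1478.45, 1478.04],
    "hr_chemo_os": [647.67, 636.17, 637.56, 638.57, 635.57, 636.57, 645.34],
    "hr_chemo_pfs": [618.79, 613.11, 601.61, 620.56, 615.93, 606.70, 601.35],
    "all_tdxd_os": [1313.07, 1276.44, 1278.18, 1284.91, 1276.28, 1276.86, 1284.34],
    "all_tdxd_pfs": [1755.62, 1742.46, 1742.19, 1751.28, 1744.41, 1745.00, 1744.78],
    "all_chemo_os": [730.71, 709.42, 711.28, 719.06, 710.68, 708.48, 712.74],
    "all_chemo_pfs": [725.48, 717.89, 703.71, 727.20, 721.55, 709.49, 703.39],
}
_ORDER = ["exponential", "gamma", "generalized_gamma", "gompertz",
          "weibull", "loglogistic", "lognormal"]


def _fits_from_aic(aics, n=300):
    out = []
    for fam, aic in zip(_ORDER, aics):
        k = n_params(fam)
        ll = (2 * k - aic) / 2
        out.append(FitResult.from_fit(fam, (1.0,) * k, ll, n, True))
    return out


class TestSelectBest:
    @pytest.mark.parametrize("endpoint,winner", [
        ("all_chemo_os", "loglogistic"),
        ("hr_chemo_pfs", "lognormal"),
        ("all_chemo_pfs", "lognormal"),
        ("hr_tdxd_pfs", "generalized_gamma"),
        ("hr_chemo_os", "weibull"),
        ("all_tdxd_os", "weibull"),
    ])
    def test_published_aic_columns_pick_reported_family(self, endpoint, winner):
        fits = _fits_from_aic(TABLE1_AIC[endpoint])
        assert select_best(fits, "aic") == winner

    def test_tie_breaks_toward_fewer_parameters(self):
        a = FitResult.from_fit("exponential", (0.1,), -50.0, 100, True)
        b = FitResult.from_fit("weibull", (1.0, 10.0), -49.0, 100, True)  # same AIC
        assert a.aic == b.aic
        assert select_best([b, a]) == "exponential"

    def test_unconverged_fits_excluded(self):
        good = FitResult.from_fit("weibull", (1.0, 10.0), -60.0, 100, True)
        bad = FitResult.from_fit("exponential", (0.1,), -10.0, 100, False)
        assert select_best([bad, good]) == "weibull"
        with pytest.raises(ValueError):
            select_best([bad])


class TestSurvivalCurves:
    def test_all_curves_start_at_one(self):
        curves = [ParametricCurve("gompertz", (0.05, 0.03)),
                  KMCurve(km_estimate(pd.DataFrame(
                      {"time": [1, 2, 3], "event": [1, 1, 0]}))[0])]
        for c in curves:
            assert survival_at(c, 0.0) == 1.0

    def test_exponential_median_property(self):
        # rate set from the published 23.4-month median
        curve = ParametricCurve("exponential", (np.log(2) / 23.4,))
        assert survival_at(curve, 23.4) == pytest.approx(0.5, abs=1e-12)

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            survival_at(ParametricCurve("exponential", (0.1,)), -1.0)

    def test_hybrid_continuity_at_splice(self):
        ipd = simulate_arm(ArmSpec("h", "weibull", (1.3, 15.0), 60, 0.02, 20.0), 2)
        km, _ = km_estimate(ipd)
        hybrid = HybridCurve(km=km, tail=ParametricCurve("weibull", (1.1, 18.0)))
        tm = hybrid.t_max
        left = float(survival_at(hybrid, tm))
        right = float(survival_at(hybrid, tm + 1e-9))
        assert abs(left - right) < 1e-6
        # the scaled tail is exactly continuous in the limit
        assert hybrid.continuity_scale * hybrid.tail.survival(np.array([tm]))[0] \
            == pytest.approx(km.evaluate(np.array([tm]))[0], abs=1e-12)

    def test_hybrid_monotone_through_splice(self):
        ipd = simulate_arm(ArmSpec("h", "weibull", (1.3, 15.0), 60, 0.02, 20.0), 2)
        km, _ = km_estimate(ipd)
        hybrid = HybridCurve(km=km, tail=ParametricCurve("weibull", (1.1, 18.0)))
        grid = np.linspace(0, 60, 601)
        s = survival_at(hybrid, grid)
        assert np.all(np.diff(s) <= 1e-12)


class TestMedianSurvival:
    def test_exponential_closed_form(self):
        curve = ParametricCurve("exponential", (0.05,))
        assert median_survival(curve) == pytest.approx(np.log(2) / 0.05, abs=1e-5)

    def test_weibull_closed_form(self):
        curve = ParametricCurve("weibull", (2.0, 10.0))
        assert median_survival(curve) == pytest.approx(10 * np.log(2) ** 0.5, abs=1e-5)

    def test_fitted_median_recovers_generating_target(self):
        """Fit a synthetic chemotherapy-PFS arm generated with a 5.1-month
        median; the fitted curve's median lands within 10% at n=300."""
        shape = 1.1
        scale = 5.1 / np.log(2) ** (1 / shape)
        ipd = simulate_arm(ArmSpec("pfs", "weibull", (shape, scale), 300, 0.01, 30.0), 77)
        fit = fit_mle("weibull", ipd)
        med = median_survival(ParametricCurve.from_fit(fit))
        assert med == pytest.approx(5.1, rel=0.10)

    def test_never_reaching_half_raises(self):
        km = psmcea.KMPoints(np.array([0.0, 10.0]), np.array([1.0, 0.9]))
        with pytest.raises(ValueError):
            median_survival(KMCurve(km), horizon=100.0)


@pytest.mark.parametrize("family", sorted(FAMILIES))
def test_parameter_recovery_with_censoring(family):
    """Each family refits its own simulated data (n=5,000, ~20% censoring)
    within 10% relative error on every parameter."""
    true = {"exponential": (0.05,), "weibull": (1.4, 20.0), "gamma": (2.0, 10.0),
            "gompertz": (0.08, 0.02), "loglogistic": (1.8, 12.0),
            "lognormal": (2.5, 0.8), "generalized_gamma": (2.8, 0.7, 0.5)}[family]
    ipd = simulate_arm(ArmSpec("pr", family, true, 5000, 0.012, 200.0), 123)
    censored_frac = 1 - ipd["event"].mean()
    assert 0.1 < censored_frac < 0.3
    fit = fit_mle(family, ipd)
    rel = np.abs(np.array(fit.params) - np.array(true)) / np.abs(true)
    assert fit.converged and np.all(rel < 0.10)
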