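"""Survival-machinery tests.

The Aalen fit is checked against closed-form Nelson-Aalen identities and
against cumulative coefficients computed independently with R's
survival::aareg on a frozen fixture; the Cox fit is cross-checked against
lifelines (an independent implementation of the same partial likelihood).
"""

import numpy as np
import pandas as pd
import pytest

from mrhaz.survival import (
    SurvivalError,
    fit_additive_hazard,
    fit_cox,
    kaplan_meier,
    likelihood_ratio_test,
)


def _design(**cols):
    return pd.DataFrame(cols)


class TestAdditiveHazard:
    def test_intercept_only_is_nelson_aalen_on_tiny_toy(self):
        fit = fit_additive_hazard([1.0, 2.0, 3.0], [1, 1, 1],
                                  _design(intercept=[1.0, 1.0, 1.0]))
        np.testing.assert_allclose(
            fit.cum_coef["intercept"], [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1]
        )

    def test_intercept_only_is_nelson_aalen_with_censoring(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(5.0, 20).round(2) + 0.1
        d = rng.binomial(1, 0.7, 20)
        d[t.argmax()] = 1  # ensure at least one late event
        fit = fit_additive_hazard(t, d, _design(intercept=np.ones(20)))
        # hand Nelson-Aalen: sum over event times of d_k / n_at_risk
        expected = []
        total = 0.0
        for et in np.unique(t[d == 1]):
            total += ((t == et) & (d == 1)).sum() / (t >= et).sum()
            expected.append(total)
        np.testing.assert_allclose(fit.cum_coef["intercept"], expected)

    def test_binary_covariate_reproduces_groupwise_nelson_aalen(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(1, 0.5, 40).astype(float)
        t = rng.exponential(1.0 + 2.0 * g)
        d = np.ones(40, dtype=int)
        fit = fit_additive_hazard(t, d, _design(intercept=np.ones(40), group=g))

        def na(times):
            out, tot = {}, 0.0
            for et in np.sort(times):
                tot += 1.0 / (times >= et).sum()
                out[et] = tot
            return out

        na0, na1 = na(t[g == 0]), na(t[g == 1])
        # the two-column fit reproduces both groups' estimators exactly,
        # up to the time both groups remain at risk
        tau_joint = min(t[g == 0].max(), t[g == 1].max())
        for et in fit.times:
            if et > tau_joint:
                break
            b0 = fit.cum_coef.loc[et, "intercept"]
            b1 = b0 + fit.cum_coef.loc[et, "group"]
            exp0 = max((v for k, v in na0.items() if k <= et), default=0.0)
            exp1 = max((v for k, v in na1.items() if k <= et), default=0.0)
            np.testing.assert_allclose(b0, exp0, atol=1e-10)
            np.testing.assert_allclose(b1, exp1, atol=1e-10)

    def test_matches_r_aareg_on_frozen_fixture(self):
        time = [1.84, 11.02, 32.47, 5.01, 2.77, 3.68, 3.39, 1.54, 9.17, 11.51,
                12.56, 42.98, 17.35, 13.66, 8.85, 5.24, 0.86, 8.15, 5.47, 12.56,
                16.72, 3.16, 0.9, 7.9, 20.93]
        event = [1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
                 1, 1, 0, 0, 1]
        x1 = [1, 0, 1, 1, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 0, 1, 0, 1, 1, 1,
              0, 1, 1, 1]
        x2 = [-0.352, 0.532, 0.365, 0.413, 0.431, 2.142, -0.406, -0.512,
              -0.814, 0.616, 1.129, -0.114, -0.84, -0.824, 0.651, 0.743,
              0.543, -0.666, 0.232, 0.117, 0.219, 0.871, 0.224, 0.679, 0.068]
        fit = fit_additive_hazard(
            time, event,
            _design(intercept=np.ones(25), x1=np.array(x1, float),
                    x2=np.array(x2)),
        )
        # cumulative coefficients from survival::aareg (nmin=1), frozen
        np.testing.assert_allclose(
            fit.cum_coef.loc[8.85].to_numpy(),
            [0.73192128531, -0.23982383117, -0.0099232650043], rtol=1e-8,
        )
        np.testing.assert_allclose(
            fit.cum_coef.loc[11.51].to_numpy(),
            [2.18308324384, -1.78240555801, -0.6441535704795], rtol=1e-8,
        )

    def test_constant_extra_covariate_fails_at_first_event(self):
        with pytest.raises(SurvivalError, match="rank"):
            fit_additive_hazard(
                [1, 2, 3, 4], [1, 1, 1, 1],
                _design(intercept=np.ones(4), dup=np.ones(4)),
            )

    def test_zero_events_fail(self):
        with pytest.raises(SurvivalError, match="no events"):
            fit_additive_hazard([1, 2], [0, 0], _design(intercept=np.ones(2)))

    def test_constant_slope_recovered(self):
        rng = np.random.default_rng(13)
        n = 1000
        x = rng.uniform(-1, 1, n)  # bounded, so the hazard stays positive
        lam = 0.1 + 0.05 * x
        t = rng.exponential(1 / lam)
        fit = fit_additive_hazard(
            t, np.ones(n, int), _design(intercept=np.ones(n), x=x)
        )
        assert 0.02 <= fit.coefficient_slope("x") <= 0.08

    def test_variance_curves_non_negative_and_monotone(self):
        rng = np.random.default_rng(14)
        n = 200
        x = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        d = rng.binomial(1, 0.8, n)
        d[t.argmax()] = 1
        fit = fit_additive_hazard(t, d, _design(intercept=np.ones(n), x=x))
        v = fit.cum_var.to_numpy()
        assert (v >= 0).all()
        assert (np.diff(v, axis=0) >= -1e-15).all()

    def test_endpoint_policy_reaches_last_estimable_time(self):
        rng = np.random.default_rng(15)
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        stable = fit_additive_hazard(t, np.ones(n, int),
                                     _design(intercept=np.ones(n), x=x))
        endpoint = fit_additive_hazard(t, np.ones(n, int),
                                       _design(intercept=np.ones(n), x=x),
                                       test_time="endpoint")
        assert endpoint.test_tau == endpoint.tau
        assert stable.test_tau <= endpoint.test_tau

    def test_supremum_test_reports_probabilities(self):
        rng = np.random.default_rng(16)
        n = 150
        x = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        fit = fit_additive_hazard(t, np.ones(n, int),
                                  _design(intercept=np.ones(n), x=x),
                                  sup_test=True)
        assert ((fit.sup_p >= 0) & (fit.sup_p <= 1)).all()
        endpoint = fit_additive_hazard(t, np.ones(n, int),
                                       _design(intercept=np.ones(n), x=x),
                                       test_time="endpoint")
        # the supremum dominates the endpoint statistic on the same SE scale
        assert (fit.sup_z >= endpoint.z.abs() - 1e-12).all()
        assert fit.sup_p["intercept"] < 1e-6  # baseline hazard is real


class TestCox:
    @staticmethod
    def _sim(n=600, ties=False, seed=20):
        rng = np.random.default_rng(seed)
        X = _design(x1=rng.standard_normal(n),
                    x2=rng.binomial(1, 0.4, n).astype(float))
        lam = 0.1 * np.exp(0.5 * X["x1"] - 0.3 * X["x2"])
        T = rng.exponential(1 / lam)
        C = rng.uniform(0, np.quantile(T, 0.9), n)
        t = np.minimum(T, C)
        d = (T <= C).astype(int)
        if ties:
            t = np.round(t, 0) + 0.5
        return t, d, X

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_lifelines(self, ties):
        from lifelines import CoxPHFitter

        t, d, X = self._sim(ties=ties)
        fit = fit_cox(t, d, X)
        df = X.copy()
        df["_t"], df["_e"] = t, d
        ref = CoxPHFitter().fit(df, "_t", "_e")
        np.testing.assert_allclose(fit.coef, ref.params_, atol=2e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_, atol=2e-5)
        np.testing.assert_allclose(fit.log_likelihood, ref.log_likelihood_,
                                   rtol=1e-8)
        np.testing.assert_allclose(fit.log_likelihood_null, ref._ll_null_,
                                   rtol=1e-8)

    def test_two_group_hazard_ratio_two(self):
        rng = np.random.default_rng(21)
        n = 2000
        g = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.1 * 2**g))
        fit = fit_cox(t, np.ones(n, int), _design(group=g))
        assert np.log(1.7) <= fit.coef["group"] <= np.log(2.35)

    def test_fitted_likelihood_beats_null(self):
        t, d, X = self._sim()
        fit = fit_cox(t, d, X)
        assert fit.log_likelihood >= fit.log_likelihood_null

    def test_single_subject_fails(self):
        with pytest.raises(SurvivalError):
            fit_cox([1.0], [1], _design(x=[1.0]))

    def test_separation_detected_and_named(self):
        # covariate perfectly orders the survival times -> monotone likelihood
        n = 40
        x = np.arange(n, dtype=float)
        t = np.exp(-x / 4) + 0.01
        with pytest.raises(SurvivalError, match="x"):
            fit_cox(t, np.ones(n, int), _design(x=x))

    def test_constant_column_named(self):
        with pytest.raises(SurvivalError, match="const"):
            fit_cox([1, 2, 3], [1, 1, 1], _design(const=np.ones(3)))


class TestLrt:
    def test_identical_models_give_zero(self):
        t, d, X = TestCox._sim(n=200)
        fit = fit_cox(t, d, X)
        chi2, df, p = likelihood_ratio_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_df_counts_added_biomarkers(self):
        rng = np.random.default_rng(22)
        t, d, X = TestCox._sim(n=300)
        bio = pd.DataFrame(rng.standard_normal((300, 3)),
                           columns=["b1", "b2", "b3"], index=X.index)
        full = fit_cox(t, d, pd.concat([X, bio], axis=1))
        reduced = fit_cox(t, d, X)
        chi2, df, p = likelihood_ratio_test(full, reduced)
        assert df == 3 and chi2 >= 0.0 and 0 <= p <= 1

    def test_non_nested_rejected(self):
        t, d, X = TestCox._sim(n=200)
        f1 = fit_cox(t, d, X[["x1"]])
        f2 = fit_cox(t, d, X[["x2"]])
        with pytest.raises(SurvivalError):
            likelihood_ratio_test(f1, f2)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        km = kaplan_meier(t, np.ones(5, int), np.zeros(5, int))
        curve = km.curves["0"].set_index("time")["survival"]
        np.testing.assert_allclose(curve.loc[[1, 2, 3, 4, 5]],
                                   [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_all_censored_flat_with_undefined_median(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0], ["a", "a", "a"])
        assert (km.curves["a"]["survival"] == 1.0).all()
        assert np.isnan(km.medians["a"])

    def test_exponential_median(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(10.0, 2000)
        km = kaplan_meier(t, np.ones(2000, int), np.zeros(2000, int))
        assert 6.0 <= km.medians["0"] <= 7.9
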