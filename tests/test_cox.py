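"""Cox baselines: partial likelihood, LASSO, CVPL and backward elimination."""

import numpy as np
import pandas as pd
import pytest

from plannsurv import (
    GeneratorSpec,
    SurvivalDataset,
    backward_eliminate,
    cvpl,
    fit_cox,
    fit_cox_lasso,
    generate,
    lasso_lambda_max,
    log_partial_likelihood,
    predict_cox_survival,
    select_lambda,
)
from plannsurv.cox import _stratified_folds


def _toy_binary():
    """8 subjects, one binary covariate, no tied times."""
    return SurvivalDataset(
        time=np.array([1.0, 2, 3, 4, 5, 6, 7, 8]),
        event=np.array([1, 1, 0, 1, 1, 0, 1, 1]),
        covariates=pd.DataFrame({"x": [1.0, 0, 1, 1, 0, 0, 1, 0]}),
    )


def _brute_breslow_ll(time, event, X, beta):
    """Direct evaluation of the Breslow partial likelihood by looping
    over the event terms."""
    X = np.atleast_2d(np.asarray(X, float).T).T
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            eta = X @ beta
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


class TestFitCox:
    def test_null_loglik_matches_direct_evaluation(self, toy_dataset):
        fit = fit_cox(toy_dataset)
        expected = _brute_breslow_ll(
            toy_dataset.time, toy_dataset.event,
            toy_dataset.covariates.to_numpy() - toy_dataset.covariates.to_numpy().mean(0),
            np.zeros(2),
        )
        assert fit.loglik_null == pytest.approx(expected)

    def test_single_covariate_matches_grid_search(self):
        """Beta maximising the partial likelihood, against an exhaustive
        1-D optimisation frozen from an independent script."""
        fit = fit_cox(_toy_binary())
        assert fit.beta["x"] == pytest.approx(0.7751564179174769, abs=1e-6)
        assert fit.loglik == pytest.approx(-7.3581146440565135, abs=1e-8)

    def test_parameter_recovery_within_3se(self):
        spec = GeneratorSpec(n=2000, p_binary=1, p_continuous=1,
                             beta=(0.5, -0.3), seed=21)
        fit = fit_cox(generate(spec))
        for name, truth in zip(fit.beta.index, spec.beta):
            assert abs(fit.beta[name] - truth) < 3 * fit.se[name]

    def test_agrees_with_lifelines(self, medium_cohort):
        from lifelines import CoxPHFitter
        # no tied event times in the continuous-time generator (ties occur
        # only among administratively censored subjects), so Efron == Breslow
        ev_times = medium_cohort.time[medium_cohort.event == 1]
        assert len(np.unique(ev_times)) == len(ev_times)
        fit = fit_cox(medium_cohort)
        cph = CoxPHFitter()
        df = medium_cohort.to_frame().drop(columns="id")
        cph.fit(df, duration_col="time", event_col="event")
        np.testing.assert_allclose(fit.beta.to_numpy(),
                                   cph.params_[fit.beta.index].to_numpy(), rtol=1e-4)
        np.testing.assert_allclose(fit.se.to_numpy(),
                                   cph.standard_errors_[fit.beta.index].to_numpy(), rtol=1e-3)

    def test_score_vanishes_at_optimum(self, medium_cohort):
        fit = fit_cox(medium_cohort)
        beta = fit.beta.to_numpy()
        eps = 1e-5
        for j in range(len(beta)):
            up, dn = beta.copy(), beta.copy()
            up[j] += eps
            dn[j] -= eps
            g = (log_partial_likelihood(medium_cohort, up)
                 - log_partial_likelihood(medium_cohort, dn)) / (2 * eps)
            assert abs(g) < 1e-3  # score ~ 0 at the maximum

    def test_zero_events_error(self):
        data = SurvivalDataset(time=np.array([1.0, 2.0]), event=np.array([0, 0]),
                               covariates=pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="no events"):
            fit_cox(data)


class TestPredictSurvival:
    def test_null_beta_matches_nelson_aalen(self, medium_cohort):
        from lifelines import NelsonAalenFitter
        data = medium_cohort.subset(np.arange(300))
        # a p=0 fit is the null model: its baseline is the Nelson-Aalen estimate
        null = fit_cox(
            SurvivalDataset(time=data.time, event=data.event,
                            covariates=pd.DataFrame(index=range(data.n)))
        )
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(data.time, event_observed=data.event)
        times = np.array([1.0, 3.0, 5.0, 8.0])
        expected = np.exp(-naf.cumulative_hazard_at_times(times).to_numpy())
        surv = predict_cox_survival(null, np.zeros((1, 0)), times)
        np.testing.assert_allclose(surv[0], expected, rtol=1e-10)

    def test_doubling_risk_squares_survival(self):
        data = _toy_binary()
        fit = fit_cox(data)
        x1 = np.array([[0.0]])
        x2 = x1 + np.log(2) / fit.beta["x"]  # PI shift of exactly log 2
        times = np.array([2.0, 5.0, 7.0])
        s1 = predict_cox_survival(fit, x1, times)[0]
        s2 = predict_cox_survival(fit, x2, times)[0]
        np.testing.assert_allclose(s2, s1 ** 2, rtol=1e-10)

    def test_single_event_breslow_increment(self):
        data = SurvivalDataset(
            time=np.array([1.0, 2.0, 3.0]), event=np.array([1, 0, 0]),
            covariates=pd.DataFrame({"x": [0.5, -0.5, 0.0]}),
        )
        fit = fit_cox(data)
        pi = fit.prognostic_index(data.covariates)
        expected_h0 = 1.0 / np.exp(pi).sum()  # every subject at risk at t=1
        assert fit.baseline_cumhaz[0] == pytest.approx(expected_h0)
        assert fit.baseline_times[0] == 1.0

    def test_monotone_and_carries_last_value(self, medium_cohort):
        fit = fit_cox(medium_cohort.subset(np.arange(200)))
        times = np.array([1.0, 2.0, 5.0, 9.0, 50.0])
        surv = predict_cox_survival(fit, medium_cohort.covariates.iloc[:5], times)
        assert np.all(np.diff(surv, axis=1) <= 1e-15)
        assert np.allclose(surv[:, -1], surv[:, -2])  # beyond last event time


class TestLasso:
    def test_full_shrinkage_at_lambda_max(self, medium_cohort):
        data = medium_cohort.subset(np.arange(500))
        lam_max = lasso_lambda_max(data)
        fit = fit_cox_lasso(data, lam_max * 1.001)
        assert np.all(fit.beta.to_numpy() == 0)
        assert fit.active_set == []

    def test_lambda_zero_matches_unpenalized(self, medium_cohort):
        data = medium_cohort.subset(np.arange(500))
        lasso = fit_cox_lasso(data, 0.0)
        plain = fit_cox(data)
        np.testing.assert_allclose(lasso.beta.to_numpy(), plain.beta.to_numpy(), atol=1e-4)

    def test_kkt_conditions(self, medium_cohort):
        """Stationarity of -loglik + lambda*||beta||_1 on the standardized
        scale, with the score computed by numerical differentiation."""
        data = medium_cohort.subset(np.arange(500))
        lam = lasso_lambda_max(data) * 0.3
        fit = fit_cox_lasso(data, lam)
        X = data.covariates.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        sdata = SurvivalDataset(time=data.time, event=data.event,
                                covariates=pd.DataFrame(Xs, columns=data.covariate_names))
        beta_std = fit.beta.to_numpy() * X.std(0)
        eps = 1e-5
        for j, bj in enumerate(beta_std):
            up, dn = beta_std.copy(), beta_std.copy()
            up[j] += eps
            dn[j] -= eps
            g = (log_partial_likelihood(sdata, up)
                 - log_partial_likelihood(sdata, dn)) / (2 * eps)
            if bj != 0:
                assert g == pytest.approx(lam * np.sign(bj), abs=1e-3)
            else:
                assert abs(g) <= lam + 1e-3

    def test_objective_sandwich(self, medium_cohort):
        data = medium_cohort.subset(np.arange(500))
        lam = lasso_lambda_max(data) * 0.3
        fit = fit_cox_lasso(data, lam)

        def objective(beta_orig):
            X = data.covariates.to_numpy()
            beta_std = np.asarray(beta_orig) * X.std(0)
            Xs = (X - X.mean(0)) / X.std(0)
            sdata = SurvivalDataset(time=data.time, event=data.event,
                                    covariates=pd.DataFrame(Xs, columns=data.covariate_names))
            return -log_partial_likelihood(sdata, beta_std) + lam * np.abs(beta_std).sum()

        obj_hat = objective(fit.beta.to_numpy())
        assert obj_hat <= objective(np.zeros(len(fit.beta))) + 1e-9
        assert obj_hat <= objective(fit_cox(data).beta.to_numpy()) + 1e-9

    def test_active_set_shrinks_along_path(self, medium_cohort):
        data = medium_cohort.subset(np.arange(500))
        lam_max = lasso_lambda_max(data)
        sizes = [len(fit_cox_lasso(data, f * lam_max).active_set)
                 for f in (0.05, 0.2, 0.5, 0.9, 1.01)]
        assert sizes == sorted(sizes, reverse=True)


class TestCVPL:
    def test_full_shrinkage_closed_form(self, medium_cohort):
        """At a penalty beyond lambda_max every fold fit is beta = 0, so
        the CVPL has the closed form sum[l_full(0) - l_train(0)]."""
        data = medium_cohort.subset(np.arange(400))
        lam = lasso_lambda_max(data) * 1.5
        seed, k = 3, 5
        value = cvpl(data, lam, n_folds=k, seed=seed)
        expected = 0.0
        zero = np.zeros(len(data.covariate_names))
        for fold in _stratified_folds(data.event, k, seed):
            mask = np.ones(data.n, dtype=bool)
            mask[fold] = False
            train = data.subset(np.flatnonzero(mask))
            expected += (log_partial_likelihood(data, zero)
                         - log_partial_likelihood(train, zero))
        assert value == pytest.approx(expected, abs=1e-9)

    def test_two_fold_direct_evaluation(self):
        """2-fold CVPL at lambda=0 against an independently scripted
        evaluation using lifelines fits and brute-force likelihood sums."""
        from lifelines import CoxPHFitter
        data = generate(GeneratorSpec(n=200, p_binary=1, p_continuous=1,
                                      beta=(0.6, -0.4), seed=13))
        seed = 5
        value = cvpl(data, 0.0, n_folds=2, seed=seed)
        expected = 0.0
        for fold in _stratified_folds(data.event, 2, seed):
            mask = np.ones(data.n, dtype=bool)
            mask[fold] = False
            train = data.subset(np.flatnonzero(mask))
            cph = CoxPHFitter()
            cph.fit(train.to_frame().drop(columns="id"),
                    duration_col="time", event_col="event")
            beta = cph.params_[data.covariate_names].to_numpy()
            expected += (_brute_breslow_ll(data.time, data.event,
                                           data.covariates.to_numpy(), beta)
                         - _brute_breslow_ll(train.time, train.event,
                                             train.covariates.to_numpy(), beta))
        assert value == pytest.approx(expected, abs=5e-3)

    def test_finite_over_grid(self, medium_cohort):
        data = medium_cohort.subset(np.arange(300))
        lam_max = lasso_lambda_max(data)
        for lam in (0.1 * lam_max, 0.5 * lam_max, 2 * lam_max):
            assert np.isfinite(cvpl(data, lam, seed=1))


class TestSelectLambda:
    def test_singleton_grid(self, medium_cohort):
        data = medium_cohort.subset(np.arange(300))
        lam, table = select_lambda(data, [2.5], seed=0)
        assert lam == 2.5 and len(table) == 1

    def test_deterministic_given_seed(self, medium_cohort):
        data = medium_cohort.subset(np.arange(300))
        grid = [0.5, 2.0, 8.0]
        a, ta = select_lambda(data, grid, seed=4)
        b, tb = select_lambda(data, grid, seed=4)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_selects_informative_model_on_ph_data(self):
        data = generate(GeneratorSpec(n=1000, seed=17))
        lam_max = lasso_lambda_max(data)
        lam, _ = select_lambda(data, [0.02 * lam_max, 1.5 * lam_max], seed=2)
        fit = fit_cox_lasso(data, lam)
        # the strong true effects survive selection
        assert lam < lam_max
        assert {"bin_1", "cont_1"} <= set(fit.active_set)


class TestBackwardElimination:
    def test_strong_factors_retained(self):
        data = generate(GeneratorSpec(n=1500, p_binary=2, p_continuous=1,
                                      beta=(0.8, -0.6, 0.5), seed=23))
        fit = backward_eliminate(data)
        assert list(fit.beta.index) == data.covariate_names
        assert fit.elimination_trace == []

    def test_noise_factor_eliminated(self):
        rng = np.random.default_rng(29)
        data = generate(GeneratorSpec(n=1500, p_binary=1, p_continuous=1,
                                      beta=(0.8, -0.6), seed=23))
        noise = pd.DataFrame({f"noise_lvl{i}": rng.binomial(1, 0.3, data.n).astype(float)
                              for i in range(3)})
        full = SurvivalDataset(
            time=data.time, event=data.event,
            covariates=pd.concat([data.covariates, noise], axis=1),
            group_map={**{c: c for c in data.covariate_names},
                       **{c: "noise" for c in noise.columns}},
        )
        fit = backward_eliminate(full)
        assert [t["dropped"] for t in fit.elimination_trace] == ["noise"]
        assert set(fit.beta.index) == set(data.covariate_names)

    def test_single_level_factors_reduce_to_1df_wald(self):
        data = generate(GeneratorSpec(n=800, p_binary=2, p_continuous=0,
                                      beta=(0.7, 0.0), seed=31))
        fit_full = fit_cox(data)
        fit = backward_eliminate(data, alpha_stay=0.05)
        from scipy import stats
        p_vals = {nm: stats.chi2.sf(fit_full.z[nm] ** 2, df=1) for nm in fit_full.beta.index}
        dropped = {t["dropped"] for t in fit.elimination_trace}
        for nm, p in p_vals.items():
            if p > 0.05:
                assert nm in dropped

    def test_all_eliminated_returns_null_model(self):
        rng = np.random.default_rng(37)
        n = 300
        data = SurvivalDataset(
            time=rng.exponential(5, n), event=rng.binomial(1, 0.5, n),
            covariates=pd.DataFrame({"junk": rng.normal(size=n)}),
        )
        with pytest.warns(UserWarning, match="null model"):
            fit = backward_eliminate(data, alpha_stay=1e-12)
        assert len(fit.beta) == 0
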