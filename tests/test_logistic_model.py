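import numpy as np
import pandas as pd
import pytest

from springpulse.exceptions import (
    AssemblyError,
    SeparationError,
    UndefinedStatisticError,
)
from springpulse.logistic_model import (
    DesignMatrix,
    TABLE2_SPECS,
    assemble_design,
    collinearity_screen,
    fit_bayes_logistic,
    gelman_rubin,
    model_scores,
    period_summaries,
    predict_initiation_day,
    prediction_rmse,
)
from springpulse.migration_response import HerdYearResponse, binary_response


def make_response(herd, year, init, horizon=150):
    return HerdYearResponse(
        herd=herd, year=year, n_collared=10, max_simultaneous=7,
        group_initiation_day=init, earliest_individual_day=init,
        daily_response=binary_response(init, horizon),
    )


def make_covariates(years, pulse_days, horizon=150):
    out = {}
    days = np.arange(1, horizon + 1)
    for year, pd_day in zip(years, pulse_days):
        out[year] = pd.DataFrame({"Dsm": days - pd_day}, index=days)
    return out


def simple_matrix(beta, n=3000, seed=0, herd_col=False):
    """iid Bernoulli rows from a known logit model on a daily covariate."""
    rng = np.random.default_rng(seed)
    day = np.tile(np.arange(1.0, 151.0), n // 150)
    cols = [np.ones(day.size), day]
    names = ["intercept", "day"]
    if herd_col:
        herd = np.repeat(np.arange(day.size // 150) % 2, 150).astype(float)
        cols.append(herd)
        names.append("herd")
    X = np.column_stack(cols)
    theta = 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta))))
    y = (rng.random(day.size) < theta).astype(float)
    idx = pd.DataFrame({"herd": "NAR", "year": 2000, "day": day.astype(int)})
    return DesignMatrix(X=X, y=y, columns=tuple(names), index=idx)


class TestAssembleDesign:
    def test_row_and_column_counts(self):
        responses = [make_response("NAR", 2001, 100), make_response("SAR", 2001, 95)]
        cov = make_covariates([2001], [99])
        for frame in cov.values():
            pass
        m = assemble_design(responses, cov, ["Dsm", "herd"])
        assert m.n == 300
        assert m.columns == ("intercept", "Dsm", "herd")
        # herd dummy: NAR rows 0, SAR rows 1
        assert set(m.X[m.index["herd"] == "NAR", 2]) == {0.0}
        assert set(m.X[m.index["herd"] == "SAR", 2]) == {1.0}

    def test_missing_year_lists_gaps(self):
        responses = [make_response("NAR", 2001, 100), make_response("NAR", 2002, 90)]
        cov = make_covariates([2001], [99])
        with pytest.raises(AssemblyError, match="2002"):
            assemble_design(responses, cov, ["Dsm"])

    def test_absent_covariate_name(self):
        responses = [make_response("NAR", 2001, 100)]
        cov = make_covariates([2001], [99])
        with pytest.raises(AssemblyError, match="GDD"):
            assemble_design(responses, cov, ["GDD"])

    def test_table2_specs_all_assemble(self):
        days = np.arange(1, 151)
        frame = pd.DataFrame(
            {name: np.linspace(-50, 50, 150) + i
             for i, name in enumerate(
                 ["T_mean", "GDD", "JERK", "Dsm_lily", "Dsm_slater", "Dpsm_slater"])},
            index=days,
        )
        responses = [make_response("NAR", 2001, 100), make_response("SAR", 2001, 95)]
        for spec in TABLE2_SPECS.values():
            m = assemble_design(responses, {2001: frame}, spec)
            assert m.k == len(spec) + 1


class TestCollinearityScreen:
    def _matrix(self, cols):
        names = ["intercept"] + [f"c{i}" for i in range(len(cols))]
        X = np.column_stack([np.ones(len(cols[0])), *cols])
        n = len(cols[0])
        idx = pd.DataFrame(
            {"herd": "NAR", "year": 2000, "day": np.arange(1, n + 1)})
        return DesignMatrix(X=X, y=np.zeros(len(cols[0])), columns=tuple(names), index=idx)

    def test_duplicated_column_flagged(self, rng):
        a = rng.normal(size=500)
        table = collinearity_screen(self._matrix([a, a.copy()]))
        assert table.iloc[0]["pearson_r"] == pytest.approx(1.0)
        assert bool(table.iloc[0]["flagged"])

    def test_negated_column_flagged_by_absolute_value(self, rng):
        a = rng.normal(size=500)
        table = collinearity_screen(self._matrix([a, -a]))
        assert table.iloc[0]["pearson_r"] == pytest.approx(-1.0)
        assert bool(table.iloc[0]["flagged"])

    def test_independent_columns_unflagged(self, rng):
        a, b = rng.normal(size=(2, 10_000))
        table = collinearity_screen(self._matrix([a, b]))
        assert abs(table.iloc[0]["pearson_r"]) < 0.20
        assert not bool(table.iloc[0]["flagged"])

    def test_zero_variance_column(self, rng):
        with pytest.raises(UndefinedStatisticError):
            collinearity_screen(self._matrix([rng.normal(size=50), np.full(50, 3.0)]))


class TestFitBayesLogistic:
    def test_intercept_only_balanced_response_centers_at_zero(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(500), np.zeros(500)]
        rng.shuffle(y)
        m = DesignMatrix(
            X=np.ones((1000, 1)), y=y, columns=("intercept",),
            index=pd.DataFrame({"herd": "NAR", "year": 2000, "day": 1}, index=range(1000)),
        )
        fit = fit_bayes_logistic(m, chains=3, steps=3000, burn_in=500, seed=9)
        assert abs(fit.coef_mean()[0]) < 0.2
        assert fit.converged

    def test_known_coefficients_inside_credible_interval(self):
        m = simple_matrix([-6.0, 0.08], n=4500, seed=4)
        fit = fit_bayes_logistic(m, chains=3, steps=5000, burn_in=1000, seed=5)
        ci = fit.credible_interval()
        assert ci[0, 0] < -6.0 < ci[0, 1]
        assert ci[1, 0] < 0.08 < ci[1, 1]
        assert np.all(fit.gelman_rubin < 1.1)

    def test_single_class_response_is_separation_error(self):
        m = simple_matrix([-6.0, 0.08], n=300, seed=4)
        m = DesignMatrix(X=m.X, y=np.ones(m.n), columns=m.columns, index=m.index)
        with pytest.raises(SeparationError):
            fit_bayes_logistic(m, steps=100, burn_in=10)

    def test_gelman_rubin_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(3, 400, 2))
        draws[2, :, 1] += 2.0  # shift one chain of one parameter only
        ours = gelman_rubin(draws)
        theirs = np.array([
            float(arviz.rhat(arviz.convert_to_dataset(draws[:, :, i]))["x"])
            for i in range(2)
        ])
        # arviz uses rank-normalized split-Rhat; agreement is approximate
        assert ours == pytest.approx(theirs, rel=0.1)
        assert ours[0] < 1.05  # untouched parameter converged
        assert ours[1] > 1.1   # shifted chain flagged


class TestModelScores:
    def test_dic_matches_hand_computation_on_fixed_draws(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        draws = np.array([[[-1.0, 0.5], [-2.0, 1.5]]])  # 1 chain, 2 draws
        m = DesignMatrix(X=X, y=y, columns=("intercept", "x"),
                         index=pd.DataFrame({"herd": "NAR", "year": 2000,
                                             "day": [1, 2, 3, 4]}))
        fit = fit_bayes_logistic(m, chains=2, steps=50, burn_in=10, seed=0)
        fit.draws = draws  # freeze a known draw set

        def deviance(b):
            eta = X @ b
            return -2 * float(y @ eta - np.logaddexp(0, eta).sum())

        dbar = np.mean([deviance(b) for b in draws[0]])
        dhat = deviance(draws[0].mean(axis=0))
        expected = 2 * dbar - dhat
        scores = model_scores(fit, m)
        assert scores.dic == pytest.approx(expected)

    def test_separable_data_scores_perfectly(self):
        m = simple_matrix([-30.0, 0.4], n=3000, seed=8)  # crossing at day 75, steep
        fit = fit_bayes_logistic(m, chains=3, steps=4000, burn_in=1000, seed=8)
        scores = model_scores(fit, m)
        assert scores.recall > 0.97
        assert scores.precision > 0.97

    def test_confusion_matrix_identities(self):
        m = simple_matrix([-6.0, 0.08], n=3000, seed=2)
        fit = fit_bayes_logistic(m, chains=3, steps=3000, burn_in=500, seed=2)
        scores = model_scores(fit, m)
        assert 0.0 <= scores.recall <= 1.0
        assert 0.0 <= scores.precision <= 1.0

    def test_informative_model_beats_intercept_only_by_dic(self):
        m = simple_matrix([-6.0, 0.08], n=3000, seed=6)
        fit = fit_bayes_logistic(m, chains=3, steps=3000, burn_in=500, seed=6)
        m0 = DesignMatrix(X=m.X[:, :1], y=m.y, columns=("intercept",), index=m.index)
        fit0 = fit_bayes_logistic(m0, chains=3, steps=3000, burn_in=500, seed=6)
        assert model_scores(fit, m).dic < model_scores(fit0, m0).dic


class TestPrediction:
    def _degenerate_fit(self, beta, columns):
        draws = np.tile(np.asarray(beta, dtype=float), (1, 100, 1))
        m = simple_matrix([-6.0, 0.08], n=300, seed=1)
        fit = fit_bayes_logistic(m, chains=2, steps=50, burn_in=10, seed=1)
        fit.draws = draws
        fit.columns = columns
        return fit

    def test_positive_slope_crosses_the_day_after_the_pulse(self):
        days = np.arange(1, 151)
        cov = pd.DataFrame({"Dsm": (days - 99).astype(float)}, index=days)
        fit = self._degenerate_fit([0.0, 0.3], ("intercept", "Dsm"))
        # theta = 0.5 exactly at Dsm = 0 (day 99); strict exceedance -> day 100
        assert predict_initiation_day(fit, cov) == 100

    def test_all_negative_predictor_never_crosses(self):
        days = np.arange(1, 151)
        cov = pd.DataFrame({"Dsm": np.full(150, -5.0)}, index=days)
        fit = self._degenerate_fit([0.0, 0.3], ("intercept", "Dsm"))
        assert predict_initiation_day(fit, cov) is None

    def test_positive_intercept_alone_predicts_day_one(self):
        days = np.arange(1, 151)
        cov = pd.DataFrame({"Dsm": (days - 99).astype(float)}, index=days)
        fit = self._degenerate_fit([2.0, 0.0], ("intercept", "Dsm"))
        assert predict_initiation_day(fit, cov) == 1

    def test_monotone_in_positive_covariate(self):
        days = np.arange(1, 151)
        fit = self._degenerate_fit([0.0, 0.3], ("intercept", "Dsm"))
        base = pd.DataFrame({"Dsm": (days - 110).astype(float)}, index=days)
        earlier = pd.DataFrame({"Dsm": (days - 110 + 15).astype(float)}, index=days)
        d_base = predict_initiation_day(fit, base)
        d_earlier = predict_initiation_day(fit, earlier)
        assert d_earlier <= d_base


class TestRmseAndPeriods:
    def test_identical_vectors(self):
        assert prediction_rmse({"a": 5}, {"a": 5}) == 0.0

    def test_hand_computed_rmse(self):
        pred = {"a": 103, "b": 104}
        obs = {"a": 100, "b": 100}
        assert prediction_rmse(pred, obs) == pytest.approx(np.sqrt(12.5))

    def test_single_pair(self):
        assert prediction_rmse({"a": 10}, {"a": 5}) == 5.0

    def test_unpaired_entries_rejected(self):
        with pytest.raises(ValueError):
            prediction_rmse({"a": 1}, {"b": 2})

    def test_period_median_and_iqr(self):
        preds = {1950: 110, 1951: 120, 1952: 130, 1965: 128}
        table = period_summaries(preds)
        first = table.iloc[0]
        assert first["median_day"] == 120
        assert first["iqr_days"] == 10
        second = table.iloc[1]
        assert second["median_day"] == 128 and second["iqr_days"] == 0
        assert np.isnan(table.iloc[2]["median_day"])
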