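"""Logistic hazard fitting, clustered variance, ranking, closed-form export."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from akipredict import (
    export_closed_form,
    fit_discrete_logit,
    parse_closed_form,
    predict_risk,
    rank_covariates,
    score_closed_form,
)
from akipredict.errors import AkiPredictError, SeparationError, SingularDesignError


def _frame(y, pid=None, **covs):
    n = len(y)
    return pd.DataFrame(
        {"patient_id": pid if pid is not None else np.arange(n), "y": y, **covs}
    )


def test_intercept_only_is_log_odds_of_prevalence():
    rows = _frame(np.r_[np.ones(25), np.zeros(75)].astype(int))
    fit = fit_discrete_logit(rows, "full", "y", covariates=[])
    assert fit.beta[0] == pytest.approx(np.log(25 / 75), abs=1e-8)


def test_matches_statsmodels_with_cluster_covariance():
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    n, G = 600, 120
    pid = np.repeat(np.arange(G), n // G)
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.3, n).astype(float)
    u = rng.normal(size=G)[pid]
    y = (rng.random(n) < expit(-1.0 + 0.8 * x1 - 0.5 * x2 + u)).astype(int)
    rows = _frame(y, pid=pid, x1=x1, x2=x2)
    fit = fit_discrete_logit(rows, "full", "y", covariates=["x1", "x2"])
    ref = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(
        disp=0, cov_type="cluster", cov_kwds={"groups": pid}
    )
    np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6)
    # statsmodels applies an extra (n-1)/(n-k) small-sample factor
    np.testing.assert_allclose(fit.se, ref.bse, rtol=0.01)


def test_one_row_per_cluster_reduces_to_hc0():
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    n = 400
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(0.5 * x)).astype(int)
    rows = _frame(y, x=x)  # unique patient per row
    fit = fit_discrete_logit(rows, "full", "y", covariates=["x"], small_sample_correction=False)
    ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0, cov_type="HC0")
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-8)


def test_order_invariance_under_patient_permutation():
    rng = np.random.default_rng(5)
    n = 500
    pid = np.repeat(np.arange(100), 5)
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(0.3 * x)).astype(int)
    rows = _frame(y, pid=pid, x=x)
    fit1 = fit_discrete_logit(rows, "full", "y", covariates=["x"])
    shuffled = rows.sample(frac=1.0, random_state=1).reset_index(drop=True)
    fit2 = fit_discrete_logit(shuffled, "full", "y", covariates=["x"])
    np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)
    np.testing.assert_allclose(np.diag(fit1.cov), np.diag(fit2.cov), rtol=1e-8)


def test_complete_separation_raises_naming_covariate():
    x = np.linspace(-2, 2, 100)
    y = (x > 0).astype(int)
    with pytest.raises(SeparationError) as exc:
        fit_discrete_logit(_frame(y, x=x), "full", "y", covariates=["x"])
    assert "x" in str(exc.value)


def test_singular_design_raises_listing_columns():
    rng = np.random.default_rng(8)
    x = rng.normal(size=200)
    y = (rng.random(200) < expit(x)).astype(int)
    rows = _frame(y, x=x, x_copy=x)
    with pytest.raises(SingularDesignError):
        fit_discrete_logit(rows, "full", "y", covariates=["x", "x_copy"])


def test_single_class_labels_rejected():
    with pytest.raises(AkiPredictError):
        fit_discrete_logit(_frame(np.zeros(50, dtype=int)), "full", "y", covariates=[])


def test_missing_values_rejected_not_imputed():
    y = np.r_[np.ones(10), np.zeros(10)].astype(int)
    x = np.r_[np.nan, np.zeros(19)]
    with pytest.raises(AkiPredictError):
        fit_discrete_logit(_frame(y, x=x), "full", "y", covariates=["x"])


@pytest.fixture(scope="module")
def two_covariate_fit():
    rng = np.random.default_rng(2)
    n = 300
    a, b = rng.normal(size=n), rng.normal(size=n)
    y = (rng.random(n) < expit(-0.5 + a - 0.7 * b)).astype(int)
    return fit_discrete_logit(_frame(y, a=a, b=b), "full", "y", covariates=["a", "b"])


class TestPredict:
    @pytest.fixture
    def fit(self, two_covariate_fit):
        return two_covariate_fit

    def test_all_zero_covariates_give_inverse_logit_intercept(self, fit):
        p = predict_risk(fit, {"a": 0.0, "b": 0.0})
        assert p == pytest.approx(float(expit(fit.beta[0])), abs=1e-12)

    def test_hand_computed_dot_product(self, fit):
        row = {"a": 1.5, "b": -2.0}
        eta = fit.beta[0] + fit.beta[1] * 1.5 + fit.beta[2] * (-2.0)
        assert predict_risk(fit, row) == pytest.approx(float(expit(eta)), abs=1e-12)

    def test_zero_model_predicts_half(self, fit):
        neutral = type(fit)(**{**fit.__dict__, "beta": np.zeros_like(fit.beta)})
        assert predict_risk(neutral, {"a": 3.0, "b": -1.0}) == 0.5

    def test_missing_covariate_is_an_error(self, fit):
        with pytest.raises(AkiPredictError):
            predict_risk(fit, {"a": 1.0})
        with pytest.raises(AkiPredictError):
            predict_risk(fit, {"a": 1.0, "b": np.nan})


class TestRanking:
    def test_strong_covariate_ranks_first(self):
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(100):
            n = 400
            strong = rng.normal(size=n)
            w1, w2 = rng.normal(size=n), rng.normal(size=n)
            y = (rng.random(n) < expit(-1.0 + 1.5 * strong)).astype(int)
            if y.min() == y.max():
                continue
            fit = fit_discrete_logit(
                _frame(y, strong=strong, w1=w1, w2=w2), "full", "y",
                covariates=["strong", "w1", "w2"],
            )
            wins += rank_covariates(fit)[0][0] == "strong"
        assert wins >= 95

    def test_null_covariate_has_small_z(self):
        rng = np.random.default_rng(23)
        small = 0
        for _ in range(100):
            n = 2000
            x = rng.normal(size=n)
            null = rng.normal(size=n)
            y = (rng.random(n) < expit(-1.0 + x)).astype(int)
            fit = fit_discrete_logit(
                _frame(y, x=x, null=null), "full", "y", covariates=["x", "null"]
            )
            z = dict(rank_covariates(fit))["null"]
            small += z < 3
        assert small >= 99

    def test_ties_break_alphabetically(self):
        from akipredict.model import ModelFit

        fit = ModelFit(
            model_class="full", outcome="y", names=["(intercept)", "b", "a", "c"],
            beta=np.array([0.0, 1.0, -1.0, 2.0]), cov=np.eye(4),
            n_rows=10, n_patients=10, n_events=5, loglik=0.0, n_iter=1, converged=True,
        )
        # |z| ties between a and b resolve alphabetically; c leads on |z|
        assert [n for n, _ in rank_covariates(fit)] == ["c", "a", "b"]


class TestClosedForm:
    def test_intercept_only_export(self):
        rows = _frame(np.r_[np.ones(30), np.zeros(70)].astype(int))
        fit = fit_discrete_logit(rows, "full", "y", covariates=[])
        text = export_closed_form(fit)
        assert text.startswith("logit(p) = ")
        intercept, coefs = parse_closed_form(text)
        assert intercept == pytest.approx(fit.beta[0])
        assert coefs == {}

    def test_round_trip_scores_match_predict(self):
        rng = np.random.default_rng(41)
        n = 300
        a, b, c = rng.normal(size=(3, n))
        y = (rng.random(n) < expit(0.5 + a - 2 * b + 0.01 * c)).astype(int)
        rows = _frame(y, a=a, b=b, c=c)
        fit = fit_discrete_logit(rows, "full", "y", covariates=["a", "b", "c"])
        text = export_closed_form(fit)
        new_rows = pd.DataFrame({"a": rng.normal(size=100),
                                 "b": rng.normal(size=100),
                                 "c": rng.normal(size=100)})
        np.testing.assert_allclose(
            score_closed_form(text, new_rows), predict_risk(fit, new_rows), atol=1e-9
        )

    def test_exported_coefficient_count(self):
        rng = np.random.default_rng(43)
        n = 200
        a, b = rng.normal(size=(2, n))
        y = (rng.random(n) < expit(a)).astype(int)
        fit = fit_discrete_logit(_frame(y, a=a, b=b), "full", "y", covariates=["a", "b"])
        _, coefs = parse_closed_form(export_closed_form(fit))
        assert len(coefs) == 2  # covariate count; intercept reported separately


def test_naive_and_clustered_variance_agree_for_independent_rows():
    """When rows are independent within patients the cluster correction is a
    no-op on average (variance ratio centered at 1)."""
    from akipredict.model import cluster_sandwich, _irls

    rng = np.random.default_rng(51)
    ratios = []
    for _ in range(40):
        n = 800
        pid = np.repeat(np.arange(160), 5)
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + 0.6 * x)).astype(int)
        X = np.column_stack([np.ones(n), x])
        beta, bread, *_ = _irls(X, y.astype(float), ["i", "x"])
        v_clu = cluster_sandwich(X, y, beta, bread, pid, small_sample_correction=False)
        v_row = cluster_sandwich(X, y, beta, bread, np.arange(n), small_sample_correction=False)
        ratios.append(v_clu[1, 1] / v_row[1, 1])
    assert abs(np.mean(ratios) - 1.0) < 0.1
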