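"""Estimators: quasi-likelihood fractional logit, two-limit Tobit, OLS —
score identities, oracle equivalence, robust covariance and invariances."""
import numpy as np
import pytest
from scipy import optimize, stats

import reefstress as rs
from reefstress.models import OLS, FractionalLogit, Tobit, _hc1_sandwich, inv_logit
from reefstress.exceptions import IdentificationError

from conftest import make_logistic_design


def powell_max(fun, x0):
    """Independent derivative-free maximiser of an objective."""
    res = optimize.minimize(lambda b: -fun(b), x0, method="Powell",
                            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000})
    for _ in range(2):
        res = optimize.minimize(lambda b: -fun(b), res.x, method="Powell",
                                options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000})
    return res.x


# ---------------------------------------------------------------------------
# link function
# ---------------------------------------------------------------------------

def test_inv_logit_values():
    assert inv_logit(0.0) == 0.5
    assert inv_logit(np.log(3.0)) == pytest.approx(0.75)
    assert inv_logit(700.0) == pytest.approx(1.0)
    assert inv_logit(-700.0) == pytest.approx(0.0)
    assert np.isfinite(inv_logit(np.array([-750.0, 750.0]))).all()


# ---------------------------------------------------------------------------
# fractional logit
# ---------------------------------------------------------------------------

def test_intercept_only_fit_matches_sample_mean(rng):
    y = rng.beta(3, 7, 200)  # mean 0.3
    dm = rs.DesignMatrix(X=np.ones((200, 1)), y=y, column_names=["const"])
    fit = rs.fit_fractional_logit(dm)
    assert fit.params[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)


def test_score_identity_at_optimum(bleaching_fit):
    dm, fit = bleaching_fit
    resid = dm.y - fit.predict()
    assert np.max(np.abs(dm.X.T @ resid)) < 1e-6


def test_fractional_logit_agrees_with_derivative_free_oracle():
    dm, _ = make_logistic_design(n=60, p=4, seed=3)
    fit = rs.fit_fractional_logit(dm)
    model = FractionalLogit(dm.y, dm.X)
    oracle = powell_max(model.loglike, np.zeros(dm.n_params))
    np.testing.assert_allclose(fit.params, oracle, atol=1e-5)


def test_fractional_logit_matches_glm_quasibinomial():
    sm = pytest.importorskip("statsmodels.api")
    dm, _ = make_logistic_design(n=120, p=5, seed=9)
    fit = rs.fit_fractional_logit(dm)
    glm = sm.GLM(dm.y, dm.X, family=sm.families.Binomial()).fit(cov_type="HC0")
    np.testing.assert_allclose(fit.params, glm.params, atol=1e-7)
    # our sandwich is HC1-scaled; the GLM one is HC0
    n, p = dm.X.shape
    np.testing.assert_allclose(fit.bse, glm.bse * np.sqrt(n / (n - p)), rtol=1e-6)


def test_fractional_logit_on_binary_outcome_is_logistic_regression():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
    y = (rng.random(300) < inv_logit(X @ np.array([-0.3, 0.8, -0.5]))).astype(float)
    fit = FractionalLogit(y, X).fit()
    logit = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(fit.params, logit.params, atol=1e-6)


def test_rank_deficiency_names_collinear_column():
    dm, _ = make_logistic_design(n=50, p=3, seed=1)
    X = np.column_stack([dm.X, dm.X[:, 1] * 2.0])
    # either member of the collinear pair is a valid culprit to report
    with pytest.raises(np.linalg.LinAlgError, match="x1"):
        FractionalLogit(dm.y, X, column_names=dm.column_names + ["x1_copy"]).fit()


def test_column_reordering_invariance():
    dm, _ = make_logistic_design(n=90, p=4, seed=5)
    fit = rs.fit_fractional_logit(dm)
    perm = [2, 0, 3, 1]
    fit_p = FractionalLogit(
        dm.y, dm.X[:, perm], column_names=[dm.column_names[j] for j in perm]
    ).fit()
    for j, pj in enumerate(perm):
        assert fit_p.params[j] == pytest.approx(fit.params[pj], abs=1e-7)


def test_affine_rescaling_equivariance():
    dm, _ = make_logistic_design(n=90, p=4, seed=6)
    fit = rs.fit_fractional_logit(dm)
    X2 = dm.X.copy()
    X2[:, 1] *= 10.0
    fit2 = FractionalLogit(dm.y, X2, column_names=dm.column_names).fit()
    assert fit2.params[1] == pytest.approx(fit.params[1] / 10.0, abs=1e-7)
    assert fit2.bse[1] == pytest.approx(fit.bse[1] / 10.0, rel=1e-5)


def test_coefficient_recovery_within_robust_cis(rng):
    """Estimates land within 3 robust SEs of the generating coefficients in
    nearly all replicates at n = 5000."""
    hits = 0
    reps = 40
    for r in range(reps):
        rng_r = np.random.default_rng(1000 + r)
        n = 5000
        X = np.column_stack([np.ones(n), rng_r.normal(size=(n, 2))])
        beta = np.array([-0.8, 0.5, -0.3])
        mu = inv_logit(X @ beta)
        y = rng_r.beta(mu * 4, (1 - mu) * 4)
        fit = FractionalLogit(y, X).fit()
        hits += np.all(np.abs(fit.params - beta) <= 3 * fit.bse)
    assert hits / reps >= 0.9


# ---------------------------------------------------------------------------
# sandwich covariance
# ---------------------------------------------------------------------------

def test_sandwich_reduces_to_model_based_when_b_equals_a(rng):
    X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
    A = X.T @ X
    cov = _hc1_sandwich(A, X, df_scale=1.0)  # scores = X so B = A
    np.testing.assert_allclose(cov, np.linalg.inv(A), atol=1e-10)


# ---------------------------------------------------------------------------
# Tobit
# ---------------------------------------------------------------------------

def _uncensored_fixture(rng, n=60):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = np.clip(0.5 + 0.05 * X[:, 1] - 0.04 * X[:, 2] + rng.normal(0, 0.05, n), 0, 1)
    assert not ((y <= 0) | (y >= 1)).any()
    return X, y


def test_tobit_without_censoring_equals_ols(rng):
    X, y = _uncensored_fixture(rng)
    ols = OLS(y, X).fit()
    tob = Tobit(y, X).fit()
    np.testing.assert_allclose(tob.params, ols.params, atol=1e-6)
    assert tob.sigma == pytest.approx(np.std(y - X @ ols.params), abs=1e-6)


def test_tobit_with_infinite_limits_equals_ols(rng):
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ np.array([0.2, 1.0, -0.7]) + rng.normal(0, 0.5, n)
    ols = OLS(y, X).fit()
    tob = Tobit(y, X, lower=-np.inf, upper=np.inf).fit()
    np.testing.assert_allclose(tob.params, ols.params, atol=1e-6)


def test_tobit_loglik_matches_independent_evaluation(rng):
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 1))])
    y = np.clip(0.15 + 0.3 * X[:, 1] + rng.normal(0, 0.3, n), 0.0, 1.0)
    model = Tobit(y, X)
    fit = model.fit()
    beta, sigma = fit.params, fit.sigma
    # direct censored-normal likelihood, written out independently
    ll = 0.0
    for yi, xi in zip(y, X):
        m = xi @ beta
        if yi <= 0.0:
            ll += np.log(stats.norm.cdf((0.0 - m) / sigma))
        elif yi >= 1.0:
            ll += np.log(1.0 - stats.norm.cdf((1.0 - m) / sigma))
        else:
            ll += np.log(stats.norm.pdf(yi, loc=m, scale=sigma))
    assert fit.llf == pytest.approx(ll, abs=1e-8)


def test_tobit_agrees_with_derivative_free_oracle(rng):
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = np.clip(0.1 + 0.25 * X[:, 1] - 0.2 * X[:, 2] + rng.normal(0, 0.25, n), 0, 1)
    model = Tobit(y, X)
    fit = model.fit()
    oracle = powell_max(model.loglike, model._start())
    np.testing.assert_allclose(fit.params, oracle[:-1], atol=1e-5)
    assert fit.sigma == pytest.approx(np.exp(oracle[-1]), abs=1e-5)


def test_tobit_recovers_truth_under_heavy_censoring():
    rng = np.random.default_rng(77)
    n = 4000
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta = np.array([-0.05, 0.25, -0.2])
    y = np.clip(X @ beta + rng.normal(0, 0.3, n), 0.0, 1.0)
    assert (y == 0).mean() > 0.3  # heavy left censoring
    fit = Tobit(y, X).fit()
    assert np.all(np.abs(fit.params - beta) <= 3 * fit.bse)
    assert fit.sigma == pytest.approx(0.3, abs=0.03)


def test_tobit_all_censored_is_unidentified():
    X = np.column_stack([np.ones(20), np.linspace(-1, 1, 20)])
    with pytest.raises(IdentificationError):
        Tobit(np.zeros(20), X)


# ---------------------------------------------------------------------------
# OLS and predictions
# ---------------------------------------------------------------------------

def test_ols_exact_linear_fit(rng):
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
    y = X @ np.array([0.3, 0.1, -0.2])
    fit = OLS(y, X).fit()
    np.testing.assert_allclose(y - X @ fit.params, 0.0, atol=1e-12)


def test_ols_intercept_only_is_mean(rng):
    y = rng.uniform(0, 1, 50)
    fit = OLS(y, np.ones((50, 1))).fit()
    assert fit.params[0] == pytest.approx(y.mean())


def test_ols_matches_statsmodels_hc1(rng):
    sm = pytest.importorskip("statsmodels.api")
    X = np.column_stack([np.ones(70), rng.normal(size=(70, 3))])
    y = X @ rng.normal(size=4) + rng.normal(0, 0.3, 70) * (1 + np.abs(X[:, 1]))
    fit = OLS(y, X).fit()
    ref = sm.OLS(y, X).fit(cov_type="HC1")
    np.testing.assert_allclose(fit.params, ref.params, atol=1e-10)
    np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-8)


def test_prediction_ranges(bleaching_fit, rng):
    dm, fit = bleaching_fit
    pred = fit.predict()
    assert np.all((pred > 0) & (pred < 1))
    tob = rs.fit_tobit(dm)
    tpred = tob.predict()
    assert np.all((tpred >= 0) & (tpred <= 1))
    ols = rs.fit_ols(dm)
    X_extreme = dm.X.copy()
    X_extreme[:, 1] = dm.X[:, 1].max() * 50
    with pytest.warns(UserWarning, match="outside"):
        out = ols.predict(X_extreme)
    assert out.max() > 1.0


def test_summary_and_json_outputs(bleaching_fit):
    _, fit = bleaching_fit
    text = fit.summary()
    assert "p<0.01" in text and "obs_dhw" in text
    import json

    payload = json.loads(fit.to_json())
    assert payload["family"] == "fractional_logit"
    assert payload["converged"] is True
    assert set(payload["coefficients"]) == set(fit.column_names)
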