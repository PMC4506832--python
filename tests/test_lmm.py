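"""Random-intercept REML: oracle agreement, boundary behaviour, inference."""

import numpy as np
import pandas as pd
import pytest

from nrtmodel.lmm import RandomInterceptLMM, RandomInterceptLMMResults


# ---------------------------------------------------------------------------
# Independent oracle: dense-matrix REML criterion maximised by grid search
# ---------------------------------------------------------------------------

def dense_reml_loglik(lam, y, X, groups):
    """Textbook REML log-likelihood via explicit N x N covariance matrices."""
    n, p = X.shape
    Z = (np.asarray(groups)[:, None] == np.unique(groups)[None, :]).astype(float)
    Vlam = np.eye(n) + lam * (Z @ Z.T)
    Vi = np.linalg.inv(Vlam)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    rss = float(r @ Vi @ r)
    s2e = rss / (n - p)
    ll = -0.5 * (
        n * np.log(s2e) + np.linalg.slogdet(Vlam)[1]
        + np.linalg.slogdet(XtVX / s2e)[1]
        + rss / s2e + (n - p) * np.log(2 * np.pi)
    )
    return ll, beta, s2e


def grid_search_reml(y, X, groups):
    """Three-stage grid refinement over lambda in [1e-6, 1e6]."""
    lo, hi = -6.0, 6.0
    best = None
    for _ in range(3):
        grid = np.logspace(lo, hi, 400)
        lls = [dense_reml_loglik(l, y, X, groups)[0] for l in grid]
        k = int(np.argmax(lls))
        best = grid[k]
        lo = np.log10(grid[max(k - 1, 0)])
        hi = np.log10(grid[min(k + 1, len(grid) - 1)])
    ll, beta, s2e = dense_reml_loglik(best, y, X, groups)
    return {"lambda": best, "beta": beta, "sigma2_e": s2e, "sigma2_b": best * s2e}


@pytest.mark.parametrize("seed,sigma_b", [(11, 1.5), (12, 0.3)])
def test_reml_matches_grid_search_oracle(seed, sigma_b):
    """Profiled-likelihood optimum agrees with brute-force grid REML on a
    small fixture (beta to 4 significant figures, variances to 3)."""
    rng = np.random.default_rng(seed)
    n_g, n_i = 3, 4
    groups = np.repeat(np.arange(n_g), n_i)
    x = rng.normal(size=n_g * n_i)
    y = 1.0 + 0.8 * x + np.repeat(rng.normal(0, sigma_b, n_g), n_i) + rng.normal(0, 1.0, n_g * n_i)
    X = pd.DataFrame({"intercept": 1.0, "x": x})
    res = RandomInterceptLMM(y, X, groups).fit()
    oracle = grid_search_reml(y, X.to_numpy(), groups)
    np.testing.assert_allclose(res.params.to_numpy(), oracle["beta"], rtol=1e-4)
    assert res.sigma2_e == pytest.approx(oracle["sigma2_e"], rel=1e-3)
    assert res.sigma2_b == pytest.approx(oracle["sigma2_b"], rel=1e-3, abs=1e-6)


def test_reml_matches_statsmodels(small_lmm_data):
    """Estimates, SEs, variance components and restricted log-likelihood
    agree with the independent MixedLM implementation."""
    sm = pytest.importorskip("statsmodels.api")
    y, X, groups = small_lmm_data
    res = RandomInterceptLMM(y, X, groups).fit()
    ref = sm.MixedLM(y, X.to_numpy(), groups=groups).fit(reml=True)
    np.testing.assert_allclose(res.params.to_numpy(), ref.fe_params, rtol=1e-5)
    # MixedLM reports Hessian-based SEs, slightly off the plug-in GLS form
    np.testing.assert_allclose(res.bse.to_numpy(), ref.bse_fe, rtol=5e-3)
    assert res.sigma2_b == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-4)
    assert res.sigma2_e == pytest.approx(ref.scale, rel=1e-4)
    assert res.reml_loglik == pytest.approx(ref.llf, abs=1e-5)
    ref_ml = sm.MixedLM(y, X.to_numpy(), groups=groups).fit(reml=False)
    assert res.loglik_ml == pytest.approx(ref_ml.llf, abs=1e-4)


def test_boundary_fit_equals_ols_exactly():
    """When the group means carry no extra variance the REML estimate sits on
    the sigma_b^2 = 0 boundary and the fit is exactly ordinary least squares."""
    rng = np.random.default_rng(5)
    n_g, n_i = 8, 5
    groups = np.repeat(np.arange(n_g), n_i)
    x = rng.normal(size=n_g * n_i)
    e = rng.normal(size=n_g * n_i)
    # remove all between-group residual variation
    e -= pd.Series(e).groupby(groups).transform("mean").to_numpy()
    x -= pd.Series(x).groupby(groups).transform("mean").to_numpy()
    y = 2.0 + 0.5 * x + e
    X = pd.DataFrame({"intercept": 1.0, "x": x})
    res = RandomInterceptLMM(y, X, groups).fit()
    assert res.sigma2_b == 0.0
    beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    np.testing.assert_allclose(res.params.to_numpy(), beta_ols, rtol=1e-10)


def test_single_observation_per_group_falls_back_to_ols():
    rng = np.random.default_rng(9)
    n = 30
    x = rng.normal(size=n)
    y = 1.0 + x + rng.normal(size=n)
    X = pd.DataFrame({"intercept": 1.0, "x": x})
    with pytest.warns(UserWarning, match="one observation per group"):
        res = RandomInterceptLMM(y, X, np.arange(n)).fit()
    assert res.sigma2_b == 0.0
    beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    np.testing.assert_allclose(res.params.to_numpy(), beta_ols, rtol=1e-10)


def test_parameter_recovery_large_sample():
    """With many groups the estimates land within 2 SE of the truth."""
    rng = np.random.default_rng(100)
    n_g, n_i = 120, 10
    groups = np.repeat(np.arange(n_g), n_i)
    x = rng.normal(size=n_g * n_i)
    y = 3.0 - 1.2 * x + np.repeat(rng.normal(0, 2.0, n_g), n_i) + rng.normal(0, 1.0, n_g * n_i)
    res = RandomInterceptLMM(y, pd.DataFrame({"intercept": 1.0, "x": x}), groups).fit()
    assert abs(res.params["x"] - (-1.2)) < 2 * res.bse["x"]
    assert abs(res.params["intercept"] - 3.0) < 2 * res.bse["intercept"]
    assert res.sigma2_b == pytest.approx(4.0, rel=0.4)
    assert res.sigma2_e == pytest.approx(1.0, rel=0.15)


# ---------------------------------------------------------------------------
# Inference on the fitted object
# ---------------------------------------------------------------------------

def _manual_results(params, cov, sigma2_b, sigma2_e, y, X, groups):
    model = RandomInterceptLMM(y, X, groups)
    labels, sizes = np.unique(groups, return_counts=True)
    return RandomInterceptLMMResults(
        model=model,
        params=pd.Series(params, index=X.columns),
        cov_params_=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        sigma2_b=sigma2_b, sigma2_e=sigma2_e,
        lambda_=sigma2_b / sigma2_e if sigma2_e else 0.0,
        reml_loglik=0.0, group_labels=labels, group_sizes=sizes,
    )


def test_wald_z_and_pvalues():
    y = np.array([0.0, 0.0, 0.0, 0.0])
    X = pd.DataFrame({"b": [1.0, 1.0, 1.0, 1.0]})
    groups = np.array(["a", "a", "b", "b"])
    # reported scala-tympani contrast: -8.50 with SE 1.97 is significant
    res = _manual_results([-8.50], [[1.97**2]], 1.0, 1.0, y, X, groups)
    w = res.wald_test("b")
    assert w.z == pytest.approx(-4.31, abs=0.01)
    assert w.pvalue < 0.01
    # a null coefficient has p = 1
    res0 = _manual_results([0.0], [[1.0]], 1.0, 1.0, y, X, groups)
    assert res0.wald_test("b").pvalue == pytest.approx(1.0)
    # the 1.96 SE boundary sits at p ~ 0.05
    res196 = _manual_results([1.96], [[1.0]], 1.0, 1.0, y, X, groups)
    assert res196.wald_test("b").pvalue == pytest.approx(0.05, abs=1e-3)


def test_wald_unknown_coefficient():
    y = np.zeros(4)
    X = pd.DataFrame({"b": np.ones(4)})
    res = _manual_results([0.0], [[1.0]], 1.0, 1.0, y, X, ["a", "a", "b", "b"])
    with pytest.raises(KeyError):
        res.wald_test("nope")


def test_wald_p_invariant_to_covariate_rescaling(small_lmm_data):
    y, X, groups = small_lmm_data
    res1 = RandomInterceptLMM(y, X, groups).fit()
    X2 = X.copy()
    X2["x1"] = X2["x1"] * 1000.0
    res2 = RandomInterceptLMM(y, X2, groups).fit()
    w1, w2 = res1.wald_test("x1"), res2.wald_test("x1")
    assert w1.pvalue == pytest.approx(w2.pvalue, rel=1e-6)
    assert res2.params["x1"] == pytest.approx(res1.params["x1"] / 1000.0, rel=1e-6)


def test_bic_arithmetic_and_penalty_direction(small_lmm_data):
    y, X, groups = small_lmm_data
    res = RandomInterceptLMM(y, X, groups).fit()
    k = res.k_fe + 2
    assert res.bic == pytest.approx(-2 * res.loglik_ml + k * np.log(res.nobs))
    # identical fits give identical BIC
    res_b = RandomInterceptLMM(y, X, groups).fit()
    assert res.bic == res_b.bic


def test_pure_noise_covariate_raises_bic(small_lmm_data):
    y, X, groups = small_lmm_data
    rng = np.random.default_rng(21)
    raised = 0
    n_try = 10
    for _ in range(n_try):
        X2 = X.copy()
        X2["noise"] = rng.normal(size=len(X))
        if RandomInterceptLMM(y, X2, groups).fit().bic > RandomInterceptLMM(y, X, groups).fit().bic:
            raised += 1
    assert raised >= 8  # BIC penalises an uninformative covariate


def test_predict_center_and_extrapolation_width(small_lmm_data):
    y, X, groups = small_lmm_data
    res = RandomInterceptLMM(y, X, groups).fit()
    pred = res.predict(X)
    np.testing.assert_allclose(pred["mean"], res.fittedvalues)
    assert np.all(pred["lower95"] <= pred["mean"])
    assert np.all(pred["mean"] <= pred["upper95"])
    # band widens outside the observed covariate range
    inside = pd.DataFrame({"intercept": [1.0], "x1": [0.0], "x2": [0.0]})
    outside = pd.DataFrame({"intercept": [1.0], "x1": [15.0], "x2": [0.0]})
    w_in = res.predict(inside)
    w_out = res.predict(outside)
    assert (w_out["upper95"] - w_out["lower95"]).iloc[0] > (w_in["upper95"] - w_in["lower95"]).iloc[0]


def test_predict_zero_design_row():
    y = np.arange(6, dtype=float)
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    res = RandomInterceptLMM(y, X, ["a"] * 3 + ["b"] * 3).fit()
    pred = res.predict(pd.DataFrame({"x": [0.0]}))
    assert pred["mean"].iloc[0] == 0.0
    assert pred["upper95"].iloc[0] - pred["lower95"].iloc[0] == pytest.approx(0.0)


def test_predict_column_mismatch(small_lmm_data):
    y, X, groups = small_lmm_data
    res = RandomInterceptLMM(y, X, groups).fit()
    with pytest.raises(ValueError, match="column"):
        res.predict(X[["x1", "intercept", "x2"]])


def test_blup_hand_shrinkage():
    """Two subjects, two observations each, sigma_b^2 = sigma_e^2 = 1:
    the BLUP is 2/3 of the subject-mean residual."""
    y = np.array([1.0, 1.0, -1.0, -1.0])
    X = pd.DataFrame({"intercept": np.ones(4)})
    res = _manual_results([0.0], [[1.0]], 1.0, 1.0, y, X, ["a", "a", "b", "b"])
    blups = res.random_effects
    assert blups["a"] == pytest.approx(2.0 / 3.0)
    assert blups["b"] == pytest.approx(-2.0 / 3.0)


def test_blup_zero_variance_all_zero():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    X = pd.DataFrame({"intercept": np.ones(4)})
    res = _manual_results([2.5], [[1.0]], 0.0, 1.0, y, X, ["a", "a", "b", "b"])
    assert (res.random_effects == 0.0).all()


def test_blup_large_group_approaches_mean_residual():
    n = 2000
    y = np.r_[np.full(n, 1.0), np.full(n, -1.0)]
    X = pd.DataFrame({"intercept": np.ones(2 * n)})
    res = _manual_results([0.0], [[1.0]], 1.0, 1.0, y, X, ["a"] * n + ["b"] * n)
    assert res.random_effects["a"] == pytest.approx(1.0, abs=1e-3)


def test_conditional_residuals_center_per_subject(small_lmm_data):
    y, X, groups = small_lmm_data
    res = RandomInterceptLMM(y, X, groups).fit()
    r = pd.Series(res.resid_conditional).groupby(pd.Series(groups)).mean()
    # BLUP shrinkage leaves a small per-subject remainder, near zero
    assert np.abs(r).max() < 0.2


# ---------------------------------------------------------------------------
# Validation errors
# ---------------------------------------------------------------------------

def test_rank_deficiency_names_aliased_columns(small_lmm_data):
    y, X, groups = small_lmm_data
    X2 = X.copy()
    X2["x1_copy"] = X2["x1"]
    with pytest.raises(ValueError, match="x1_copy"):
        RandomInterceptLMM(y, X2, groups)


def test_duplicate_column_names_rejected(small_lmm_data):
    y, X, groups = small_lmm_data
    X2 = X.copy()
    X2.columns = ["intercept", "x1", "x1"]
    with pytest.raises(ValueError, match="unique"):
        RandomInterceptLMM(y, X2, groups)


def test_missing_values_rejected(small_lmm_data):
    y, X, groups = small_lmm_data
    X2 = X.copy()
    X2.iloc[0, 1] = np.nan
    with pytest.raises(ValueError, match="missing"):
        RandomInterceptLMM(y, X2, groups)


def test_single_group_rejected():
    y = np.arange(4, dtype=float)
    X = pd.DataFrame({"intercept": np.ones(4), "x": [0.0, 1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="two groups"):
        RandomInterceptLMM(y, X, ["a"] * 4).fit()


def test_summary_renders(small_lmm_data):
    y, X, groups = small_lmm_data
    text = RandomInterceptLMM(y, X, groups).fit().summary()
    assert "sigma_b^2" in text and "x1" in text
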