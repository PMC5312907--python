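"""OLS fitting, the statistics suite, and leave-one-out cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import loo_refit_press
from nanodisp.regression import (
    DispersibilityMLR,
    correlation_matrix,
    fit_ols,
    loo_crossvalidate,
    predict,
)


@pytest.fixture(scope="module")
def random_problem():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(20, 3))
    y = X @ [1.5, -0.7, 0.2] + rng.normal(scale=0.5, size=20) + 3.0
    return X, y


def test_coefficients_match_normal_equations(random_problem):
    X, y = random_problem
    res = fit_ols(X, y)
    design = np.column_stack([X, np.ones(len(y))])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)


def test_statistics_match_statsmodels(random_problem):
    import statsmodels.api as sm

    X, y = random_problem
    res = fit_ols(X, y)
    ref = sm.OLS(y, sm.add_constant(X)).fit()
    assert res.rsquared == pytest.approx(ref.rsquared, abs=1e-12)
    assert res.fvalue == pytest.approx(ref.fvalue, rel=1e-10)
    assert res.f_pvalue == pytest.approx(ref.f_pvalue, rel=1e-8)
    # statsmodels params order: const first
    assert np.allclose(res.params.to_numpy()[:-1], ref.params[1:], atol=1e-10)
    assert np.allclose(res.bse.to_numpy()[:-1], ref.bse[1:], atol=1e-10)


def test_perfect_fit_degenerates_cleanly():
    X = np.arange(10.0)[:, None]
    res = fit_ols(X, 2.0 * X.ravel() + 1.0)
    assert res.rsquared == pytest.approx(1.0)
    assert res.s == pytest.approx(0.0, abs=1e-10)


def test_single_descriptor_training_fit(train_frame):
    """The packaged SRW09-only model reproduces the published statistics."""
    res = DispersibilityMLR.from_dataframe(train_frame, "LogC", ["SRW09"]).fit()
    assert res.params["SRW09"] == pytest.approx(0.0020, abs=1e-4)
    assert res.intercept == pytest.approx(-2.1522, abs=0.01)
    assert res.rsquared == pytest.approx(0.548, abs=0.01)
    assert res.loo.q2 == pytest.approx(0.453, abs=0.01)
    assert res.fvalue == pytest.approx(24.249, abs=0.5)
    assert res.f_pvalue < 1e-3
    # published halfwidths are 95% CI halfwidths
    assert res.halfwidths["SRW09"] == pytest.approx(0.0008, abs=1e-4)
    assert res.halfwidths["intercept"] == pytest.approx(0.3620, abs=0.01)


def test_f_statistic_identity(train_frame):
    res = DispersibilityMLR.from_dataframe(train_frame, "LogC", ["SRW09"]).fit()
    r2, p, n = res.rsquared, 1, res.nobs
    assert res.fvalue == pytest.approx((r2 / p) / ((1 - r2) / (n - p - 1)), rel=5e-3)


def test_r2_equals_squared_pearson_of_fit(train_frame):
    for cols in (["SRW09"], ["Ram", "piPC05", "DipoleZ"]):
        res = DispersibilityMLR.from_dataframe(train_frame, "LogC", cols).fit()
        r = np.corrcoef(train_frame["LogC"], res.fittedvalues)[0, 1]
        assert res.rsquared == pytest.approx(r**2, abs=1e-12)


def test_rank_deficient_design_names_columns(train_frame):
    df = train_frame.copy()
    df["SRW09_copy"] = df["SRW09"]
    with pytest.raises(ValueError, match="SRW09"):
        DispersibilityMLR.from_dataframe(df, "LogC", ["SRW09", "SRW09_copy"]).fit()


def test_loo_hat_shortcut_equals_refit_loop(random_problem, train_frame):
    X, y = random_problem
    stats = loo_crossvalidate(X, y)
    assert stats.press == pytest.approx(loo_refit_press(X, y), abs=1e-10)
    Xt = train_frame[["SRW09", "ATS6m", "X0Av", "DipoleZ"]].to_numpy()
    yt = train_frame["LogC"].to_numpy()
    assert loo_crossvalidate(Xt, yt).press == pytest.approx(
        loo_refit_press(Xt, yt), abs=1e-10
    )


def test_loo_perfect_data():
    X = np.arange(12.0)[:, None]
    stats = loo_crossvalidate(X, 3.0 * X.ravel() - 1.0)
    assert stats.press == pytest.approx(0.0, abs=1e-18)
    assert stats.q2 == pytest.approx(1.0)


def test_loo_df_conventions(train_frame):
    Xt, yt = train_frame[["SRW09"]], train_frame["LogC"]
    n, p = len(yt), 1
    default = loo_crossvalidate(Xt, yt)  # sdep denominator n-1
    assert default.spress == pytest.approx(np.sqrt(default.press / (n - p - 1)))
    assert default.sdep == pytest.approx(np.sqrt(default.press / (n - 1)))
    alt = loo_crossvalidate(Xt, yt, sdep_df="n")
    assert alt.sdep == pytest.approx(np.sqrt(default.press / n))


def test_loo_requires_enough_rows():
    with pytest.raises(ValueError, match="n >= p\\+3"):
        loo_crossvalidate(np.ones((3, 2)), np.arange(3.0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.01, 100.0),
    shift=st.floats(-50.0, 50.0),
    seed=st.integers(0, 2**16),
)
def test_affine_rescaling_invariance(scale, shift, seed):
    """Rescaling a predictor leaves R2/Q2/F/s unchanged, rescales its slope."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(15, 2))
    y = X @ [2.0, -1.0] + rng.normal(scale=0.3, size=15)
    base = fit_ols(X, y)
    X2 = X.copy()
    X2[:, 0] = X2[:, 0] * scale + shift
    scaled = fit_ols(X2, y)
    assert scaled.rsquared == pytest.approx(base.rsquared, rel=1e-9)
    assert scaled.fvalue == pytest.approx(base.fvalue, rel=1e-9)
    assert scaled.s == pytest.approx(base.s, rel=1e-9)
    assert scaled.loo.q2 == pytest.approx(base.loo.q2, rel=1e-8)
    assert scaled.params.iloc[0] == pytest.approx(base.params.iloc[0] / scale, rel=1e-8)


def test_q2_below_r2_on_packaged_fits(frame, train_frame):
    for cols in (["SRW09"], ["SRW09", "DipoleZ"], ["SRW09", "ATS6m", "X0Av", "DipoleZ"]):
        res = DispersibilityMLR.from_dataframe(train_frame, "LogC", cols).fit()
        assert res.loo.q2 <= res.rsquared


def test_correlation_matrix_properties(frame):
    cols = frame.drop(columns="split")
    corr = correlation_matrix(cols)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)
    assert (corr.abs().to_numpy() <= 1 + 1e-12).all()
    assert corr.attrs["zero_variance"] == []


def test_correlation_matrix_flags_zero_variance():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    corr = correlation_matrix(df)
    assert corr.attrs["zero_variance"] == ["b"]
    assert np.isnan(corr.loc["a", "b"])


def test_correlation_of_anticorrelated_pair():
    x = np.array([1.0, 2.0, 5.0, 7.0])
    corr = correlation_matrix(pd.DataFrame({"x": x, "negx": -x}))
    assert corr.loc["x", "negx"] == pytest.approx(-1.0)


def test_predict_paths(train_frame):
    res = DispersibilityMLR.from_dataframe(train_frame, "LogC", ["SRW09"]).fit()
    # all-zero descriptor row predicts the intercept
    assert predict(res, np.zeros((1, 1)))[0] == pytest.approx(res.intercept)
    # refitting training rows reproduces fitted values
    assert np.allclose(res.predict(train_frame[["SRW09"]]), res.fittedvalues, atol=1e-12)
    with pytest.raises(KeyError, match="SRW09"):
        res.predict(train_frame[["Ram"]].rename(columns={"Ram": "other"}))


def test_summary_prints_equation(train_frame):
    res = DispersibilityMLR.from_dataframe(train_frame, "LogC", ["SRW09"]).fit()
    text = res.summary()
    assert "SRW09" in text and "R²" in text and "Q²" in text
    assert "+0.0020" in text
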