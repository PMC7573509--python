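"""Design construction and the cusp polynomial regression."""

import numpy as np
import pandas as pd
import pytest

from cuspshift.polyreg import (
    CuspPolynomialRegression,
    DegenerateInputError,
    LinearBaselineRegression,
    SingularDesignError,
    build_design,
    fit_cusp_model,
    fit_linear_model,
    make_z,
    ols_fit,
    residualized_change,
)
from cuspshift.simulate import SimConfig, gen_linear_panel, simulate_panel
from .conftest import random_panel


# ---------------------------------------------------------------------------
# residualized change and z terms
# ---------------------------------------------------------------------------

def test_residualized_change_examples():
    early = np.array([1.0, 2.0, 3.0])
    assert np.allclose(residualized_change(early, 2 * early), 0.0, atol=1e-12)
    # cov(early, late) = 0 -> slope 0, residuals are the centered late values
    late = np.array([1.0, -2.0, 1.0])
    assert np.allclose(residualized_change(early, late), [1.0, -2.0, 1.0])


def test_residualized_change_orthogonality_and_zero_mean():
    rng = np.random.default_rng(0)
    early, late = rng.normal(size=(2, 500))
    r = residualized_change(early, late)
    assert abs(r.mean()) < 1e-12
    assert abs(np.corrcoef(r, early)[0, 1]) < 1e-12


def test_residualized_change_constant_early_raises():
    with pytest.raises(DegenerateInputError):
        residualized_change(np.ones(5), np.arange(5.0))


def test_make_z_construction_invariants():
    assert np.allclose(make_z(np.array([2.0, 4.0, 6.0])), [0.0, 1.0, 2.0])
    rng = np.random.default_rng(1)
    x = rng.normal(size=10_000)
    z = make_z(x)
    assert z.min() == 0.0
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(z, (x - x.min()) / x.std(ddof=1))
    with pytest.raises(DegenerateInputError):
        make_z(np.full(5, 2.0))


def test_build_design_shape_and_invariants(toy_roles):
    rng = np.random.default_rng(2)
    panel = random_panel(rng, n=60)
    design = build_design(panel, toy_roles)
    f = design.frame
    assert list(f.columns) == ["dv", "z", "z2", "z3", "bif", "loss_t1"]
    assert f["z"].min() == pytest.approx(0.0, abs=1e-12)
    assert f["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    assert abs(f["dv"].mean()) < 1e-9
    early = f.attrs["earlier_state"]
    assert abs(np.corrcoef(f["dv"], early)[0, 1]) < 1e-9
    assert np.allclose(f["z2"], f["z"] ** 2)
    assert np.allclose(f["z3"], f["z"] ** 3)
    # bif equals the elementwise product recomputed from raw columns
    cse = panel.data.loc[f.index, "cse_t1"].to_numpy(dtype=float)
    assert np.allclose(f["bif"], f["z"].to_numpy() * cse)


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def pinv_ols_oracle(X, y):
    """Independent normal-equation solution with classical SEs."""
    A = np.column_stack([np.ones(len(X)), X])
    coef = np.linalg.pinv(A.T @ A) @ A.T @ y
    resid = y - A @ coef
    rss = float(resid @ resid)
    df = A.shape[0] - A.shape[1]
    se = np.sqrt(np.diag(np.linalg.pinv(A.T @ A)) * rss / df)
    return coef, se, rss


def test_ols_matches_pseudoinverse_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        res = ols_fit(pd.DataFrame(X, columns=list("abcde")), y)
        coef, se, rss = pinv_ols_oracle(X, y)
        assert np.allclose(res.coef, coef, atol=1e-8)
        assert np.allclose(res.se, se, atol=1e-8)
        assert res.rss == pytest.approx(rss, abs=1e-8)


def test_ols_orthonormal_design_exact():
    q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(50, 3)))
    y = q[:, 0].copy()
    res = ols_fit(pd.DataFrame(q, columns=["a", "b", "c"]), y, add_intercept=False)
    assert np.allclose(res.coef, [1.0, 0.0, 0.0], atol=1e-12)
    assert res.rss == pytest.approx(0.0, abs=1e-20)


def test_ols_single_standardized_predictor_equals_pearson_r():
    rng = np.random.default_rng(5)
    x = rng.normal(size=200)
    y = 0.6 * x + rng.normal(size=200)
    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    res = ols_fit(pd.DataFrame({"x": xs}), ys)
    assert res.coef[1] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


def test_ols_rank_deficiency_names_columns():
    rng = np.random.default_rng(6)
    x = rng.normal(size=80)
    X = pd.DataFrame({"z2": x, "z3": x})  # duplicated column
    with pytest.raises(SingularDesignError, match="z"):
        ols_fit(X, rng.normal(size=80))


# ---------------------------------------------------------------------------
# model fitting and pruning
# ---------------------------------------------------------------------------

def _toy_design_frame(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "z3": rng.normal(size=n),
            "z2": rng.normal(size=n),
            "bif": rng.normal(size=n),
            "loss": rng.normal(size=n),
            "noisevar": rng.normal(size=n),
        }
    )
    y = 0.5 * X["z2"] - 0.5 * X["bif"] + 0.4 * X["loss"] + rng.normal(size=n)
    return X, y.to_numpy()


def test_pruning_drops_z3_first_then_weakest_covariates():
    X, y = _toy_design_frame()
    est = CuspPolynomialRegression().fit(X, y)
    fit = est.fit_
    dropped = [e["term"] for e in fit.pruning_log]
    assert dropped[0] == "z3"
    assert "noisevar" in dropped
    assert {"z2", "bif"} <= set(fit.pvalues)
    assert "z3" not in fit.pvalues
    # retained true covariate
    assert "loss" in fit.pvalues


def test_pruning_is_deterministic():
    X, y = _toy_design_frame(seed=8)
    f1 = CuspPolynomialRegression().fit(X, y).fit_
    f2 = CuspPolynomialRegression().fit(X, y).fit_
    assert f1.pruning_log == f2.pruning_log
    assert f1.coef == f2.coef


def test_standardized_coefficients_invariant_to_column_scaling():
    X, y = _toy_design_frame(seed=9)
    f1 = CuspPolynomialRegression().fit(X, y).fit_
    X2 = X.copy()
    X2["loss"] = X2["loss"] * 37.0
    f2 = CuspPolynomialRegression().fit(X2, 5.0 * y).fit_
    for t in f1.coef:
        assert f1.coef[t] == pytest.approx(f2.coef[t], abs=1e-9)
        assert f1.pvalues[t] == pytest.approx(f2.pvalues[t], abs=1e-9)


def test_estimator_sklearn_contract():
    X, y = _toy_design_frame(seed=10)
    est = CuspPolynomialRegression(alpha_level=0.1)
    assert est.get_params()["alpha_level"] == 0.1
    est.set_params(alpha_level=0.05).fit(X, y)
    pred = est.predict(X)
    assert pred.shape == y.shape
    assert np.corrcoef(pred, y)[0, 1] > 0.3


def test_fit_linear_model_zero_noise_perfect_fit(study1_small):
    cfg = study1_small
    cfg.linear.noise = 0.0
    cfg.linear.c2 = -0.05
    cfg.linear.c3 = 0.1
    # baseline independent of the covariates, so the residualized change is an
    # exact linear function of the predictors the model actually has
    cfg.linear.distress.loading = 0.0
    panel = gen_linear_panel(cfg, 11)
    from cuspshift.experiments import contrast_roles

    roles = contrast_roles("study1", ("T1", "T2"))
    fit = fit_linear_model(panel, roles)
    # dv is linear in cse and loss up to the O(1/n) finite-sample projection
    # of the baseline onto the covariates inside the residualization
    assert fit.r2 > 0.999
    assert fit.rss < 1e-3 * fit.n


def test_saturated_null_pvalues_uniform():
    """dv independent of all predictors -> p-values uniform on [0, 1]."""
    from scipy.stats import kstest

    rng = np.random.default_rng(12)
    pvals = []
    for _ in range(400):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["z3", "z2", "bif"])
        y = rng.normal(size=40)
        fit = CuspPolynomialRegression(prune=False).fit(X, y).fit_
        pvals.extend(fit.pvalues[t] for t in ("z3", "z2", "bif"))
    assert kstest(pvals, "uniform").pvalue > 0.01
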