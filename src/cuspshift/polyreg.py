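"""Cusp-catastrophe polynomial regression on residualized change scores.

The estimation core: from two waves of a panel, build the cusp design

    dv  = residuals of OLS(later-wave state ~ earlier-wave state)
    z   = (earlier-wave state - min) / SD          (min 0, sample SD 1)
    z2, z3 = z**2, z**3
    bif = z * bifurcation variable                 (the cusp interaction)
    asymmetry covariates carried through unchanged

and fit ``dv ~ 1 + z3 + z2 + bif + asymmetry...`` by OLS with all columns
z-standardized, so coefficients are standardized betas. Pruning follows the
published procedure: a non-significant cubic term is dropped first, then
non-significant asymmetry covariates one at a time (largest p first); the
quadratic term and the bifurcation product are always retained so the cusp
hypothesis stays evaluable. A plain linear baseline (no z terms, no
product) is fitted on the same dv for model comparison.

`CuspPolynomialRegression` and `LinearBaselineRegression` are
scikit-learn-compatible estimators; the module-level functions are thin
wrappers over them. Column names are meaningful to the cusp estimator:
``z3``, ``z2`` and ``bif`` are the state/bifurcation terms, every other
column is treated as an asymmetry covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .panel import PanelDataset, PanelSchemaError, VariableRoles
from .selection import aic as _aic, bic as _bic, adjusted_r2 as _adjusted_r2

__all__ = [
    "CuspDesign",
    "CuspFit",
    "OLSResult",
    "SingularDesignError",
    "DegenerateInputError",
    "residualized_change",
    "make_z",
    "build_design",
    "ols_fit",
    "CuspPolynomialRegression",
    "LinearBaselineRegression",
    "fit_cusp_model",
    "fit_linear_model",
]

STATE_TERMS = ("z3", "z2")
BIF_TERM = "bif"


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


class DegenerateInputError(ValueError):
    """Constant or too-short input where variation is required."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def residualized_change(y_early: np.ndarray, y_late: np.ndarray) -> np.ndarray:
    """Residuals of OLS (with intercept) of the later on the earlier wave.

    The result has mean exactly zero and is orthogonal to ``y_early``; it is
    the baseline-adjusted change score used as the dependent variable.
    """
    y_early = np.asarray(y_early, dtype=float)
    y_late = np.asarray(y_late, dtype=float)
    if y_early.shape != y_late.shape or y_early.ndim != 1 or len(y_early) < 3:
        raise ValueError("y_early and y_late must be equal-length vectors, n >= 3")
    dx = y_early - y_early.mean()
    sxx = dx @ dx
    if sxx == 0.0:
        raise DegenerateInputError("earlier-wave state is constant")
    slope = (dx @ (y_late - y_late.mean())) / sxx
    resid = y_late - y_late.mean() - slope * dx
    return resid - resid.mean()  # exact zero mean against rounding


def make_z(x: np.ndarray) -> np.ndarray:
    """State term ``z = (x - min(x)) / SD(x)`` with sample SD (n-1).

    By construction min(z) = 0 and SD(z) = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("x must be a vector of length >= 3")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("state vector is constant (zero SD)")
    return (x - x.min()) / sd


@dataclass
class CuspDesign:
    """Regression columns for one wave-pair contrast, before standardization.

    ``frame`` holds dv, z, z2, z3, bif and one column per asymmetry
    variable, on complete cases only; ``term_roles`` maps fitted term names
    to their cusp roles.
    """

    frame: pd.DataFrame
    roles: VariableRoles
    n: int
    term_roles: Dict[str, str]

    @property
    def dv(self) -> np.ndarray:
        return self.frame["dv"].to_numpy()

    def predictors(self, include_z3: bool = True) -> pd.DataFrame:
        cols = (["z3"] if include_z3 else []) + ["z2", "bif"] + list(self.roles.asymmetry)
        return self.frame[cols]


def _complete_cases(panel: PanelDataset, columns: Sequence[str]) -> pd.DataFrame:
    df = panel.data[list(columns)].apply(pd.to_numeric, errors="coerce")
    return df.dropna()


def _resolve_role_columns(panel: PanelDataset, roles: VariableRoles) -> Tuple[str, str, str, List[str]]:
    early, late = roles.wave_pair
    col_early = panel.column(roles.state, early)
    col_late = panel.column(roles.state, late)
    for name in (roles.bifurcation, *roles.asymmetry):
        if name not in panel.data.columns:
            raise PanelSchemaError(f"role variable {name!r} not in panel")
    return col_early, col_late, roles.bifurcation, list(roles.asymmetry)


def build_design(panel: PanelDataset, roles: VariableRoles) -> CuspDesign:
    """Build the cusp design for one contrast on complete cases.

    Binary asymmetry columns (e.g. gender) are assumed pre-coded 0/1; all
    fitting-time standardization happens inside the estimators, so the
    stored columns keep their construction-time invariants (min(z) = 0,
    SD(z) = 1, mean(dv) = 0, dv orthogonal to the earlier-wave state).
    """
    col_early, col_late, bif_var, asym = _resolve_role_columns(panel, roles)
    df = _complete_cases(panel, [col_early, col_late, bif_var] + asym)
    if len(df) < 3:
        raise DegenerateInputError("fewer than 3 complete cases for this contrast")
    dv = residualized_change(df[col_early].to_numpy(), df[col_late].to_numpy())
    z = make_z(df[col_early].to_numpy())
    out = pd.DataFrame(index=df.index)
    out["dv"] = dv
    out["z"] = z
    out["z2"] = z**2
    out["z3"] = z**3
    out["bif"] = z * df[bif_var].to_numpy()
    for name in asym:
        out[name] = df[name].to_numpy()
    term_roles = {"z3": "state", "z2": "state", "bif": "bifurcation"}
    term_roles.update({name: "asymmetry" for name in asym})
    out.attrs["earlier_state"] = df[col_early].to_numpy()
    return CuspDesign(frame=out, roles=roles, n=len(out), term_roles=term_roles)


# ---------------------------------------------------------------------------
# OLS with inference
# ---------------------------------------------------------------------------

@dataclass
class OLSResult:
    terms: List[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    rss: float
    n: int
    df_resid: int
    r2: float


def _name_collinear(X: pd.DataFrame) -> List[str]:
    # columns loading on the smallest singular vector of the centered design
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    v = np.abs(vt[-1])
    return [c for c, w in zip(X.columns, v) if w > 0.3]


def ols_fit(X: pd.DataFrame, y: np.ndarray, add_intercept: bool = True) -> OLSResult:
    """Least squares with classical inference (wraps statsmodels OLS).

    SEs come from sigma2 * (X'X)^-1 with sigma2 = RSS/(n-k); p-values are
    two-sided t with n-k degrees of freedom. Rank deficiency raises
    `SingularDesignError` naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X, prepend=True, has_constant="add") if add_intercept else X
    A = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design; collinear columns: {_name_collinear(X)}"
        )
    if A.shape[0] <= A.shape[1]:
        raise SingularDesignError("need n > number of parameters")
    res = sm.OLS(y, design).fit()
    terms = ["intercept"] + list(X.columns) if add_intercept else list(X.columns)
    return OLSResult(
        terms=terms,
        coef=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        rss=float(res.ssr),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
        r2=float(res.rsquared),
    )


def _gaussian_loglik(rss: float, n: int) -> float:
    # full-constant Gaussian log-likelihood at the MLE sigma2 = RSS/n
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class CuspFit:
    """Standardized-coefficient fit of one model (cusp or linear baseline)."""

    terms: List[str]
    coef: Dict[str, float]
    se: Dict[str, float]
    pvalues: Dict[str, float]
    n: int
    k: int  # estimated parameters: coefficients incl. intercept, plus sigma2
    rss: float
    loglik: float
    aic: float
    bic: float
    r2: float
    adj_r2: float
    pruning_log: List[Dict[str, float]] = field(default_factory=list)
    term_roles: Dict[str, str] = field(default_factory=dict)

    def significant(self, term: str, alpha_level: float = 0.05) -> bool:
        return term in self.pvalues and self.pvalues[term] < alpha_level

    def to_dict(self) -> dict:
        return asdict(self)


def _standardize(v: np.ndarray, label: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError(f"column {label!r} is constant; cannot standardize")
    return (v - v.mean()) / sd


def _fit_from_ols(res: OLSResult, term_roles: Dict[str, str],
                  pruning_log: List[Dict[str, float]]) -> CuspFit:
    ll = _gaussian_loglik(res.rss, res.n)
    k = len(res.terms) + 1  # + error variance
    names = res.terms
    return CuspFit(
        terms=names,
        coef=dict(zip(names, res.coef.tolist())),
        se=dict(zip(names, res.se.tolist())),
        pvalues=dict(zip(names, res.pvalues.tolist())),
        n=res.n,
        k=k,
        rss=res.rss,
        loglik=ll,
        aic=_aic(ll, k),
        bic=_bic(ll, k, res.n),
        r2=res.r2,
        adj_r2=_adjusted_r2(res.r2, res.n, len(res.terms)),
        pruning_log=pruning_log,
        term_roles={"intercept": "intercept", **term_roles},
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _StandardizedOLSBase(BaseEstimator, RegressorMixin):
    """Shared machinery: z-standardize X and y, fit OLS, expose a CuspFit."""

    def _prepare(self, X: pd.DataFrame, y) -> Tuple[pd.DataFrame, np.ndarray]:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in range(np.shape(X)[1])])
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        self.x_mean_ = X.mean()
        self.x_sd_ = X.std(ddof=1)
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std(ddof=1))
        Xs = pd.DataFrame(
            {c: _standardize(X[c].to_numpy(dtype=float), c) for c in X.columns},
            index=X.index,
        )
        ys = _standardize(y, "dv")
        return Xs, ys

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise AttributeError("estimator is not fitted")
        Xs = (X[self.feature_names_in_] - self.x_mean_[self.feature_names_in_]) / \
            self.x_sd_[self.feature_names_in_]
        coef = np.array([self.fit_.coef[t] for t in self.fit_.terms if t != "intercept"])
        cols = [t for t in self.fit_.terms if t != "intercept"]
        ys = self.fit_.coef.get("intercept", 0.0) + Xs[cols].to_numpy() @ coef
        return self.y_mean_ + self.y_sd_ * ys


class CuspPolynomialRegression(_StandardizedOLSBase):
    """Polynomial-regression cusp model with term pruning.

    Fit ``dv ~ 1 + z3 + z2 + bif + asymmetry...`` on z-standardized columns.
    Columns named ``z3``, ``z2`` and ``bif`` are the cubic/quadratic state
    terms and the bifurcation product; all other columns are asymmetry
    covariates. Pruning (at ``alpha_level``): drop ``z3`` if non-significant,
    then drop non-significant asymmetry terms one at a time, largest p
    first. ``z2`` and ``bif`` are never pruned.

    Attributes set by ``fit``: ``fit_`` (CuspFit), ``pruning_log_``,
    ``feature_names_in_``.
    """

    def __init__(self, alpha_level: float = 0.05, prune: bool = True):
        self.alpha_level = alpha_level
        self.prune = prune

    def fit(self, X: pd.DataFrame, y, term_roles: Optional[Dict[str, str]] = None):
        Xs, ys = self._prepare(X, y)
        self.feature_names_in_ = list(Xs.columns)
        roles = dict(term_roles or {})
        for c in Xs.columns:
            roles.setdefault(
                c, {"z3": "state", "z2": "state", "bif": "bifurcation"}.get(c, "asymmetry")
            )
        pruning_log: List[Dict[str, float]] = []
        cols = list(Xs.columns)
        res = ols_fit(Xs[cols], ys)
        if self.prune and "z3" in cols:
            p_z3 = res.pvalues[res.terms.index("z3")]
            if p_z3 >= self.alpha_level:
                pruning_log.append({"term": "z3", "pvalue": float(p_z3)})
                cols.remove("z3")
                res = ols_fit(Xs[cols], ys)
        if self.prune:
            while True:
                candidates = [
                    (res.pvalues[res.terms.index(c)], c)
                    for c in cols
                    if roles.get(c) == "asymmetry"
                    and res.pvalues[res.terms.index(c)] >= self.alpha_level
                ]
                if not candidates:
                    break
                p_drop, worst = max(candidates)
                pruning_log.append({"term": worst, "pvalue": float(p_drop)})
                cols.remove(worst)
                res = ols_fit(Xs[cols], ys)
        self.fit_ = _fit_from_ols(res, {c: roles[c] for c in cols}, pruning_log)
        self.pruning_log_ = pruning_log
        return self


class LinearBaselineRegression(_StandardizedOLSBase):
    """Plain standardized OLS baseline (no z terms, no product, no pruning)."""

    def __init__(self):
        pass

    def fit(self, X: pd.DataFrame, y):
        Xs, ys = self._prepare(X, y)
        self.feature_names_in_ = list(Xs.columns)
        res = ols_fit(Xs, ys)
        self.fit_ = _fit_from_ols(
            res, {c: "linear" for c in Xs.columns}, pruning_log=[]
        )
        return self


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------

def fit_cusp_model(design: CuspDesign, alpha_level: float = 0.05) -> CuspFit:
    """Fit and prune the cusp polynomial regression on a built design."""
    est = CuspPolynomialRegression(alpha_level=alpha_level)
    est.fit(design.predictors(include_z3=True), design.dv,
            term_roles=design.term_roles)
    return est.fit_


def fit_linear_model(
    panel: PanelDataset,
    roles: VariableRoles,
    match_fit: Optional[CuspFit] = None,
) -> CuspFit:
    """Linear comparison model: dv ~ bifurcation variable + asymmetry terms.

    Uses the same residualized dv and the same complete cases as the cusp
    design for this contrast, but raw predictors (no state terms, no
    product). When ``match_fit`` is a final pruned cusp fit, the asymmetry
    covariates are restricted to the ones that survived pruning there, so
    the two models are compared on the same covariate support (the
    convention of the published linear comparison, whose predictors matched
    the final cusp model).
    """
    design = build_design(panel, roles)
    col_bif = roles.bifurcation
    asym = list(roles.asymmetry)
    if match_fit is not None:
        asym = [a for a in asym if a in match_fit.pvalues]
    df = _complete_cases(panel, list({col_bif, *roles.asymmetry}))
    df = df.loc[design.frame.index]
    X = df[[col_bif] + asym]
    est = LinearBaselineRegression()
    est.fit(X, design.dv)
    return est.fit_
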