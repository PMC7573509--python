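"""Information criteria, cusp-vs-linear comparison and support verdicts.

AIC and BIC use the full-constant Gaussian log-likelihood, with the error
variance counted as an estimated parameter; only differences between models
fitted to the same dv matter for the verdicts. Delta categories follow the
multimodel-inference conventions: an AIC difference above 2 is meaningful,
above 4 moderately meaningful, above 10 considerable (strict inequalities);
a BIC difference in [0, 2] is not worth more than a bare mention, (2, 6] is
positive, (6, 10] strong, above 10 very strong.

The support verdict mirrors how polynomial-regression cusp results are
read: a significant quadratic (or retained cubic) state term is evidence a
cusp occurred; the model is *supported* only when the bifurcation product
and at least one asymmetry covariate are significant as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .polyreg import CuspFit

__all__ = [
    "aic",
    "bic",
    "adjusted_r2",
    "interpret_delta_aic",
    "interpret_delta_bic",
    "decide_cusp_support",
    "compare_models",
    "ComparisonVerdict",
    "ModelComparisonError",
]


class ModelComparisonError(ValueError):
    """Models are not comparable (different subjects / sample sizes)."""


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, AIC = -2*loglik + 2k."""
    return -2.0 * loglik + 2.0 * k


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, BIC = -2*loglik + k*ln(n)."""
    if n <= k:
        raise ValueError("need n > k for BIC")
    return -2.0 * loglik + k * math.log(n)


def adjusted_r2(r2: float, n: int, k_coef: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k_coef), k_coef incl. intercept."""
    if n <= k_coef:
        raise ValueError("need n > number of coefficients")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k_coef)


def interpret_delta_aic(delta: float) -> str:
    """Verbal category for an AIC difference magnitude (strict thresholds)."""
    d = abs(delta)
    if not math.isfinite(d):
        raise ValueError("delta must be finite")
    if d <= 2.0:
        return "negligible"
    if d <= 4.0:
        return "meaningful"
    if d <= 10.0:
        return "moderately_meaningful"
    return "considerable"


def interpret_delta_bic(delta: float) -> str:
    """Verbal category for a BIC difference magnitude.

    Takes ``|delta|``; the direction (which model wins) is carried by the
    sign of the delta upstream.
    """
    d = abs(delta)
    if not math.isfinite(d):
        raise ValueError("delta must be finite")
    if d <= 2.0:
        return "bare_mention"
    if d <= 6.0:
        return "positive"
    if d <= 10.0:
        return "strong"
    return "very_strong"


def decide_cusp_support(cusp_fit: "CuspFit", alpha_level: float = 0.05) -> str:
    """Classify a final pruned cusp fit as no_cusp / cusp_unsupported / cusp_supported.

    ``no_cusp``: neither the quadratic nor a retained cubic state term is
    significant — no evidence the non-linear shift occurred.
    ``cusp_unsupported``: a state term is significant but either the
    bifurcation product is not, or no asymmetry covariate survives as
    significant. ``cusp_supported``: state term, bifurcation product and at
    least one asymmetry covariate are all significant (the sign of the
    product is not enforced).
    """
    z_sig = cusp_fit.significant("z2", alpha_level) or cusp_fit.significant(
        "z3", alpha_level
    )
    if not z_sig:
        return "no_cusp"
    bif_sig = cusp_fit.significant("bif", alpha_level)
    asym_sig = any(
        cusp_fit.significant(t, alpha_level)
        for t, role in cusp_fit.term_roles.items()
        if role == "asymmetry" and t in cusp_fit.pvalues
    )
    if bif_sig and asym_sig:
        return "cusp_supported"
    return "cusp_unsupported"


@dataclass
class ComparisonVerdict:
    """Cusp-vs-linear information-criterion comparison plus support decision.

    Deltas are linear minus cusp, so positive deltas favor the cusp model.
    """

    aic_cusp: float
    aic_linear: float
    bic_cusp: float
    bic_linear: float
    delta_aic: float
    delta_bic: float
    aic_category: str
    bic_category: str
    preferred_by_aic: str
    support: str

    def to_dict(self) -> dict:
        return asdict(self)


def compare_models(
    cusp_fit: "CuspFit", linear_fit: "CuspFit", alpha_level: float = 0.05
) -> ComparisonVerdict:
    """Compare a cusp fit with its linear baseline on the same subjects."""
    if cusp_fit.n != linear_fit.n:
        raise ModelComparisonError(
            f"sample sizes differ (cusp n={cusp_fit.n}, linear n={linear_fit.n})"
        )
    delta_aic = linear_fit.aic - cusp_fit.aic
    delta_bic = linear_fit.bic - cusp_fit.bic
    return ComparisonVerdict(
        aic_cusp=cusp_fit.aic,
        aic_linear=linear_fit.aic,
        bic_cusp=cusp_fit.bic,
        bic_linear=linear_fit.bic,
        delta_aic=delta_aic,
        delta_bic=delta_bic,
        aic_category=interpret_delta_aic(delta_aic),
        bic_category=interpret_delta_bic(delta_bic),
        preferred_by_aic="cusp" if delta_aic > 0 else "linear",
        support=decide_cusp_support(cusp_fit, alpha_level),
    )
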