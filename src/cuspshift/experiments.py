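"""Monte Carlo operating characteristics of the cusp regression.

Replicate-level experiments used by the test suite and the acceptance
script: type-I error of the quadratic state term under the linear null,
power to detect the bifurcation product and asymmetry effects under the
cusp generator, and the direction of the AIC comparison under each truth.
Replicates run without missingness or attrition so the per-replicate n is
exact; every replicate is a pure function of (config, seed).
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .panel import VariableRoles
from .polyreg import build_design, fit_cusp_model, fit_linear_model
from .selection import compare_models
from .simulate import SimConfig, gen_linear_panel, simulate_panel

__all__ = [
    "contrast_roles",
    "run_replicates",
    "type_one_error_rate",
    "power_summary",
    "delta_aic_summary",
]


def contrast_roles(profile: str, wave_pair=("T1", "T3")) -> VariableRoles:
    """Default roles for a study profile: CSE bifurcation, study-specific asymmetry."""
    asym_main = "loss_t1" if profile == "study1" else "pd_t1"
    return VariableRoles(
        state="distress",
        bifurcation="cse_t1",
        asymmetry=(asym_main, "time_since", "gender"),
        wave_pair=tuple(wave_pair),
    )


def _clean_config(profile: str, n_subjects: int) -> SimConfig:
    return SimConfig.from_profile(
        profile,
        n_subjects=n_subjects,
        missing_rates=(0.0, 0.0, 0.0),
        attrition_rates=(0.0, 0.0),
    )


def run_replicates(
    generator: str,
    n_subjects: int = 150,
    n_reps: int = 200,
    seed: int = 0,
    profile: str = "study1",
    alpha_level: float = 0.05,
    config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Fit cusp + linear models on ``n_reps`` fresh panels; one row per replicate.

    ``generator`` is ``"cusp"`` (stochastic-cusp truth) or ``"linear"``
    (no-cusp null). Columns record final-model p-values of the state and
    bifurcation terms, the bifurcation coefficient, whether any asymmetry
    term survived as significant, and the linear-minus-cusp AIC/BIC deltas.
    """
    if generator not in ("cusp", "linear"):
        raise ValueError("generator must be 'cusp' or 'linear'")
    cfg = config if config is not None else _clean_config(profile, n_subjects)
    roles = contrast_roles(profile)
    rows = []
    root_ss = np.random.SeedSequence(seed)
    for i, child in enumerate(root_ss.spawn(n_reps)):
        rep_seed = int(child.generate_state(1, np.uint32)[0])
        panel = (
            simulate_panel(cfg, rep_seed)
            if generator == "cusp"
            else gen_linear_panel(cfg, rep_seed)
        )
        design = build_design(panel, roles)
        cusp = fit_cusp_model(design, alpha_level=alpha_level)
        linear = fit_linear_model(panel, roles, match_fit=cusp)
        verdict = compare_models(cusp, linear, alpha_level=alpha_level)
        asym_ps = [
            cusp.pvalues[t]
            for t, role in cusp.term_roles.items()
            if role == "asymmetry" and t in cusp.pvalues
        ]
        rows.append(
            {
                "rep": i,
                "n": cusp.n,
                "p_z2": cusp.pvalues.get("z2", np.nan),
                "z3_retained": "z3" in cusp.pvalues,
                "p_z3": cusp.pvalues.get("z3", np.nan),
                "p_bif": cusp.pvalues.get("bif", np.nan),
                "coef_bif": cusp.coef.get("bif", np.nan),
                "any_asym_sig": bool(asym_ps) and min(asym_ps) < alpha_level,
                "delta_aic": verdict.delta_aic,
                "delta_bic": verdict.delta_bic,
                "support": verdict.support,
            }
        )
    return pd.DataFrame(rows)


def type_one_error_rate(
    n_subjects: int = 150,
    n_reps: int = 1000,
    seed: int = 0,
    profile: str = "study1",
    alpha_level: float = 0.05,
) -> float:
    """Rejection rate of the final-model z^2 term under the linear null."""
    reps = run_replicates(
        "linear", n_subjects, n_reps, seed, profile, alpha_level
    )
    return float((reps["p_z2"] < alpha_level).mean())


def power_summary(
    n_subjects: int = 150,
    n_reps: int = 200,
    seed: int = 0,
    profile: str = "study1",
    alpha_level: float = 0.05,
    reps: Optional[pd.DataFrame] = None,
) -> Dict[str, float]:
    """Power under the cusp truth: negative-significant bif term, asymmetry hits."""
    if reps is None:
        reps = run_replicates("cusp", n_subjects, n_reps, seed, profile, alpha_level)
    bif_hit = (reps["coef_bif"] < 0) & (reps["p_bif"] < alpha_level)
    return {
        "power_bifurcation": float(bif_hit.mean()),
        "power_any_asymmetry": float(reps["any_asym_sig"].mean()),
        "support_rate": float((reps["support"] == "cusp_supported").mean()),
    }


def delta_aic_summary(reps: pd.DataFrame) -> Dict[str, float]:
    """Median linear-minus-cusp AIC/BIC deltas over a replicate table."""
    return {
        "median_delta_aic": float(reps["delta_aic"].median()),
        "median_delta_bic": float(reps["delta_bic"].median()),
        "cusp_preferred_rate": float((reps["delta_aic"] > 0).mean()),
    }
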