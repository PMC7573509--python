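"""Deterministic geometry of the cusp catastrophe.

The canonical cusp is a gradient system on a scalar state ``y`` with
potential

    V(y; alpha, beta) = y**4 / 4 - beta * y**2 / 2 - alpha * y

where ``alpha`` is the asymmetry control parameter (tilts the potential
toward the lower or upper well) and ``beta`` is the bifurcation control
parameter (splits the single well into two once it is large enough).
Equilibria are the real roots of the cubic ``y**3 - beta*y - alpha = 0``;
the system is bistable exactly when the discriminant
``D = 4*beta**3 - 27*alpha**2`` is positive.

Everything here is pure math used by the simulator and diagnostics; roots
are solved in closed form (trigonometric / Cardano) and polished with a few
Newton steps so residuals stay small even near the bifurcation set, where
iterative solvers stall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "CuspControls",
    "potential",
    "gradient",
    "discriminant",
    "equilibrium_roots",
    "classify_regime",
    "delay_step",
    "alpha_sweep",
    "hysteresis_loop_area",
]

#: tolerance on the discriminant below which controls sit on the bifurcation set
BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class CuspControls:
    """Control parameters (asymmetry ``alpha``, bifurcation ``beta``) and state ``y``."""

    alpha: float
    beta: float
    y: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "y"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"CuspControls.{name} must be finite")


def potential(y, alpha: float, beta: float):
    """Cusp potential ``V(y) = y^4/4 - beta*y^2/2 - alpha*y`` (vectorized in y)."""
    y = np.asarray(y, dtype=float)
    v = 0.25 * y**4 - 0.5 * beta * y**2 - alpha * y
    return float(v) if v.ndim == 0 else v


def gradient(y, alpha: float, beta: float):
    """dV/dy = y^3 - beta*y - alpha."""
    y = np.asarray(y, dtype=float)
    g = y**3 - beta * y - alpha
    return float(g) if g.ndim == 0 else g


def discriminant(alpha: float, beta: float) -> float:
    """D = 4*beta^3 - 27*alpha^2; positive inside the bistable wedge."""
    return 4.0 * beta**3 - 27.0 * alpha**2


def _polish(y: float, alpha: float, beta: float, iters: int = 4) -> float:
    # Newton refinement; skipped where the derivative vanishes (double roots).
    for _ in range(iters):
        fp = 3.0 * y * y - beta
        if abs(fp) < 1e-12:
            break
        y -= (y**3 - beta * y - alpha) / fp
    return y


def equilibrium_roots(alpha: float, beta: float) -> List[Tuple[float, str]]:
    """Real equilibria of the cusp, ascending, with stability labels.

    Returns 1-3 ``(root, label)`` pairs, ``label in {"stable", "unstable"}``.
    Stability follows the sign of ``V'' = 3y^2 - beta``; double roots on the
    bifurcation set are labeled unstable so simulated trajectories cannot be
    trapped on a measure-zero set. A unique real root is always attracting
    and labeled stable (including the triple root at the cusp point).
    """
    if not (math.isfinite(alpha) and math.isfinite(beta)):
        raise ValueError("controls must be finite")
    p, q = -beta, -alpha  # depressed cubic t^3 + p t + q
    d = discriminant(alpha, beta)
    if abs(d) <= BOUNDARY_TOL:
        if abs(p) < 1e-12 and abs(q) < 1e-12:
            return [(0.0, "stable")]  # triple root at the cusp point
        a = math.copysign(abs(0.5 * q) ** (1.0 / 3.0), q)
        double, simple = a, _polish(-2.0 * a, alpha, beta)
        pairs = [(double, "unstable"), (simple, "stable")]
        pairs.sort(key=lambda rs: rs[0])
        return pairs
    if d > 0:  # three distinct real roots (trigonometric form; p < 0 here)
        m = 2.0 * math.sqrt(-p / 3.0)
        arg = 3.0 * q / (2.0 * p) * math.sqrt(-3.0 / p)
        theta = math.acos(max(-1.0, min(1.0, arg))) / 3.0
        roots = sorted(
            _polish(m * math.cos(theta - 2.0 * math.pi * k / 3.0), alpha, beta)
            for k in range(3)
        )
        return [(roots[0], "stable"), (roots[1], "unstable"), (roots[2], "stable")]
    # single real root (Cardano)
    s = math.sqrt(q * q / 4.0 + p**3 / 27.0)
    y = float(np.cbrt(-q / 2.0 + s) + np.cbrt(-q / 2.0 - s))
    return [(_polish(y, alpha, beta), "stable")]


def classify_regime(alpha: float, beta: float) -> str:
    """Classify controls as ``monostable``, ``bistable`` or ``boundary``."""
    d = discriminant(alpha, beta)
    if d > BOUNDARY_TOL:
        return "bistable"
    if d < -BOUNDARY_TOL:
        return "monostable"
    return "boundary"


def delay_step(y_prev: float, alpha: float, beta: float) -> float:
    """Stable equilibrium reached by gradient descent on V started at ``y_prev``.

    Implements the delay convention: the state relaxes to the attractor of
    the basin containing it and jumps only when that attractor vanishes.
    A start exactly on the basin boundary resolves to the upper basin
    (documented tie-break; the event has measure zero under noise).
    """
    roots = equilibrium_roots(alpha, beta)
    stable = [r for r, lab in roots if lab == "stable"]
    if len(stable) == 1:
        return stable[0]
    boundary = next(r for r, lab in roots if lab == "unstable")
    return stable[0] if y_prev < boundary else stable[1]


def alpha_sweep(alphas, beta: float, y0: float) -> np.ndarray:
    """Quasi-static state track under the delay convention along ``alphas``."""
    states = np.empty(len(alphas))
    y = float(y0)
    for i, a in enumerate(np.asarray(alphas, dtype=float)):
        y = delay_step(y, a, beta)
        states[i] = y
    return states


def hysteresis_loop_area(beta: float, alpha_max: float = 2.0, n: int = 201) -> float:
    """Area enclosed between up- and down-sweeps of alpha in ``[-alpha_max, alpha_max]``.

    Positive area is the dynamical signature of bistability (hysteresis);
    monostable ``beta`` gives exactly zero because the state track is
    single-valued in alpha.
    """
    alphas = np.linspace(-alpha_max, alpha_max, n)
    up = alpha_sweep(alphas, beta, y0=-abs(alpha_max) - abs(beta) - 1.0)
    down = alpha_sweep(alphas[::-1], beta, y0=abs(alpha_max) + abs(beta) + 1.0)[::-1]
    return float(np.trapezoid(np.abs(up - down), alphas))
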