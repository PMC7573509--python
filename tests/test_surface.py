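"""Cusp geometry: potential, equilibria, regimes, delay dynamics."""

import math

import numpy as np
import pytest

from cuspshift.surface import (
    CuspControls,
    alpha_sweep,
    classify_regime,
    delay_step,
    discriminant,
    equilibrium_roots,
    gradient,
    hysteresis_loop_area,
    potential,
)


def grid_scan_roots(alpha, beta, half=8.0, n=200001):
    """Independent root finder: sign changes of the cubic on a dense grid."""
    y = np.linspace(-half, half, n)
    f = y**3 - beta * y - alpha
    sign = np.sign(f)
    idx = np.where(np.diff(sign) != 0)[0]
    roots = []
    for i in idx:
        a, b = y[i], y[i + 1]
        for _ in range(80):  # bisection
            m = 0.5 * (a + b)
            if (m**3 - beta * m - alpha) * (a**3 - beta * a - alpha) <= 0:
                b = m
            else:
                a = m
        roots.append(0.5 * (a + b))
    return roots


def test_potential_basic_and_reflection_symmetry():
    assert potential(0.0, 0.0, 0.0) == 0.0
    rng = np.random.default_rng(0)
    y, a, b = rng.normal(size=(3, 100)) * 2
    assert np.allclose(potential(y, 0, 0), potential(-y, 0, 0))
    for yi, ai, bi in zip(y, a, b):
        assert potential(yi, ai, bi) == pytest.approx(potential(-yi, -ai, bi))


def test_gradient_matches_finite_difference():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        y, a, b = rng.uniform(-3, 3, 3)
        h = 1e-6
        num = (potential(y + h, a, b) - potential(y - h, a, b)) / (2 * h)
        assert gradient(y, a, b) == pytest.approx(num, abs=1e-6)


@pytest.mark.parametrize(
    "alpha,beta,expected",
    [
        (0.0, 0.0, [(0.0, "stable")]),
        (0.0, 3.0, [(-math.sqrt(3), "stable"), (0.0, "unstable"), (math.sqrt(3), "stable")]),
        (2.0, 3.0, [(-1.0, "unstable"), (2.0, "stable")]),
    ],
)
def test_equilibrium_roots_analytic_cases(alpha, beta, expected):
    got = equilibrium_roots(alpha, beta)
    assert len(got) == len(expected)
    for (r, lab), (er, elab) in zip(got, expected):
        assert r == pytest.approx(er, abs=1e-9)
        assert lab == elab


def test_roots_against_grid_scan_and_discriminant():
    rng = np.random.default_rng(2)
    for _ in range(300):
        a, b = rng.uniform(-5, 5, 2)
        roots = equilibrium_roots(a, b)
        d = discriminant(a, b)
        if abs(d) > 1e-9:
            assert len(roots) == (3 if d > 0 else 1)
        scan = grid_scan_roots(a, b)
        assert len(scan) == len(roots)
        for (r, _), s in zip(roots, scan):
            assert r == pytest.approx(s, abs=1e-6)
        for r, _ in roots:
            assert abs(r**3 - b * r - a) <= 1e-9
        vals = [r for r, _ in roots]
        assert vals == sorted(vals)
        if len(roots) == 3:
            assert [lab for _, lab in roots] == ["stable", "unstable", "stable"]


def test_classify_regime_cases_and_agreement_with_root_count():
    assert classify_regime(0, 1) == "bistable"
    assert classify_regime(0, -1) == "monostable"
    assert classify_regime(2, 3) == "boundary"
    rng = np.random.default_rng(3)
    for _ in range(2000):
        a, b = rng.uniform(-5, 5, 2)
        regime = classify_regime(a, b)
        n_roots = len(equilibrium_roots(a, b))
        if regime == "bistable":
            assert n_roots == 3
        elif regime == "monostable":
            assert n_roots == 1


def test_delay_step_basins_and_idempotence():
    # monostable: unique attractor regardless of start
    for y0 in (-5.0, 0.0, 5.0):
        assert delay_step(y0, 1.0, -1.0) == pytest.approx(
            equilibrium_roots(1.0, -1.0)[0][0]
        )
    # bistable basin symmetry
    assert delay_step(1.0, 0.0, 3.0) == pytest.approx(math.sqrt(3))
    assert delay_step(-1.0, 0.0, 3.0) == pytest.approx(-math.sqrt(3))
    rng = np.random.default_rng(4)
    for _ in range(200):
        a, b, y0 = rng.uniform(-4, 4, 3)
        y1 = delay_step(y0, a, b)
        assert delay_step(y1, a, b) == y1


def test_hysteresis_loop_positive_only_when_bistable():
    assert hysteresis_loop_area(3.0) > 0
    assert hysteresis_loop_area(-1.0) == 0.0
    # the sweep visits different states on up vs down inside the band
    alphas = np.linspace(-2, 2, 101)
    up = alpha_sweep(alphas, 3.0, y0=-3.0)
    down = alpha_sweep(alphas[::-1], 3.0, y0=3.0)[::-1]
    inside = np.abs(alphas) < 1.9
    assert np.any(np.abs(up[inside] - down[inside]) > 1.0)


def test_controls_reject_nonfinite():
    with pytest.raises(ValueError):
        CuspControls(alpha=math.nan, beta=0.0)
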