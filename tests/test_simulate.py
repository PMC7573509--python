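"""Synthetic generator: covariates, stationary sampling, SDE waves, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuspshift.simulate import (
    CovariateSpec,
    SimConfig,
    SimConfigError,
    cobb_moments,
    gen_covariates,
    gen_linear_panel,
    inject_attrition,
    inject_missing,
    sample_cobb,
    simulate_panel,
    simulate_waves_sde,
    stationary_sample,
)
from cuspshift.surface import equilibrium_roots


def test_config_validation():
    with pytest.raises(SimConfigError):
        SimConfig(n_subjects=5)
    with pytest.raises(SimConfigError):
        SimConfig(sigma=-0.1)
    with pytest.raises(SimConfigError):
        SimConfig(missing_rates=(0.5, 0.5, 1.5))
    with pytest.raises(SimConfigError):
        CovariateSpec(mean=0, sd=1, lo=-5, hi=5, loading=1.2)


def test_profile_roundtrip_through_dict():
    cfg = SimConfig.from_profile("study1")
    back = SimConfig.from_dict(cfg.to_dict())
    assert back.to_dict() == cfg.to_dict()


def test_zero_loadings_give_independent_covariates():
    cfg = SimConfig.from_profile("study1", n_subjects=4000)
    for spec in cfg.covariates.values():
        spec.loading = 0.0
    base = gen_covariates(cfg, 5)
    r = np.corrcoef(base["cse"], base["loss"])[0, 1]
    assert abs(r) < 3 / np.sqrt(len(base))


def test_covariate_marginals_hit_targets():
    cfg = SimConfig.from_profile("study1", n_subjects=10_000)
    base = gen_covariates(cfg, 6)
    assert base["cse"].mean() == pytest.approx(5.37, abs=0.05)
    assert base["cse"].std(ddof=1) == pytest.approx(1.16, abs=0.05)
    assert base["loss"].mean() == pytest.approx(0.89, abs=0.05)
    assert (base["cse"] >= 1).all() and (base["cse"] <= 7).all()


def test_sample_cobb_matches_quadrature():
    for alpha, beta in [(0.0, 0.0), (0.0, 2.0), (3.0, 0.0)]:
        draws = sample_cobb(alpha, beta, 100_000, seed=8)
        m, v = cobb_moments(alpha, beta)
        se_mean = np.sqrt(v / len(draws))
        assert abs(draws.mean() - m) < 4 * se_mean
        assert abs(draws.var() - v) / v < 0.02


def test_stationary_sample_sigma_scaling_matches_canonical():
    """At sigma = sqrt(2) the diffusion's stationary law is the canonical density."""
    rng = np.random.default_rng(9)
    draws = stationary_sample(np.full(50_000, 1.0), np.full(50_000, 1.0),
                              sigma=np.sqrt(2.0), rng=rng)
    m, v = cobb_moments(1.0, 1.0)
    assert draws.mean() == pytest.approx(m, abs=4 * np.sqrt(v / 50_000))
    assert draws.var() == pytest.approx(v, rel=0.03)


def test_sde_deterministic_fixed_point_at_sigma_zero():
    cfg = SimConfig.from_profile("study1", n_subjects=50,
                                 missing_rates=(0, 0, 0), attrition_rates=(0, 0))
    cfg.sigma = 0.0
    base = gen_covariates(cfg, 10)
    panel = simulate_waves_sde(base, cfg, 11)
    d = panel.data[["distress_t1", "distress_t2", "distress_t3"]].to_numpy()
    assert np.allclose(d[:, 0], d[:, 1], atol=1e-6)
    assert np.allclose(d[:, 0], d[:, 2], atol=1e-6)


def test_equal_seeds_identical_panels():
    cfg = SimConfig.from_profile("study1", n_subjects=100)
    p1 = simulate_panel(cfg, 21)
    p2 = simulate_panel(cfg, 21)
    pd.testing.assert_frame_equal(p1.data, p2.data)
    l1 = gen_linear_panel(cfg, 22)
    l2 = gen_linear_panel(cfg, 22)
    pd.testing.assert_frame_equal(l1.data, l2.data)


def test_low_cse_subgroup_shows_larger_change_variance():
    """b1 < 0 puts low-CSE subjects in the bistable regime: bimodal shifts."""
    cfg = SimConfig.from_profile("study1", n_subjects=5000,
                                 missing_rates=(0, 0, 0), attrition_rates=(0, 0))
    panel = simulate_panel(cfg, 13)
    df = panel.data
    change = df["distress_t3"] - df["distress_t1"]
    low = df["cse_t1"] < df["cse_t1"].median()
    assert change[low].var() > change[~low].var()


def test_bimodality_of_t3_distress_by_regime():
    """Deep bistable controls give a two-mode T3 histogram; monostable does not."""
    base_kwargs = dict(n_subjects=5000, missing_rates=(0, 0, 0), attrition_rates=(0, 0))
    cfg = SimConfig.from_profile("study1", **base_kwargs)
    cfg.b1 = 0.0
    cfg.a1 = 0.0
    cfg.a0 = 0.0
    cfg.obs_scale, cfg.obs_offset = 0.8, 2.0
    cfg.sigma = 0.4

    def modes(b0, seed):
        cfg.b0 = b0
        base = gen_covariates(cfg, seed)
        panel = simulate_waves_sde(base, cfg, seed + 1)
        d = panel.data["distress_t3"].to_numpy()
        hist, _ = np.histogram(d, bins=np.linspace(0.4, 3.6, 4))
        return hist

    bistable = modes(3.0, 30)  # wells at +-sqrt(3): outer bins heavy, middle light
    assert bistable[1] < bistable[0] and bistable[1] < bistable[2]
    monostable = modes(-1.0, 31)  # single well at 0 (distress 2): middle heavy
    assert monostable[1] > monostable[0] and monostable[1] > monostable[2]


def test_linear_panel_slope_recovery():
    cfg = SimConfig.from_profile("study1", n_subjects=10_000)
    panel = gen_linear_panel(cfg, 14)
    d1 = panel.data["distress_t1"].to_numpy()
    d2 = panel.data["distress_t2"].to_numpy()
    slope = np.polyfit(d1, d2, 1)[0]
    assert slope == pytest.approx(cfg.linear.c1, abs=0.02)


def test_linear_panel_exact_affine_when_noiseless():
    cfg = SimConfig.from_profile("study1", n_subjects=200)
    cfg.linear.noise = 0.0
    cfg.linear.c2 = 0.0
    cfg.linear.c3 = 0.0
    panel = gen_linear_panel(cfg, 15)
    d1 = panel.data["distress_t1"].to_numpy()
    d2 = panel.data["distress_t2"].to_numpy()
    assert np.allclose(d2, cfg.linear.c0 + cfg.linear.c1 * d1, atol=1e-12)


def test_inject_missing_rate_zero_and_binomial_band():
    cfg = SimConfig.from_profile("study1", n_subjects=1000,
                                 missing_rates=(0, 0, 0), attrition_rates=(0, 0))
    panel = simulate_panel(cfg, 16)
    same = inject_missing(panel, 0.0, seed=1)
    pd.testing.assert_frame_equal(same.data, panel.data)
    holed = inject_missing(panel, 0.5, seed=2)
    cells = holed.data[["distress_t1", "distress_t2", "distress_t3"]].isna()
    n_cells = cells.size
    frac = cells.to_numpy().mean()
    half_width = 2.576 * np.sqrt(0.25 / n_cells)
    assert abs(frac - 0.5) < half_width


def test_attrition_counts_match_study1_follow_up():
    """Rates (0.18, 0.21) on n = 189 give ~155 and ~123 completers."""
    cfg = SimConfig.from_profile("study1", n_subjects=189,
                                 missing_rates=(0, 0, 0), attrition_rates=(0, 0))
    panel = simulate_panel(cfg, 17)
    t2_counts, t3_counts = [], []
    for seed in range(20):
        out = inject_attrition(panel, (0.18, 0.21), seed=seed)
        t2_counts.append(out.data["distress_t2"].notna().sum())
        t3_counts.append(out.data["distress_t3"].notna().sum())
    n = 189
    p2, p3 = 0.82, 0.82 * 0.79
    for counts, p in [(t2_counts, p2), (t3_counts, p3)]:
        mean_count = np.mean(counts)
        se = np.sqrt(n * p * (1 - p) / len(counts))
        assert abs(mean_count - n * p) < 3 * se
    # wave 1 never deleted
    assert out.data["distress_t1"].notna().all()
    # monotone dropout: missing at T2 implies missing at T3
    t2na = out.data["distress_t2"].isna()
    assert out.data.loc[t2na, "distress_t3"].isna().all()


def test_generated_panels_satisfy_invariants():
    for profile in ("study1", "study2"):
        cfg = SimConfig.from_profile(profile, n_subjects=300)
        panel = simulate_panel(cfg, 18)
        panel.validate()
        assert panel.n_subjects == 300
        linear = gen_linear_panel(cfg, 19)
        linear.validate()
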