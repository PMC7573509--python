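"""Synthetic multi-wave panels from a stochastic cusp process.

The generator realizes the data-generating process the cusp analysis
assumes. A single latent vulnerability factor ``L ~ N(0,1)`` induces the
correlation pattern among baseline covariates (coping self-efficacy loads
negatively, loss / peritraumatic dissociation positively). Per subject the
control parameters are affine in the standardized covariates,

    beta_i  = b0 + b1 * std(cse_i)        (b1 < 0: low CSE -> bistable)
    alpha_i = a0 + a1 * std(loss_i or pd_i)

and the canonical distress state evolves between waves by Euler-Maruyama on

    dy = -(y^3 - beta_i * y - alpha_i) dt + sigma dW,

with the wave-1 state drawn from the stationary density of that diffusion
(the cusp stationary family; see `sample_cobb`). Observed distress is an
affine map of y clipped to the scale range. A linear-null generator with
the same covariate structure but a purely autoregressive-linear state
equation provides the comparison condition, and MCAR cell deletion plus
per-wave attrition emulate the observed missingness pattern.

Covariate marginals are produced by clipping a Gaussian to the scale range;
the pre-clip mean/SD are solved from censored-normal moment equations so
the *post*-clip moments hit the published targets. Bundled profiles
(``study1``, ``study2``) carry constants calibrated to the two wildfire
samples' descriptive tables.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid, quad
from scipy.optimize import root
from scipy.stats import norm

from .panel import DEFAULT_RANGES, PanelDataset
from .surface import equilibrium_roots, potential

__all__ = [
    "CovariateSpec",
    "LinearNullConfig",
    "SimConfig",
    "SimConfigError",
    "gen_covariates",
    "simulate_waves_sde",
    "simulate_panel",
    "sample_cobb",
    "cobb_moments",
    "stationary_sample",
    "gen_linear_panel",
    "inject_missing",
    "inject_attrition",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Target marginal (post-clip) and latent loading for one covariate."""

    mean: float
    sd: float
    lo: float
    hi: float
    loading: float = 0.0
    integer: bool = False

    def __post_init__(self) -> None:
        if abs(self.loading) > 1.0:
            raise SimConfigError(
                f"|loading| > 1 would force an impossible correlation "
                f"({self.loading})"
            )
        if not self.sd > 0:
            raise SimConfigError("covariate SD must be positive")


@dataclass
class LinearNullConfig:
    """State equation for the no-cusp generator: d' = c0 + c1 d + c2 cse + c3 asym + noise."""

    c0: float = 0.0
    c1: float = 0.8
    c2: float = 0.0
    c3: float = 0.0
    noise: float = 0.3
    distress: CovariateSpec = field(
        default_factory=lambda: CovariateSpec(0.91, 0.75, 0.0, 4.0, loading=0.9)
    )


@dataclass
class SimConfig:
    """Full specification of one synthetic study condition.

    ``covariates`` maps variable names (``cse``, ``loss``, ``pd``,
    ``exposure``, ``time_since``) to their marginal targets and loadings on
    the shared latent vulnerability. Control maps, diffusion noise, wave
    schedule (days), observation map and missingness/attrition rates define
    the rest of the condition. All randomized operations take an explicit
    integer seed.
    """

    n_subjects: int = 189
    study_profile: str = "custom"
    wave_labels: Tuple[str, ...] = ("T1", "T2", "T3")
    wave_days: Tuple[float, ...] = (0.0, 30.0, 60.0)
    covariates: Dict[str, CovariateSpec] = field(default_factory=dict)
    gender_p_female: float = 0.688
    asymmetry_source: str = "loss"
    b0: float = 1.0
    b1: float = -0.8
    a0: float = 0.4
    a1: float = 0.8
    sigma: float = 0.4
    dt: float = 0.01
    days_per_unit: float = 10.0
    obs_scale: float = 0.6
    obs_offset: float = 0.9
    state_range: Tuple[float, float] = (0.0, 4.0)
    missing_rates: Tuple[float, ...] = (0.0, 0.0, 0.0)
    attrition_rates: Tuple[float, ...] = (0.0, 0.0)
    linear: LinearNullConfig = field(default_factory=LinearNullConfig)

    def __post_init__(self) -> None:
        self.wave_labels = tuple(self.wave_labels)
        self.wave_days = tuple(float(d) for d in self.wave_days)
        self.missing_rates = tuple(float(r) for r in self.missing_rates)
        self.attrition_rates = tuple(float(r) for r in self.attrition_rates)
        if self.n_subjects < 10:
            raise SimConfigError("n_subjects must be at least 10")
        if not all(0.0 <= r <= 1.0 for r in self.missing_rates + self.attrition_rates):
            raise SimConfigError("missing/attrition rates must lie in [0, 1]")
        if self.sigma < 0:
            raise SimConfigError("sigma must be non-negative")
        if self.dt <= 0:
            raise SimConfigError("dt must be positive")
        if len(self.wave_days) != len(self.wave_labels):
            raise SimConfigError("wave_days must match wave_labels")
        if len(self.missing_rates) != len(self.wave_labels):
            raise SimConfigError("one missing rate per wave required")
        if len(self.attrition_rates) != len(self.wave_labels) - 1:
            raise SimConfigError("one attrition rate per follow-up wave required")
        if any(b <= a for a, b in zip(self.wave_days, self.wave_days[1:])):
            raise SimConfigError("wave_days must be strictly increasing")
        lo, hi = self.state_range
        want = DEFAULT_RANGES["distress"]
        if (lo, hi) != want:
            raise SimConfigError(
                f"state_range {self.state_range} must match the distress scale {want}"
            )

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["covariates"] = {
            k: CovariateSpec(**v) if isinstance(v, dict) else v
            for k, v in d.get("covariates", {}).items()
        }
        lin = d.get("linear")
        if isinstance(lin, dict):
            lin = dict(lin)
            if isinstance(lin.get("distress"), dict):
                lin["distress"] = CovariateSpec(**lin["distress"])
            d["linear"] = LinearNullConfig(**lin)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_profile(cls, name: str, **overrides) -> "SimConfig":
        """Load a bundled study profile (``study1`` or ``study2``)."""
        ref = importlib.resources.files("cuspshift.profiles") / f"{name}.yaml"
        cfg = cls.from_dict(yaml.safe_load(ref.read_text()))
        for key, val in overrides.items():
            setattr(cfg, key, val)
        cfg.__post_init__()
        return cfg


# ---------------------------------------------------------------------------
# clipped-Gaussian marginals
# ---------------------------------------------------------------------------

def _censored_moments(mu: float, sigma: float, lo: float, hi: float) -> Tuple[float, float]:
    """Mean and SD of clip(N(mu, sigma), lo, hi); bounds may be infinite."""
    a = (lo - mu) / sigma if math.isfinite(lo) else -np.inf
    b = (hi - mu) / sigma if math.isfinite(hi) else np.inf
    fa, fb = norm.cdf(a), norm.cdf(b)
    pa, pb = norm.pdf(a), norm.pdf(b)
    lo_part = lo * fa if math.isfinite(lo) else 0.0
    hi_part = hi * (1.0 - fb) if math.isfinite(hi) else 0.0
    m1 = lo_part + hi_part + mu * (fb - fa) - sigma * (pb - pa)
    mid2 = (
        (mu * mu + sigma * sigma) * (fb - fa)
        + 2.0 * mu * sigma * (pa - pb)
        - sigma * sigma * ((b * pb if math.isfinite(hi) else 0.0)
                           - (a * pa if math.isfinite(lo) else 0.0))
    )
    lo2 = lo * lo * fa if math.isfinite(lo) else 0.0
    hi2 = hi * hi * (1.0 - fb) if math.isfinite(hi) else 0.0
    m2 = lo2 + hi2 + mid2
    return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


@lru_cache(maxsize=256)
def _declip_params(mean: float, sd: float, lo: float, hi: float) -> Tuple[float, float]:
    """Pre-clip Gaussian (mu, sigma) whose clipped moments hit (mean, sd)."""

    def objective(x):
        m, s = _censored_moments(x[0], math.exp(x[1]), lo, hi)
        return [m - mean, s - sd]

    sol = root(objective, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-posed for sane targets
        raise SimConfigError(f"cannot calibrate clipped marginal for {(mean, sd, lo, hi)}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def gen_covariates(config: SimConfig, seed: int) -> pd.DataFrame:
    """Baseline covariate table driven by a shared latent vulnerability.

    Returns one row per subject with the configured scale covariates,
    ``gender`` (1 = female) and the hidden standard-normal factor in column
    ``_latent`` (dropped before panels are written).
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    latent = rng.standard_normal(n)
    out = pd.DataFrame(index=pd.RangeIndex(1, n + 1, name="subject_id"))
    for name, spec in config.covariates.items():
        eps = rng.standard_normal(n)
        lam = spec.loading
        raw = lam * latent + math.sqrt(1.0 - lam * lam) * eps
        mu, s = _declip_params(spec.mean, spec.sd, spec.lo, spec.hi)
        vals = np.clip(mu + s * raw, spec.lo, spec.hi)
        if spec.integer:
            vals = np.clip(np.round(vals), spec.lo, spec.hi)
        out[name] = vals
    out["gender"] = (rng.random(n) < config.gender_p_female).astype(float)
    out["_latent"] = latent
    return out


# ---------------------------------------------------------------------------
# stationary sampling (Cobb density)
# ---------------------------------------------------------------------------

def _cobb_logdensity(y: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return alpha * y + 0.5 * beta * y**2 - 0.25 * y**4


def sample_cobb(alpha: float, beta: float, n: int, seed: int) -> np.ndarray:
    """Draws from the canonical cusp stationary density.

    ``p(y) ∝ exp(alpha*y + beta*y^2/2 - y^4/4)``, sampled by inverse-CDF on
    a dense grid over ``[-5 - |alpha|, 5 + |alpha|]`` (the density is
    negligible outside for moderate beta).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    half = 5.0 + abs(alpha) + math.sqrt(max(beta, 0.0))
    grid = np.linspace(-half, half, 8193)
    logp = _cobb_logdensity(grid, alpha, beta)
    p = np.exp(logp - logp.max())
    cdf = cumulative_trapezoid(p, grid, initial=0.0)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def cobb_moments(alpha: float, beta: float) -> Tuple[float, float]:
    """Mean and variance of the canonical stationary density by quadrature."""
    half = 5.0 + abs(alpha) + math.sqrt(max(beta, 0.0))

    def f(y, k):
        return y**k * math.exp(_cobb_logdensity(np.asarray(y), alpha, beta))

    z = quad(f, -half, half, args=(0,), limit=200)[0]
    m1 = quad(f, -half, half, args=(1,), limit=200)[0] / z
    m2 = quad(f, -half, half, args=(2,), limit=200)[0] / z
    return m1, m2 - m1 * m1


def stationary_sample(
    alpha: np.ndarray, beta: np.ndarray, sigma: float, rng: np.random.Generator,
    grid_points: int = 1601,
) -> np.ndarray:
    """Per-subject draws from the stationary density of the cusp diffusion.

    The diffusion ``dy = -V'(y) dt + sigma dW`` has stationary density
    ``∝ exp(-2 V(y) / sigma^2)``; with sigma = 0 the draw degenerates to the
    deepest stable equilibrium.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = len(alpha)
    if sigma == 0.0:
        out = np.empty(n)
        for i in range(n):
            stable = [r for r, lab in equilibrium_roots(alpha[i], beta[i]) if lab == "stable"]
            out[i] = min(stable, key=lambda r: potential(r, alpha[i], beta[i]))
        return out
    half = float(1.5 + np.sqrt(np.maximum(beta, 0.0)).max()
                 + np.abs(alpha).max() ** (1.0 / 3.0) + 2.0 * sigma)
    grid = np.linspace(-half, half, grid_points)
    # log stationary density, rows = subjects
    logp = (-2.0 / sigma**2) * (
        0.25 * grid[None, :] ** 4
        - 0.5 * beta[:, None] * grid[None, :] ** 2
        - alpha[:, None] * grid[None, :]
    )
    p = np.exp(logp - logp.max(axis=1, keepdims=True))
    dy = grid[1] - grid[0]
    cdf = np.cumsum((p[:, 1:] + p[:, :-1]) * (0.5 * dy), axis=1)
    u = rng.random(n)[:, None] * cdf[:, -1:]
    idx = np.minimum((cdf >= u).argmax(axis=1), cdf.shape[1] - 1)
    rows = np.arange(n)
    c_hi = cdf[rows, idx]
    c_lo = np.where(idx > 0, cdf[rows, np.maximum(idx - 1, 0)], 0.0)
    frac = np.where(c_hi > c_lo, (u[:, 0] - c_lo) / np.maximum(c_hi - c_lo, 1e-300), 0.0)
    return grid[idx] + dy * np.clip(frac, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cusp-panel simulation
# ---------------------------------------------------------------------------

def _control_maps(baseline: pd.DataFrame, config: SimConfig) -> Tuple[np.ndarray, np.ndarray]:
    cse = baseline["cse"].to_numpy()
    asym = baseline[config.asymmetry_source].to_numpy()
    z_cse = (cse - cse.mean()) / cse.std(ddof=1)
    z_asym = (asym - asym.mean()) / asym.std(ddof=1)
    beta = config.b0 + config.b1 * z_cse
    alpha = config.a0 + config.a1 * z_asym
    return alpha, beta


def _observe(y: np.ndarray, config: SimConfig) -> np.ndarray:
    lo, hi = config.state_range
    return np.clip(config.obs_scale * y + config.obs_offset, lo, hi)


def _assemble_panel(
    baseline: pd.DataFrame, distress: Sequence[np.ndarray], config: SimConfig
) -> PanelDataset:
    data = pd.DataFrame(index=baseline.index)
    for k, (label, d) in enumerate(zip(config.wave_labels, distress)):
        data[f"distress_{label.lower()}"] = d
    first = config.wave_labels[0].lower()
    for name in config.covariates:
        col = name if name == "time_since" else f"{name}_{first}"
        data[col] = baseline[name].to_numpy()
    data["gender"] = baseline["gender"].to_numpy()
    return PanelDataset(data, config.wave_labels, dict(DEFAULT_RANGES))


def simulate_waves_sde(baseline: pd.DataFrame, config: SimConfig, seed: int) -> PanelDataset:
    """Evolve the canonical cusp diffusion between waves and observe distress.

    Time is measured in units of ``days_per_unit`` days with Euler-Maruyama
    step ``dt``; the wave-1 state is a stationary draw given each subject's
    controls, so the panel starts in the regime the controls imply.
    """
    rng = np.random.default_rng(seed)
    alpha, beta = _control_maps(baseline, config)
    n = len(baseline)
    y = stationary_sample(alpha, beta, config.sigma, rng)
    states = [y.copy()]
    sqdt = math.sqrt(config.dt)
    for gap_days in np.diff(config.wave_days):
        n_steps = max(1, int(round(gap_days / config.days_per_unit / config.dt)))
        for _ in range(n_steps):
            drift = -(y**3 - beta * y - alpha)
            y = y + config.dt * drift
            if config.sigma > 0.0:
                y = y + config.sigma * sqdt * rng.standard_normal(n)
        states.append(y.copy())
    distress = [_observe(s, config) for s in states]
    return _assemble_panel(baseline, distress, config)


def gen_linear_panel(config: SimConfig, seed: int) -> PanelDataset:
    """Null-model panel: same covariate structure, purely linear dynamics.

    Wave-1 distress is a clipped Gaussian loading on the latent factor;
    each later wave is ``c0 + c1*d + c2*cse + c3*asym + noise`` clipped to
    the scale. No cusp structure anywhere.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_state = ss.spawn(2)
    baseline = gen_covariates(config, _seed_int(s_cov))
    rng = np.random.default_rng(_seed_int(s_state))
    n = len(baseline)
    lin = config.linear
    spec = lin.distress
    lam = spec.loading
    mu, s = _declip_params(spec.mean, spec.sd, spec.lo, spec.hi)
    raw = lam * baseline["_latent"].to_numpy() + math.sqrt(1 - lam * lam) * rng.standard_normal(n)
    lo, hi = config.state_range
    d = np.clip(mu + s * raw, lo, hi)
    cse = baseline["cse"].to_numpy()
    asym = baseline[config.asymmetry_source].to_numpy()
    waves = [d]
    for _ in config.wave_labels[1:]:
        nxt = lin.c0 + lin.c1 * waves[-1] + lin.c2 * cse + lin.c3 * asym
        if lin.noise > 0:
            nxt = nxt + lin.noise * rng.standard_normal(n)
        waves.append(np.clip(nxt, lo, hi))
    return _assemble_panel(baseline, waves, config)


# ---------------------------------------------------------------------------
# missingness and attrition
# ---------------------------------------------------------------------------

def _wave_columns(panel: PanelDataset) -> Dict[str, list]:
    cols: Dict[str, list] = {w: [] for w in panel.wave_labels}
    for c in panel.data.columns:
        for w in panel.wave_labels:
            if c.endswith(f"_{w.lower()}"):
                cols[w].append(c)
    return cols


def inject_missing(panel: PanelDataset, rate, seed: int) -> PanelDataset:
    """MCAR cell deletion on per-wave measure columns.

    ``rate`` is a scalar or one rate per wave; time-invariant columns are
    untouched (item missingness in these designs concerns the repeated
    measures).
    """
    rates = (
        [float(rate)] * len(panel.wave_labels)
        if np.isscalar(rate)
        else [float(r) for r in rate]
    )
    if not all(0.0 <= r <= 1.0 for r in rates):
        raise SimConfigError("missing rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = panel.data.copy()
    for w, r in zip(panel.wave_labels, rates):
        if r == 0.0:
            continue
        for c in _wave_columns(panel)[w]:
            hole = rng.random(len(data)) < r
            data.loc[hole, c] = np.nan
    return PanelDataset(data, panel.wave_labels, dict(panel.ranges))


def inject_attrition(panel: PanelDataset, rates: Sequence[float], seed: int) -> PanelDataset:
    """Monotone dropout: each follow-up wave is lost with its own probability.

    A subject who drops at wave k loses that wave and all later waves;
    wave 1 is never deleted.
    """
    rates = [float(r) for r in rates]
    if len(rates) != len(panel.wave_labels) - 1:
        raise SimConfigError("need one attrition rate per follow-up wave")
    if not all(0.0 <= r <= 1.0 for r in rates):
        raise SimConfigError("attrition rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = panel.data.copy()
    n = len(data)
    gone = np.zeros(n, dtype=bool)
    wave_cols = _wave_columns(panel)
    for w, r in zip(panel.wave_labels[1:], rates):
        gone |= rng.random(n) < r
        for c in wave_cols[w]:
            data.loc[gone, c] = np.nan
    return PanelDataset(data, panel.wave_labels, dict(panel.ranges))


# ---------------------------------------------------------------------------
# end-to-end generation
# ---------------------------------------------------------------------------

def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0])


def simulate_panel(config: SimConfig, seed: int) -> PanelDataset:
    """Full cusp-condition panel: covariates, diffusion, missingness, attrition."""
    ss = np.random.SeedSequence(seed)
    s_cov, s_sde, s_miss, s_att = ss.spawn(4)
    baseline = gen_covariates(config, _seed_int(s_cov))
    panel = simulate_waves_sde(baseline, config, _seed_int(s_sde))
    if any(r > 0 for r in config.missing_rates):
        panel = inject_missing(panel, config.missing_rates, _seed_int(s_miss))
    if any(r > 0 for r in config.attrition_rates):
        panel = inject_attrition(panel, config.attrition_rates, _seed_int(s_att))
    return panel
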