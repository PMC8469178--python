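"""Synthetic-data generation by inverse-transform sampling.

Lifetimes are drawn by solving sf(t) = u for u ~ Uniform(0,1) on the
monotone survival function; exponential baselines use the closed-form
inverse, every other model a bracketed root-finder on the quadrature
survival function. Frailty values are drawn through analytic quantile
functions. Regression datasets draw covariates, verify model validity for
every profile, and invert each subject's survival function, with one RNG
substream per subject index so the first k subjects are reproducible when
n changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .baseline import (
    BaselineVitality,
    ConditionalPVIT,
    XI_ONE_TOL,
    conditional_sf,
)
from .errors import HorizonError, InvalidParameterError, UnsupportedFamilyError
from .frailty import FrailtyDistribution, MixtureModel
from .regression import (
    RegressionModel,
    Subject,
    SurvivalDataset,
    Trajectory,
    _hazard_parts,
)

#: absolute tolerance in t for lifetime root-finding
ROOT_TOL = 1e-10


# ---------------------------------------------------------------------------
# conditional lifetimes
# ---------------------------------------------------------------------------

def _invert_exponential(rate: float, xi: float, u: np.ndarray) -> np.ndarray:
    """Closed-form quantile of the exponential-baseline survival: solve
    [(xi-1)*rate*t/xi + 1]^(-xi/(xi-1)) = u."""
    if abs(xi - 1.0) < XI_ONE_TOL:
        return -np.log(u) / rate
    return xi / ((xi - 1.0) * rate) * (u ** (-(xi - 1.0) / xi) - 1.0)


def _invert_generic(model: ConditionalPVIT, u: float, horizon_cap: float = 1e6) -> float:
    if u >= 1.0:
        return 0.0
    hi = 2.0 * model.xi * model.baseline.mean
    while conditional_sf(model, hi) > u:
        hi *= 2.0
        if hi > horizon_cap:
            raise HorizonError(f"quantile for u={u:g} not bracketed below t={horizon_cap:g}")
    return float(
        optimize.brentq(lambda t: conditional_sf(model, t) - u, 0.0, hi, xtol=ROOT_TOL)
    )


def sample_conditional(model: ConditionalPVIT, n: int, seed: int) -> np.ndarray:
    """n lifetimes from the fixed-growth model via inverse transform."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    if model.baseline.family == "exponential" and model.xi >= 1.0:
        return _invert_exponential(model.baseline.params["rate"], model.xi, u)
    return np.array([_invert_generic(model, ui) for ui in u])


def sample_frailty(dist: FrailtyDistribution, n: int, seed: int) -> np.ndarray:
    """n growth values via the analytic quantile function."""
    if dist.ppf is None:
        raise UnsupportedFamilyError(
            f"frailty {dist.label!r} has no quantile function; sampling unsupported"
        )
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return np.array([float(dist.ppf(ui)) for ui in u])


def sample_mixture(model: MixtureModel, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage draw: frailty first, then the conditional lifetime at that
    growth. Returns (times, frailties)."""
    if model.frailty.ppf is None:
        raise UnsupportedFamilyError(
            f"frailty {model.frailty.label!r} has no quantile function"
        )
    rng = np.random.default_rng(seed)
    u_xi = rng.uniform(size=n)
    u_t = rng.uniform(size=n)
    xis = np.array([float(model.frailty.ppf(ui)) for ui in u_xi])
    times = np.empty(n)
    for i, (xi, u) in enumerate(zip(xis, u_t)):
        if model.baseline.family == "exponential" and xi >= 1.0:
            times[i] = float(_invert_exponential(model.baseline.params["rate"], xi, np.float64(u)))
        else:
            times[i] = _invert_generic(ConditionalPVIT(model.baseline, xi), u)
    return times, xis


# ---------------------------------------------------------------------------
# regression datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Recipe for a synthetic regression dataset.

    Defaults emulate a two-covariate observational study: one balanced
    time-free covariate (z1 = +-1, e.g. a binary exposure) and one
    non-negative instantaneous covariate trajectory (constant unit dose, or
    a unit-mean sinusoid for "sinusoid"), with coefficients acting through
    the exponential growth function. Trajectories are kept non-negative so
    that positive coefficients never drive the vitality downward.
    """

    seed: int
    n: int
    baseline: BaselineVitality
    alpha: Sequence[float] = ()
    beta: Sequence[float] = ()
    z1_dist: str = "balanced"        # "balanced" (+-1) or "normal"
    traj_family: str = "constant"    # "constant" or "sinusoid"
    horizon: float = 50.0
    max_retries: int = 100

    def __post_init__(self):
        if self.n <= 0:
            raise InvalidParameterError("n must be positive")
        if self.z1_dist not in ("balanced", "normal"):
            raise InvalidParameterError(f"unknown z1_dist {self.z1_dist!r}")
        if self.traj_family not in ("constant", "sinusoid"):
            raise InvalidParameterError(f"unknown traj_family {self.traj_family!r}")


def _draw_profile(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, Trajectory]:
    p, l = len(cfg.alpha), len(cfg.beta)
    if cfg.z1_dist == "balanced":
        z1 = rng.choice([-1.0, 1.0], size=p)
    else:
        z1 = rng.standard_normal(p)
    if l == 0:
        traj = Trajectory.empty()
    elif cfg.traj_family == "constant":
        traj = Trajectory.constant(np.ones(l), cfg.horizon)
    else:
        omega = rng.uniform(0.5, 2.0, size=l)
        phase = rng.uniform(0.0, 2.0 * math.pi, size=l)
        s = np.linspace(0.0, cfg.horizon, 513)
        vals = 1.0 + 0.5 * np.sin(np.outer(s, omega) + phase)
        traj = Trajectory(s, vals)
    return z1, traj


def _subject_valid(model: RegressionModel, subj: Subject) -> bool:
    grid = np.linspace(0.0, model.horizon, 256)
    N, D = _hazard_parts(model, subj, grid)
    return bool(np.all(D[1:] > 0) and np.all(N >= 0))


def _invert_regression(model: RegressionModel, subj: Subject, u: float) -> float:
    """Solve sf(t) = u, i.e. cumulative hazard = -log u, by bracketed
    root-finding on a Gauss-Legendre cumulative hazard."""
    target = -math.log(u)
    nodes, weights = np.polynomial.legendre.leggauss(64)

    def cumhaz(t: float) -> float:
        x = 0.5 * t * (nodes + 1.0)
        N, D = _hazard_parts(model, subj, x)
        return float((0.5 * t * weights) @ (N / D))

    hi = model.baseline.mean
    while cumhaz(hi) < target:
        hi *= 2.0
        if hi > model.horizon:
            raise HorizonError(
                f"event time for u={u:g} lies beyond the declared horizon {model.horizon:g}"
            )
    return float(optimize.brentq(lambda t: cumhaz(t) - target, 1e-12, hi, xtol=ROOT_TOL))


def simulate_regression_dataset(cfg: SimulationConfig) -> SurvivalDataset:
    """Draw a fully observed regression dataset under the configured model.

    One RNG substream per subject index: with the same seed, subject i is
    identical whatever n is. Covariate profiles violating model validity on
    [0, horizon] are redrawn (at most ``max_retries`` times each).
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n)
    alpha = np.asarray(cfg.alpha, dtype=float)
    beta = np.asarray(cfg.beta, dtype=float)
    subjects = []
    for child in children:
        rng = np.random.default_rng(child)
        for attempt in range(cfg.max_retries):
            z1, traj = _draw_profile(cfg, rng)
            probe = Subject(1.0, z1, traj)
            model = RegressionModel(cfg.baseline, alpha, beta, horizon=cfg.horizon)
            if _subject_valid(model, probe):
                break
            warnings.warn("resampling a covariate profile that violates model validity")
        else:
            raise InvalidParameterError(
                "could not draw a valid covariate profile; check (alpha, beta)"
            )
        u = rng.uniform()
        t = _invert_regression(model, probe, u)
        subjects.append(Subject(t, z1, traj))
    return SurvivalDataset(subjects)
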