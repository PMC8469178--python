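"""Time-dependent proportional-vitalities regression and maximum likelihood.

The growth parameter becomes a covariate-driven function of age,

    xi(t, gamma) = exp(alpha' z1 + beta' z2(t)),

where z1 holds p time-free covariates and z2(t) is the componentwise running
integral of l instantaneous covariate trajectories zeta2(s). The vitality of
subject i is V(t) = xi(t, gamma) V0(t), which yields the survival function

    sf(t) = exp(- int_0^t d{xi V0}/dx / (xi V0 - x) dx)

with hazard

    h(x) = (V0'(x) + beta' zeta2(x) V0(x)) / (V0(x) - x e^{-eta(x)}),
    eta(x) = alpha' z1 + beta' z2(x),

valid wherever the denominator is positive (xi(x) V0(x) > x) and the
numerator non-negative (the vitality must not decrease). With the baseline
V0 fully specified and uncensored event times, the log-likelihood is a sum
of log-hazard-minus-cumulative-hazard terms; the score is available in
closed form and the maximum-likelihood estimate is found by Newton-Raphson
with a finite-difference Hessian of the analytic score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .baseline import BaselineVitality
from .errors import (
    ConvergenceError,
    InvalidParameterError,
    ModelInvalidError,
    NumericalError,
)
from ._numdiff import jacobian

#: Gauss-Legendre order for the per-subject cumulative-hazard integral
GL_ORDER = 64
#: linear predictors beyond this overflow exp()
MAX_LINPRED = 700.0
#: dense grid size used to integrate callable covariate trajectories
TRAJ_GRID = 1025

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(GL_ORDER)


def _eval_vec(f: Callable, x: np.ndarray) -> np.ndarray:
    """Evaluate a scalar-or-vectorized callable on an array."""
    try:
        out = np.asarray(f(x), dtype=float)
        if out.shape == x.shape:
            return out
    except (TypeError, ValueError):
        pass
    out = np.array([float(f(v)) for v in x])
    return out


# ---------------------------------------------------------------------------
# covariate trajectories
# ---------------------------------------------------------------------------

class Trajectory:
    """l instantaneous covariate trajectories zeta2 and their running
    integrals z2, held on a dense grid with linear interpolation.

    Grid storage makes z2 the exact trapezoid integral of the stored zeta2
    and keeps every likelihood evaluation a vectorized interpolation.
    """

    def __init__(self, s_grid: np.ndarray, values: np.ndarray):
        s_grid = np.asarray(s_grid, dtype=float)
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] != s_grid.size:
            values = values.T
        if s_grid.size < 2 or np.any(np.diff(s_grid) <= 0):
            raise InvalidParameterError("trajectory grid must be increasing with >= 2 points")
        if s_grid[0] != 0.0:
            raise InvalidParameterError("trajectory grid must start at s = 0")
        self.s_grid = s_grid
        self.values = values                      # (m, l)
        self.l = values.shape[1]
        self.cum = np.vstack(
            [np.zeros(self.l),
             integrate.cumulative_trapezoid(values, s_grid, axis=0)]
        ) if self.l else np.zeros((s_grid.size, 0))

    @classmethod
    def empty(cls) -> "Trajectory":
        t = cls.__new__(cls)
        t.s_grid = np.array([0.0, 1.0])
        t.values = np.zeros((2, 0))
        t.cum = np.zeros((2, 0))
        t.l = 0
        return t

    @classmethod
    def from_callable(cls, f: Callable[[float], Sequence[float]], horizon: float,
                      n: int = TRAJ_GRID) -> "Trajectory":
        s = np.linspace(0.0, horizon, n)
        vals = np.array([np.atleast_1d(f(si)) for si in s], dtype=float)
        return cls(s, vals)

    @classmethod
    def constant(cls, values: Sequence[float], horizon: float) -> "Trajectory":
        v = np.atleast_1d(np.asarray(values, dtype=float))
        return cls(np.array([0.0, horizon]), np.vstack([v, v]))

    def zeta2(self, x) -> np.ndarray:
        """Instantaneous covariates at time(s) x, shape (..., l)."""
        x = np.asarray(x, dtype=float)
        if self.l == 0:
            return np.zeros(x.shape + (0,))
        cols = [np.interp(x, self.s_grid, self.values[:, k]) for k in range(self.l)]
        return np.stack(cols, axis=-1)

    def z2(self, x) -> np.ndarray:
        """Cumulative covariates z2(x) = int_0^x zeta2(s) ds, shape (..., l)."""
        x = np.asarray(x, dtype=float)
        if self.l == 0:
            return np.zeros(x.shape + (0,))
        cols = [np.interp(x, self.s_grid, self.cum[:, k]) for k in range(self.l)]
        return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class Subject:
    """One fully observed subject: event time, time-free covariates,
    instantaneous covariate trajectory."""

    time: float
    z1: np.ndarray
    traj: Trajectory

    def __post_init__(self):
        if not (self.time > 0 and math.isfinite(self.time)):
            raise InvalidParameterError(f"event time must be positive and finite, got {self.time}")
        object.__setattr__(self, "z1", np.atleast_1d(np.asarray(self.z1, dtype=float)))


@dataclass
class SurvivalDataset:
    """n uncensored subjects with covariates; p time-free and l time-varying."""

    subjects: list[Subject]

    def __post_init__(self):
        if not self.subjects:
            raise InvalidParameterError("dataset must contain at least one subject")
        p = self.subjects[0].z1.size
        l = self.subjects[0].traj.l
        for s in self.subjects:
            if s.z1.size != p or s.traj.l != l:
                raise InvalidParameterError("all subjects must share covariate dimensions")
        self.p = p
        self.l = l

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.subjects])

    # ---- CSV round trip --------------------------------------------------

    def to_csv(self, data_path, traj_path=None) -> None:
        rows = {
            "id": np.arange(len(self.subjects)),
            "time": self.times,
        }
        for k in range(self.p):
            rows[f"z1_{k + 1}"] = [s.z1[k] for s in self.subjects]
        pd.DataFrame(rows).to_csv(data_path, index=False)
        if traj_path is not None and self.l > 0:
            frames = []
            for i, s in enumerate(self.subjects):
                d = {"id": i, "s": s.traj.s_grid}
                for k in range(self.l):
                    d[f"zeta2_{k + 1}"] = s.traj.values[:, k]
                frames.append(pd.DataFrame(d))
            pd.concat(frames, ignore_index=True).to_csv(traj_path, index=False)

    @classmethod
    def from_csv(cls, data_path, traj_path=None) -> "SurvivalDataset":
        df = pd.read_csv(data_path)
        z1_cols = sorted(
            (c for c in df.columns if c.startswith("z1_")),
            key=lambda c: int(c.split("_")[1]),
        )
        traj_by_id: dict = {}
        if traj_path is not None:
            tf = pd.read_csv(traj_path)
            zcols = sorted(
                (c for c in tf.columns if c.startswith("zeta2_")),
                key=lambda c: int(c.split("_")[1]),
            )
            for sid, grp in tf.groupby("id"):
                grp = grp.sort_values("s")
                traj_by_id[sid] = Trajectory(grp["s"].to_numpy(), grp[zcols].to_numpy())
        subjects = []
        for _, row in df.iterrows():
            traj = traj_by_id.get(row["id"], Trajectory.empty())
            subjects.append(
                Subject(float(row["time"]), row[z1_cols].to_numpy(dtype=float), traj)
            )
        return cls(subjects)


@dataclass(frozen=True)
class RegressionModel:
    """Time-dependent proportional-vitalities model with coefficients
    gamma = (alpha, beta) acting on a known baseline vitality V0."""

    baseline: BaselineVitality
    alpha: np.ndarray
    beta: np.ndarray
    horizon: float = 50.0

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, dtype=float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))


# ---------------------------------------------------------------------------
# model quantities
# ---------------------------------------------------------------------------

def _linpred(model: RegressionModel, subject: Subject, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lp = float(model.alpha @ subject.z1) + subject.traj.z2(x) @ model.beta
    if np.any(np.abs(lp) > MAX_LINPRED):
        raise NumericalError("linear predictor exceeds the exp() overflow threshold")
    return lp


def growth_function(model: RegressionModel, subject: Subject, t: float) -> float:
    """xi(t, gamma) = exp(alpha' z1 + beta' z2(t))."""
    return float(np.exp(_linpred(model, subject, t)))


def regression_mrl(model: RegressionModel, subject: Subject, t: float) -> float:
    """Mean residual life M(t) = xi(t) M0(t) + (xi(t) - 1) t; non-negativity
    is equivalent to the validity condition xi(t) V0(t) > t."""
    xi = growth_function(model, subject, t)
    m0 = model.baseline.mrl(t)
    m = xi * m0 + (xi - 1.0) * t
    if m < 0:
        raise ModelInvalidError(f"negative mrl at t={t:g}: model invalid there", t=t)
    return m


def _hazard_parts(model: RegressionModel, subject: Subject, x: np.ndarray):
    """Return (N, D) with hazard = N / D on the array x."""
    v0 = _eval_vec(model.baseline.v0, x)
    dv0 = _eval_vec(model.baseline.dv0, x)
    if np.isscalar(dv0) or dv0.shape != x.shape:
        dv0 = np.broadcast_to(dv0, x.shape)
    eta = _linpred(model, subject, x)
    N = dv0 + (subject.traj.zeta2(x) @ model.beta) * v0
    D = v0 - x * np.exp(-eta)
    return N, D


def regression_sf(model: RegressionModel, subject: Subject, t: float) -> float:
    """Survival function by adaptive quadrature of the hazard on [0, t]."""
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    if t == 0:
        return 1.0
    screen = np.linspace(0.0, t, 64)
    _, D = _hazard_parts(model, subject, screen)
    if np.any(D <= 0):
        bad = screen[np.argmax(D <= 0)]
        raise ModelInvalidError(f"xi(x)V0(x) <= x at x={bad:g}", t=float(bad))

    def integrand(x: float) -> float:
        N, D = _hazard_parts(model, subject, np.atleast_1d(x))
        if D[0] <= 0:
            raise ModelInvalidError(f"xi(x)V0(x) <= x at x={x:g}", t=x)
        return float(N[0] / D[0])

    val, _ = integrate.quad(integrand, 0.0, t, epsabs=1e-10, limit=200)
    return math.exp(-val)


class SubjectValidity(NamedTuple):
    ok: bool                      # condition (i): xi(x) V0(x) > x on the grid
    hazard_nonnegative: bool      # the implied vitality is non-decreasing
    cumhaz_finite: bool           # condition (ii) at the horizon
    divergence: str               # condition (iii): "satisfied"/"indeterminate"


class ValidityReport(NamedTuple):
    ok: bool
    per_subject: list[SubjectValidity]


def check_validity(model: RegressionModel, dataset: SurvivalDataset,
                   n_grid: int = 256) -> ValidityReport:
    """Numerical check of the three validity conditions for each subject on
    [0, horizon]."""
    out = []
    for s in dataset.subjects:
        grid = np.linspace(0.0, model.horizon, n_grid)
        N, D = _hazard_parts(model, s, grid)
        cond_i = bool(np.all(D[1:] > 0))
        haz_ok = bool(np.all(N >= -1e-12))
        if cond_i:
            ch = float(np.trapezoid(np.clip(N, 0, None) / np.where(D > 0, D, np.inf), grid))
            cond_ii = math.isfinite(ch)
            div = "satisfied" if (ch > 30.0 or math.exp(-ch) < 1e-6) else "indeterminate"
        else:
            cond_ii = False
            div = "indeterminate"
        out.append(SubjectValidity(cond_i, haz_ok, cond_ii, div))
    return ValidityReport(all(v.ok and v.hazard_nonnegative and v.cumhaz_finite for v in out), out)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _SubjectCache:
    """Per-subject arrays frozen before optimization: Gauss-Legendre nodes on
    [0, t_i] and every covariate/baseline value the likelihood needs."""

    def __init__(self, baseline: BaselineVitality, s: Subject):
        t = s.time
        self.t = t
        self.z1 = s.z1
        half = 0.5 * t
        self.x = half * (_GL_NODES + 1.0)             # (GL_ORDER,)
        self.w = half * _GL_WEIGHTS
        self.v0 = _eval_vec(baseline.v0, self.x)
        dv0 = _eval_vec(baseline.dv0, self.x)
        self.dv0 = np.broadcast_to(dv0, self.x.shape) if dv0.shape != self.x.shape else dv0
        self.zeta2 = s.traj.zeta2(self.x)             # (GL_ORDER, l)
        self.z2 = s.traj.z2(self.x)                   # (GL_ORDER, l)
        self.v0_t = float(baseline.v0(t))
        self.dv0_t = float(baseline.dv0(t))
        self.zeta2_t = s.traj.zeta2(np.float64(t))    # (l,)
        self.z2_t = s.traj.z2(np.float64(t))          # (l,)


def _caches(baseline: BaselineVitality, dataset: SurvivalDataset) -> list[_SubjectCache]:
    return [_SubjectCache(baseline, s) for s in dataset.subjects]


def _subject_loglik(c: _SubjectCache, alpha: np.ndarray, beta: np.ndarray) -> float:
    a_z1 = float(alpha @ c.z1)
    eta = a_z1 + c.z2 @ beta
    if np.any(np.abs(eta) > MAX_LINPRED):
        return -math.inf
    E = np.exp(-eta)
    D = c.v0 - c.x * E
    N = c.dv0 + (c.zeta2 @ beta) * c.v0
    eta_t = a_z1 + float(c.z2_t @ beta)
    D_t = c.v0_t - c.t * math.exp(-eta_t)
    N_t = c.dv0_t + float(c.zeta2_t @ beta) * c.v0_t
    if D_t <= 0 or N_t <= 0 or np.any(D <= 0) or np.any(N < 0):
        return -math.inf
    cumhaz = float(c.w @ (N / D))
    return math.log(N_t) - math.log(D_t) - cumhaz


def _subject_score(c: _SubjectCache, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    a_z1 = float(alpha @ c.z1)
    eta = a_z1 + c.z2 @ beta
    E = np.exp(-eta)
    D = c.v0 - c.x * E
    N = c.dv0 + (c.zeta2 @ beta) * c.v0
    eta_t = a_z1 + float(c.z2_t @ beta)
    E_t = math.exp(-eta_t)
    D_t = c.v0_t - c.t * E_t
    N_t = c.dv0_t + float(c.zeta2_t @ beta) * c.v0_t

    xED2 = c.x * E / D**2
    # alpha_k: z1_k * [ int x N e^{-eta} / D^2 dx  -  t e^{-eta(t)} / D(t) ]
    common_a = float(c.w @ (N * xED2)) - c.t * E_t / D_t
    s_alpha = common_a * c.z1
    # beta_k: zeta2_k(t) V0(t)/N(t) - t e^{-eta(t)} z2_k(t)/D(t)
    #         - int zeta2_k V0 / D dx + int x N e^{-eta} z2_k / D^2 dx
    if c.z2_t.size:
        s_beta = (
            c.zeta2_t * c.v0_t / N_t
            - c.t * E_t / D_t * c.z2_t
            - (c.w * c.v0 / D) @ c.zeta2
            + (c.w * N * xED2) @ c.z2
        )
    else:
        s_beta = np.zeros(0)
    return np.concatenate([s_alpha, s_beta])


def log_likelihood(model: RegressionModel, dataset: SurvivalDataset,
                   _caches_override: list[_SubjectCache] | None = None) -> float:
    """Sum over subjects of log f(t_i); -inf when any subject violates
    validity at (alpha, beta). Compensated (exact) summation keeps the value
    invariant under permutation of the subjects."""
    caches = _caches_override or _caches(model.baseline, dataset)
    terms = [_subject_loglik(c, model.alpha, model.beta) for c in caches]
    if any(t == -math.inf for t in terms):
        return -math.inf
    return math.fsum(terms)


def score(model: RegressionModel, dataset: SurvivalDataset,
          _caches_override: list[_SubjectCache] | None = None) -> np.ndarray:
    """Analytic score (gradient of the log-likelihood) in the order
    (alpha_1..alpha_p, beta_1..beta_l)."""
    caches = _caches_override or _caches(model.baseline, dataset)
    parts = np.array([_subject_score(c, model.alpha, model.beta) for c in caches])
    return np.array([math.fsum(parts[:, j]) for j in range(parts.shape[1])])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    alpha: np.ndarray
    beta: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float
    observed_information: np.ndarray
    standard_errors: np.ndarray      # asymptotic, from the observed information
    trace: list = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])


def fit(
    dataset: SurvivalDataset,
    baseline: BaselineVitality,
    init: Sequence[float] | None = None,
    max_iter: int = 200,
    score_tol: float = 1e-6,
    step_tol: float = 1e-8,
    max_halvings: int = 30,
) -> FitResult:
    """Newton-Raphson maximum likelihood for (alpha, beta).

    The Hessian is a central finite difference of the analytic score;
    steps that do not improve the likelihood (or leave the valid region,
    where the likelihood is -inf) are halved. Initialization defaults to
    gamma = 0, the baseline model, which always lies in the valid region.
    """
    p, l = dataset.p, dataset.l
    caches = _caches(baseline, dataset)
    dim = p + l

    def ll(theta: np.ndarray) -> float:
        m = RegressionModel(baseline, theta[:p], theta[p:])
        return log_likelihood(m, dataset, _caches_override=caches)

    def sc(theta: np.ndarray) -> np.ndarray:
        m = RegressionModel(baseline, theta[:p], theta[p:])
        return score(m, dataset, _caches_override=caches)

    theta = np.zeros(dim) if init is None else np.asarray(init, dtype=float).copy()
    cur_ll = ll(theta)
    if not math.isfinite(cur_ll):
        raise InvalidParameterError("log-likelihood is not finite at the initial point")

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = sc(theta)
        trace.append({"iter": it, "loglik": cur_ll, "max_score": float(np.max(np.abs(g)))})
        if np.max(np.abs(g)) < score_tol:
            converged = True
            break
        H = jacobian(sc, theta)
        H = 0.5 * (H + H.T)
        # modified Newton: shift the spectrum so H - mu*I is safely negative
        # definite; the step is then always an ascent direction and stays
        # moderate when H is indefinite far from the optimum
        evals, evecs = np.linalg.eigh(H)
        delta = max(1e-6, 1e-2 * float(np.max(np.abs(evals))))
        mu = max(0.0, float(evals.max()) + delta)
        step = evecs @ ((evecs.T @ -g) / (evals - mu))
        new_ll = -math.inf
        for _ in range(max_halvings):
            cand = theta + step
            new_ll = ll(cand)
            if math.isfinite(new_ll) and new_ll >= cur_ll - 1e-12:
                break
            step = 0.5 * step
        if not math.isfinite(new_ll):
            raise ConvergenceError("step halving failed to find a valid ascent step", trace)
        if np.linalg.norm(step) < step_tol:
            theta = cand
            cur_ll = new_ll
            converged = True
            break
        theta, cur_ll = cand, new_ll
    else:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations", trace)

    H = jacobian(sc, theta)
    info = -0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(dim, np.nan)
    return FitResult(
        alpha=theta[:p],
        beta=theta[p:],
        converged=converged,
        n_iter=it,
        log_likelihood=cur_ll,
        observed_information=info,
        standard_errors=se,
        trace=trace,
    )
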