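"""Vitality-function calculus for the baseline law and the individual-level
proportional-vitalities (PVIT) model.

The vitality function of a lifetime X is V(t) = E(X | X >= t) = M(t) + t,
where M is the mean residual life. The PVIT model specifies a dependent
lifetime T through a multiplicative growth xi > 0 acting on a baseline
vitality v0:

    v(t | xi) = xi * v0(t).

The model is valid only where xi * v0(t) > t; its survival function is
recovered from the vitality relation as

    sf(t | xi) = exp(- int_0^t xi*v0'(x) / (xi*v0(x) - x) dx),

with hazard h(t | xi) = xi*v0'(x) / (xi*v0(t) - t). For an exponential
baseline (v0(t) = t + 1/lam) the survival function has the closed form

    sf(t | xi) = [1 / ((xi-1)*lam*t/xi + 1)]^(xi/(xi-1)),   xi != 1,

which is a generalized-Pareto tail and serves as the quadrature oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy import integrate

from .errors import (
    InvalidParameterError,
    ModelInvalidError,
    NumericalError,
)
from ._numdiff import central_difference

#: absolute tolerance of the cumulative-hazard quadrature
QUAD_ABS_TOL = 1e-10
#: number of grid points used for eager validity checks on an interval
VALIDITY_GRID = 64
#: xi this close to 1 dispatches to the exponential limit in the closed form
XI_ONE_TOL = 1e-8
#: cap for adaptive tail horizons in moment integrals
MAX_HORIZON = 1e6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineVitality:
    """The baseline law X described by its vitality function.

    Parameters
    ----------
    v0
        Baseline vitality, a non-decreasing function of age t >= 0.
    dv0
        Derivative of ``v0``.
    mean
        E(X); must equal ``v0(0)``.
    label
        Short human-readable tag.
    family, params
        Optional family name ("exponential", ...) with parameters; when set,
        closed-form fast paths (survival, sampling) become available.
    """

    v0: Callable[[float], float]
    dv0: Callable[[float], float]
    mean: float
    label: str = "baseline"
    family: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.mean > 0 and math.isfinite(self.mean)):
            raise InvalidParameterError(f"mean must be positive and finite, got {self.mean}")
        v00 = float(self.v0(0.0))
        if abs(v00 - self.mean) > 1e-8 * max(1.0, abs(self.mean)):
            raise InvalidParameterError(
                f"v0(0)={v00} must equal the mean E(X)={self.mean}"
            )

    def mrl(self, t: float) -> float:
        """Mean residual life M0(t) = v0(t) - t."""
        return float(self.v0(t)) - t


@dataclass(frozen=True)
class ConditionalPVIT:
    """The law T = (U | Xi = xi): a baseline plus a fixed scalar growth."""

    baseline: BaselineVitality
    xi: float

    def __post_init__(self):
        if not (self.xi > 0 and math.isfinite(self.xi)):
            raise InvalidParameterError(f"growth xi must be positive and finite, got {self.xi}")


class ValidityReport(NamedTuple):
    ok: bool
    first_violation: float | None


class ConditionalMoments(NamedTuple):
    mean: float
    second_moment: float
    variance: float


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def make_exponential_baseline(rate: float) -> BaselineVitality:
    """Exponential baseline with mean 1/rate: v0(t) = t + 1/rate.

    The exponential law has constant mean residual life 1/rate, hence a
    vitality function that is a unit-slope line.
    """
    if not (rate > 0 and math.isfinite(rate)):
        raise InvalidParameterError(f"rate must be positive, got {rate}")
    inv = 1.0 / rate
    return BaselineVitality(
        v0=lambda t: t + inv,
        dv0=lambda t: 1.0,
        mean=inv,
        label=f"exponential(rate={rate:g})",
        family="exponential",
        params={"rate": float(rate)},
    )


def make_custom_baseline(
    v0: Callable[[float], float],
    dv0: Callable[[float], float] | None = None,
    mean: float | None = None,
    label: str = "custom",
) -> BaselineVitality:
    """Wrap user-supplied vitality callables; the derivative is
    finite-differenced when not provided and the mean defaults to v0(0)."""
    if dv0 is None:
        dv0 = lambda t, _f=v0: central_difference(_f, max(t, 1e-6))  # noqa: E731
    if mean is None:
        mean = float(v0(0.0))
    return BaselineVitality(v0=v0, dv0=dv0, mean=mean, label=label, family="custom")


def baseline_from_config(cfg: dict) -> BaselineVitality:
    """Build a baseline from a JSON-style dict, e.g.
    ``{"family": "exponential", "rate": 3.0}``."""
    if not isinstance(cfg, dict) or "family" not in cfg:
        raise InvalidParameterError("baseline config must be a dict with a 'family' key")
    family = cfg["family"]
    if family == "exponential":
        unknown = set(cfg) - {"family", "rate"}
        if unknown:
            raise InvalidParameterError(f"unknown baseline config keys: {sorted(unknown)}")
        if "rate" not in cfg:
            raise InvalidParameterError("exponential baseline requires 'rate'")
        return make_exponential_baseline(float(cfg["rate"]))
    raise InvalidParameterError(f"unknown baseline family {family!r}")


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

def validate_growth(model: ConditionalPVIT, t_grid) -> ValidityReport:
    """Check the model-validity condition xi*v0(t) > t on a grid.

    Returns a pass/fail report; on failure, ``first_violation`` is the
    smallest grid point where the margin xi*v0(t) - t is non-positive.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.size == 0:
        raise InvalidParameterError("t_grid must be non-empty")
    for t in t_grid:
        if model.xi * float(model.baseline.v0(t)) - t <= 0.0:
            return ValidityReport(False, float(t))
    return ValidityReport(True, None)


def _check_valid_interval(model: ConditionalPVIT, t: float) -> None:
    """Eager validity screen on [0, t] before integrating."""
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    if t == 0:
        return
    grid = np.linspace(0.0, t, VALIDITY_GRID)
    rep = validate_growth(model, grid)
    if not rep.ok:
        raise ModelInvalidError(
            f"xi*v0(t) <= t at t={rep.first_violation:g} (xi={model.xi:g})",
            t=rep.first_violation,
        )


# ---------------------------------------------------------------------------
# conditional model quantities
# ---------------------------------------------------------------------------

def conditional_vitality(model: ConditionalPVIT, t: float) -> float:
    """v(t | xi) = xi * v0(t)."""
    margin = model.xi * float(model.baseline.v0(t)) - t
    if margin <= 0.0:
        raise ModelInvalidError(f"model invalid at t={t:g}: xi*v0(t) <= t", t=t)
    return margin + t


def conditional_hazard(model: ConditionalPVIT, t: float) -> float:
    """h(t | xi) = xi*v0'(t) / (xi*v0(t) - t); non-increasing in xi."""
    denom = model.xi * float(model.baseline.v0(t)) - t
    if denom <= 0.0:
        raise ModelInvalidError(f"hazard undefined at t={t:g}: xi*v0(t) <= t", t=t)
    return model.xi * float(model.baseline.dv0(t)) / denom


def cumulative_hazard(model: ConditionalPVIT, t: float) -> float:
    """int_0^t xi*v0'(x) / (xi*v0(x) - x) dx by adaptive quadrature."""
    _check_valid_interval(model, t)
    if t == 0.0:
        return 0.0
    xi, v0, dv0 = model.xi, model.baseline.v0, model.baseline.dv0

    def integrand(x: float) -> float:
        denom = xi * float(v0(x)) - x
        if denom <= 0.0:
            raise ModelInvalidError(f"xi*v0(x) <= x inside quadrature at x={x:g}", t=x)
        return xi * float(dv0(x)) / denom

    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            val, err = integrate.quad(integrand, 0.0, t, epsabs=QUAD_ABS_TOL, limit=200)
        except integrate.IntegrationWarning as exc:  # pragma: no cover - defensive
            raise NumericalError(f"cumulative-hazard quadrature failed: {exc}") from exc
    return val


def conditional_sf(model: ConditionalPVIT, t: float) -> float:
    """Survival function sf(t | xi) = exp(-cumulative_hazard)."""
    return math.exp(-cumulative_hazard(model, t))


def conditional_pdf(model: ConditionalPVIT, t: float) -> float:
    """Density f(t | xi) = h(t | xi) * sf(t | xi)."""
    return conditional_hazard(model, t) * conditional_sf(model, t)


def exponential_closed_form_sf(rate: float, xi: float, t: float) -> float:
    """Closed-form survival of the PVIT model over an exponential baseline.

    sf(t | xi) = [1 / ((xi-1)*rate*t/xi + 1)]^(xi/(xi-1)) for xi != 1; the
    xi -> 1 limit is exp(-rate*t). Valid for xi > 1 (the printed form); the
    quadrature route handles 0 < xi < 1 where the model is still valid.
    """
    if not (rate > 0 and math.isfinite(rate)):
        raise InvalidParameterError(f"rate must be positive, got {rate}")
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    if abs(xi - 1.0) < XI_ONE_TOL:
        return math.exp(-rate * t)
    if xi < 1.0:
        raise InvalidParameterError(
            "closed form requires xi > 1; use conditional_sf for 0 < xi < 1"
        )
    base = (xi - 1.0) * rate * t / xi + 1.0
    return base ** (-xi / (xi - 1.0))


def _fast_conditional_sf(baseline: BaselineVitality, xi: float, t: float) -> float:
    """Survival via closed form when the family supplies one, else quadrature.

    Used by mixture and sampling code where the survival function is evaluated
    many times; the quadrature route stays the reference implementation.
    """
    if baseline.family == "exponential" and xi >= 1.0 - XI_ONE_TOL:
        return exponential_closed_form_sf(baseline.params["rate"], max(xi, 1.0), t)
    return conditional_sf(ConditionalPVIT(baseline, xi), t)


def _fast_conditional_pdf(baseline: BaselineVitality, xi: float, t: float) -> float:
    sf = _fast_conditional_sf(baseline, xi, t)
    denom = xi * float(baseline.v0(t)) - t
    if denom <= 0.0:
        raise ModelInvalidError(f"model invalid at t={t:g}", t=t)
    return xi * float(baseline.dv0(t)) / denom * sf


def vitality_mrl_convert(v_or_m: Callable[[float], float], t: float, direction: str) -> float:
    """Convert between vitality and mean-residual-life at age t.

    direction "to_mrl": M(t) = V(t) - t; direction "to_vitality": V(t) = M(t) + t.
    A negative resulting mrl signals the input is not a vitality function.
    """
    value = float(v_or_m(t))
    if direction == "to_mrl":
        m = value - t
        if m < 0:
            raise InvalidParameterError(
                f"V(t)-t = {m:g} < 0 at t={t:g}: input is not a vitality function"
            )
        return m
    if direction == "to_vitality":
        if value < 0:
            raise InvalidParameterError(f"mrl must be non-negative, got {value:g}")
        return value + t
    raise InvalidParameterError(f"direction must be 'to_mrl' or 'to_vitality', got {direction!r}")


# ---------------------------------------------------------------------------
# tail integrals
# ---------------------------------------------------------------------------

def _adaptive_tail_integral(f: Callable[[float], float], sf_tail: Callable[[float], float]) -> float:
    """Integrate f over [0, inf) by doubling a horizon until the survival
    tail drops below 1e-12; capped at MAX_HORIZON with a warning."""
    horizon = 8.0
    while sf_tail(horizon) > 1e-12 and horizon < MAX_HORIZON:
        horizon *= 2.0
    if horizon >= MAX_HORIZON:
        warnings.warn("tail horizon capped at 1e6 time units; result may be truncated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(f, 0.0, horizon, epsabs=1e-12, limit=400)
    return val
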