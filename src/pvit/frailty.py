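"""Random-growth (frailty) proportional-vitalities model.

The growth parameter is promoted to a random variable Xi with density g on a
support [c, inf). The observable lifetime U is the mixture

    sf_U(t) = int sf(t | xi) g(xi) dxi,

and Bayes' rule refreshes the frailty density given the data: g(xi | U = t)
weights g by the conditional density f(t | xi), while the survivor posterior
g(xi | U > t) weights by sf(t | xi). Likelihood-ratio monotonicity of those
posteriors, the mixture-vitality identity

    v_U(t) = E[Xi * sf(t|Xi)] / E[sf(t|Xi)] * v0(t),

hazard-rate comparisons between U and the baseline X, and moment-based
survival bounds for the conditional law are all implemented as numerical
diagnostics on caller-supplied grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy import integrate

from .baseline import (
    BaselineVitality,
    ConditionalPVIT,
    ConditionalMoments,
    _fast_conditional_pdf,
    _fast_conditional_sf,
    conditional_hazard,
    conditional_sf,
)
from .errors import (
    BoundUnavailableError,
    DegeneratePosteriorError,
    InvalidParameterError,
    ModelInvalidError,
    NumericalError,
)

#: slack for grid-based monotonicity comparisons (floating-point jitter)
ORDER_SLACK = 1e-9
#: default horizon over which joint validity of a mixture model is screened
DEFAULT_HORIZON = 100.0


# ---------------------------------------------------------------------------
# frailty distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrailtyDistribution:
    """Mixing law of the random vitality growth Xi.

    ``pdf`` is the density g on [support_low, support_high); ``cdf`` and
    ``ppf`` are optional analytic companions used by the samplers. ``mean``
    may be ``inf`` (heavy-tailed growth is allowed). ``atom`` marks a
    point mass, for which all mixture integrals collapse to evaluation.
    """

    pdf: Callable[[float], float]
    support_low: float
    support_high: float = math.inf
    mean: float = math.nan
    cdf: Callable[[float], float] | None = None
    ppf: Callable[[float], float] | None = None
    label: str = "frailty"
    atom: float | None = None

    def __post_init__(self):
        if self.support_low < 0:
            raise InvalidParameterError("frailty support must be non-negative")
        if self.support_high <= self.support_low and self.atom is None:
            raise InvalidParameterError("support_high must exceed support_low")


def pareto_unit_frailty() -> FrailtyDistribution:
    """g(xi) = 1/xi^2 on [1, inf): unit-Pareto growth with E(Xi) = inf."""
    return FrailtyDistribution(
        pdf=lambda x: 1.0 / x**2 if x >= 1.0 else 0.0,
        support_low=1.0,
        mean=math.inf,
        cdf=lambda x: 1.0 - 1.0 / x if x >= 1.0 else 0.0,
        ppf=lambda u: 1.0 / (1.0 - u) if u < 1.0 else math.inf,
        label="pareto_unit",
    )


def uniform_frailty(low: float, high: float) -> FrailtyDistribution:
    if not (0 <= low < high):
        raise InvalidParameterError(f"need 0 <= low < high, got [{low}, {high}]")
    w = high - low
    return FrailtyDistribution(
        pdf=lambda x: 1.0 / w if low <= x <= high else 0.0,
        support_low=low,
        support_high=high,
        mean=0.5 * (low + high),
        cdf=lambda x: min(max((x - low) / w, 0.0), 1.0),
        ppf=lambda u: low + u * w,
        label=f"uniform[{low:g},{high:g}]",
    )


def point_frailty(loc: float) -> FrailtyDistribution:
    """Degenerate growth: Xi = loc almost surely."""
    if loc <= 0:
        raise InvalidParameterError("point frailty location must be positive")
    return FrailtyDistribution(
        pdf=lambda x: math.inf if x == loc else 0.0,
        support_low=loc,
        support_high=loc,
        mean=loc,
        cdf=lambda x: 1.0 if x >= loc else 0.0,
        ppf=lambda u: loc,
        label=f"point({loc:g})",
        atom=loc,
    )


def frailty_from_config(cfg: dict) -> FrailtyDistribution:
    """Build a frailty law from a JSON-style dict."""
    if not isinstance(cfg, dict) or "family" not in cfg:
        raise InvalidParameterError("frailty config must be a dict with a 'family' key")
    family = cfg["family"]
    keys = set(cfg) - {"family"}
    if family == "pareto_unit":
        if keys:
            raise InvalidParameterError(f"unknown frailty config keys: {sorted(keys)}")
        return pareto_unit_frailty()
    if family == "uniform":
        if keys - {"low", "high"}:
            raise InvalidParameterError(f"unknown frailty config keys: {sorted(keys - {'low', 'high'})}")
        return uniform_frailty(float(cfg["low"]), float(cfg["high"]))
    if family == "point":
        if keys - {"loc"}:
            raise InvalidParameterError(f"unknown frailty config keys: {sorted(keys - {'loc'})}")
        return point_frailty(float(cfg["loc"]))
    raise InvalidParameterError(f"unknown frailty family {family!r}")


@dataclass(frozen=True)
class MixtureModel:
    """Baseline law plus a frailty distribution over the growth parameter.

    Joint validity requires the lower support c of Xi to dominate
    sup_t t/v0(t) on the declared horizon, so that every realizable growth
    yields a valid conditional model with a time-free support.
    """

    baseline: BaselineVitality
    frailty: FrailtyDistribution
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self):
        grid = np.linspace(0.0, self.horizon, 256)[1:]
        ratio = np.array([t / float(self.baseline.v0(t)) for t in grid])
        sup = float(ratio.max())
        if self.frailty.support_low < sup:
            raise ModelInvalidError(
                f"frailty support_low={self.frailty.support_low:g} below "
                f"sup t/v0(t)={sup:g} on [0, {self.horizon:g}]"
            )


# ---------------------------------------------------------------------------
# expectations over the frailty law
# ---------------------------------------------------------------------------

def _frailty_expectation(dist: FrailtyDistribution, fn: Callable[[float], float]) -> float:
    """E[fn(Xi)] by quadrature; [c, inf) is mapped to [0, 1) via u = 1 - c/xi
    so heavy tails need no truncation."""
    if dist.atom is not None:
        return fn(dist.atom)
    if math.isfinite(dist.support_high):
        val, _ = integrate.quad(
            lambda x: fn(x) * dist.pdf(x),
            dist.support_low,
            dist.support_high,
            epsabs=1e-11,
            limit=200,
        )
        return val
    c = dist.support_low if dist.support_low > 0 else 1.0

    def integrand(u: float) -> float:
        xi = c / (1.0 - u)
        return fn(xi) * dist.pdf(xi) * c / (1.0 - u) ** 2

    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-11, limit=200)
    return val


def mixture_sf(model: MixtureModel, t: float) -> float:
    """Unconditional survival sf_U(t) = E[sf(t | Xi)]."""
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    if t == 0:
        return 1.0
    return _frailty_expectation(
        model.frailty, lambda xi: _fast_conditional_sf(model.baseline, xi, t)
    )


def mixture_pdf(model: MixtureModel, t: float) -> float:
    """Unconditional density f_U(t) = E[f(t | Xi)]."""
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    return _frailty_expectation(
        model.frailty, lambda xi: _fast_conditional_pdf(model.baseline, xi, t)
    )


def mixture_hazard(model: MixtureModel, t: float) -> float:
    """Hazard of U; also the survivor-posterior average of h(t | xi)."""
    sf = mixture_sf(model, t)
    if sf <= 0.0 or not math.isfinite(sf):
        raise NumericalError(f"mixture survival underflowed at t={t:g}")
    return mixture_pdf(model, t) / sf


def mixture_vitality(model: MixtureModel, t: float) -> float:
    """Mixture vitality v_U(t) = E[Xi*sf(t|Xi)] / E[sf(t|Xi)] * v0(t).

    Returns ``inf`` (a flag, not an error) when E(Xi) is infinite: the
    numerator then diverges because sf(t|xi) is non-decreasing in xi and
    bounded below by sf(t|c) > 0.
    """
    if math.isinf(model.frailty.mean):
        return math.inf
    num = _frailty_expectation(
        model.frailty, lambda xi: xi * _fast_conditional_sf(model.baseline, xi, t)
    )
    den = _frailty_expectation(
        model.frailty, lambda xi: _fast_conditional_sf(model.baseline, xi, t)
    )
    return num / den * float(model.baseline.v0(t))


def mixture_vitality_direct(model: MixtureModel, t: float) -> float:
    """Independent route: v_U(t) = int_t^inf u f_U(u) du / sf_U(t), evaluated
    in the equivalent mean-residual-life form t + int_t^inf sf_U(u) du /
    sf_U(t) (integration by parts), which an infinite-limit quadrature
    handles even for slowly decaying mixture tails.

    Cross-check for :func:`mixture_vitality`.
    """
    if math.isinf(model.frailty.mean):
        return math.inf
    sf_t = mixture_sf(model, t)
    tail, _ = integrate.quad(
        lambda u: mixture_sf(model, u), t, math.inf, epsabs=1e-11, limit=400
    )
    return t + tail / sf_t


# ---------------------------------------------------------------------------
# posterior frailty densities
# ---------------------------------------------------------------------------

def _normalized_on_grid(raw: np.ndarray, xi_grid: np.ndarray) -> np.ndarray:
    mass = float(np.trapezoid(raw, xi_grid))
    if mass <= 0.0 or not math.isfinite(mass):
        raise DegeneratePosteriorError("posterior numerator is zero on the supplied grid")
    return raw / mass


def posterior_at_death(model: MixtureModel, t: float, xi_grid) -> np.ndarray:
    """Density of Xi given U = t: g(xi | t) proportional to f(t | xi) g(xi),
    trapezoid-normalized on the supplied grid."""
    xi_grid = np.asarray(xi_grid, dtype=float)
    raw = np.array(
        [
            g * _fast_conditional_pdf(model.baseline, xi, t) if (g := model.frailty.pdf(xi)) > 0 else 0.0
            for xi in xi_grid
        ]
    )
    return _normalized_on_grid(raw, xi_grid)


def posterior_survivor(model: MixtureModel, t: float, xi_grid) -> np.ndarray:
    """Density of Xi among survivors of age t: proportional to sf(t | xi) g(xi)."""
    xi_grid = np.asarray(xi_grid, dtype=float)
    raw = np.array(
        [
            g * _fast_conditional_sf(model.baseline, xi, t) if (g := model.frailty.pdf(xi)) > 0 else 0.0
            for xi in xi_grid
        ]
    )
    return _normalized_on_grid(raw, xi_grid)


def survivor_posterior_mean(model: MixtureModel, t: float) -> float:
    """E(Xi | U > t); at least E(Xi) by positive association, inf if E(Xi) is."""
    if math.isinf(model.frailty.mean):
        return math.inf
    num = _frailty_expectation(
        model.frailty, lambda xi: xi * _fast_conditional_sf(model.baseline, xi, t)
    )
    den = _frailty_expectation(
        model.frailty, lambda xi: _fast_conditional_sf(model.baseline, xi, t)
    )
    return num / den


# ---------------------------------------------------------------------------
# stochastic-order diagnostics
# ---------------------------------------------------------------------------

def _nondecreasing(values: np.ndarray, slack: float = ORDER_SLACK) -> bool:
    scale = max(1.0, float(np.nanmax(np.abs(values))))
    return bool(np.all(np.diff(values) >= -slack * scale))


class OrderReport(NamedTuple):
    """Boolean outcomes of the stochastic-order checks on the given grids.

    ``None`` marks a check whose premise does not apply to the model.
    """

    lr_death_vs_survivor: bool          # posterior lr order at each t
    lr_survivor_time_monotone: bool     # survivor posteriors lr-increase in t
    hazard_below_baseline: bool | None  # h_U <= h0 (premise: E(Xi) >= 1)
    st_order: bool | None               # sf0 <= sf_U (premise: E(Xi) >= 1)
    density_ratio_monotone: bool | None # f_U/f0 non-decreasing (premise:
                                        # support in [1,inf) and v0(t)/t
                                        # non-decreasing on the grid)


def check_orders(model: MixtureModel, t_grid, xi_grid) -> OrderReport:
    """Grid-based verification of the posterior and mixture order relations."""
    t_grid = np.asarray(t_grid, dtype=float)
    xi_grid = np.asarray(xi_grid, dtype=float)

    if model.frailty.atom is not None:
        # degenerate growth: U =st (U | Xi = atom); posteriors stay the point
        # mass and every order holds with equality
        xi0 = model.frailty.atom
        hz_eq: bool | None = None
        st_eq: bool | None = None
        if xi0 >= 1.0:
            hz_eq = True
            st_eq = True
            for t in t_grid:
                h0 = conditional_hazard(ConditionalPVIT(model.baseline, 1.0), t)
                hu = mixture_hazard(model, t)
                hz_eq &= hu <= h0 + ORDER_SLACK * max(1.0, h0)
                st_eq &= (
                    _fast_conditional_sf(model.baseline, 1.0, t)
                    <= mixture_sf(model, t) + ORDER_SLACK
                )
        return OrderReport(True, True, hz_eq, st_eq, None)

    # (i) g(xi | U>t) / g(xi | U=t) non-decreasing in xi at each t
    lr_i = True
    for t in t_grid:
        if t <= 0:
            continue
        surv = posterior_survivor(model, t, xi_grid)
        death = posterior_at_death(model, t, xi_grid)
        lr_i &= _nondecreasing(surv / death)

    # (ii) g(xi | U>t2) / g(xi | U>t1) non-decreasing in xi for t1 <= t2
    lr_ii = True
    posts = [posterior_survivor(model, t, xi_grid) for t in t_grid]
    for a, b in zip(posts[:-1], posts[1:]):
        lr_ii &= _nondecreasing(b / a)

    mean_xi = model.frailty.mean
    hz_ok: bool | None = None
    st_ok: bool | None = None
    if mean_xi >= 1.0 or math.isinf(mean_xi):
        hz_ok = True
        st_ok = True
        for t in t_grid:
            base = ConditionalPVIT(model.baseline, 1.0)
            h0 = conditional_hazard(base, t)
            hu = mixture_hazard(model, t)
            hz_ok &= hu <= h0 + ORDER_SLACK * max(1.0, h0)
            sf0 = _fast_conditional_sf(model.baseline, 1.0, t)
            st_ok &= sf0 <= mixture_sf(model, t) + ORDER_SLACK

    dr_ok: bool | None = None
    if model.frailty.support_low >= 1.0:
        ratio_v0 = np.array([float(model.baseline.v0(t)) / t for t in t_grid if t > 0])
        if _nondecreasing(ratio_v0):
            pos_t = t_grid[t_grid > 0]
            r = np.array(
                [
                    mixture_pdf(model, t) / _fast_conditional_pdf(model.baseline, 1.0, t)
                    for t in pos_t
                ]
            )
            dr_ok = _nondecreasing(r)

    return OrderReport(bool(lr_i), bool(lr_ii), hz_ok, st_ok, dr_ok)


def density_ratio(model: MixtureModel, t: float) -> float:
    """f_U(t) / f0(t): mixture density over the baseline (xi = 1) density.

    Its shape tracks the population's selection dynamics; for an exponential
    baseline it dips below one and turns upward near t = 1/rate.
    """
    return mixture_pdf(model, t) / _fast_conditional_pdf(model.baseline, 1.0, t)


# ---------------------------------------------------------------------------
# conditional moments and survival bounds
# ---------------------------------------------------------------------------

def conditional_moments(model: ConditionalPVIT) -> ConditionalMoments:
    """Mean, second moment and variance of T = (U | Xi = xi) by tail integrals.

    mean = int sf dt (equals xi*E(X)); second moment = 2 int t sf dt. Each
    tail is accumulated over doubling segments; failure of the increments to
    vanish before the horizon cap marks the moment infinite.
    """
    sf = lambda t: _fast_conditional_sf(model.baseline, model.xi, t)  # noqa: E731

    def tail_integral(weight: Callable[[float], float]) -> float:
        # doubling segments [H, 2H]; their ratio r is ~2^(1+k-p) for a
        # survival tail t^-p and t^k weight, so r >= 1 flags divergence and
        # r < 1 gives the geometric tail estimate seg*r/(1-r)
        lo, hi = 0.0, 8.0 * model.xi * model.baseline.mean
        total, prev = 0.0, None
        for _ in range(60):
            seg, _ = integrate.quad(lambda t: weight(t) * sf(t), lo, hi, epsabs=1e-13, limit=200)
            total += seg
            if seg < 1e-12 * max(1.0, total):
                return total
            if prev is not None and prev > 0:
                r = seg / prev
                if r >= 0.999:
                    return math.inf
                tail = seg * r / (1.0 - r)
                if tail < 1e-9 * max(1.0, total):
                    return total + tail
            prev = seg
            lo, hi = hi, 2.0 * hi
        return math.inf

    mean = tail_integral(lambda t: 1.0)
    second = tail_integral(lambda t: 2.0 * t)
    var = second - mean**2 if math.isfinite(second) else math.inf
    return ConditionalMoments(mean, second, var)


def sf_lower_bound(model: ConditionalPVIT, t: float) -> float:
    """Moment lower bound on sf(t | xi), valid on the early window t < xi*E(X):

    sf(t | xi) >= (xi*E(X) - t) / (xi*v0(t) - t).
    """
    xi, ex = model.xi, model.baseline.mean
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    if t >= xi * ex:
        raise InvalidParameterError(
            f"lower bound undefined for t >= xi*E(X) = {xi * ex:g} (got t={t:g})"
        )
    denom = xi * float(model.baseline.v0(t)) - t
    if denom <= 0:
        raise ModelInvalidError(f"model invalid at t={t:g}", t=t)
    return (xi * ex - t) / denom


def sf_upper_bound(model: ConditionalPVIT, t: float) -> float:
    """Variance upper bound on sf(t | xi):

    sf(t | xi) <= Var(T) / (Var(T) + xi^2 (v0(t) - E(X))^2).
    """
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    mom = conditional_moments(model)
    if not math.isfinite(mom.variance):
        raise BoundUnavailableError(
            f"Var(T) is infinite for xi={model.xi:g}; the upper bound is unavailable"
        )
    gap = model.xi * (float(model.baseline.v0(t)) - model.baseline.mean)
    return mom.variance / (mom.variance + gap**2)
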