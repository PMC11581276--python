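"""Automatic piecewise-constant majorizer construction and thinning
efficiency.

Two constructions over ``M`` equal-length subintervals:

* endpoint construction — level is the larger of the two endpoint rates,
  plus a Lipschitz cone correction ``K * width / 2`` for functions that
  are K-Lipschitz but not monotone (``K = 0`` suffices for monotone
  rates, where the larger endpoint already bounds the subinterval);
* least-upper-bound construction — level is the numerically located
  supremum of the rate on each subinterval (tighter, costlier).

The thinning efficiency of a majorizer is the expected acceptance
fraction ``int lambda / int lambda*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import DominationError, SpecError
from .intensity import (ConstantIntensity, IntensityModel, StepIntensity,
                        _grid_refine_max, as_interval)

__all__ = [
    "MajorizerConstruction",
    "build_step_majorizer",
    "build_tight_majorizer",
    "thinning_efficiency",
    "estimate_lipschitz",
]


@dataclass(frozen=True)
class MajorizerConstruction:
    """Parameters of the endpoint construction.

    ``M``: number of equal-length subintervals.  ``K``: Lipschitz bound
    on ``|dlambda/dt|`` (rate per time), unused in ``monotone`` mode.
    """

    M: int
    K: float = 0.0
    mode: str = "lipschitz"

    def __post_init__(self) -> None:
        if self.M < 1:
            raise SpecError("M must be >= 1")
        if self.K < 0:
            raise SpecError("K must be >= 0")
        if self.mode not in ("lipschitz", "monotone"):
            raise SpecError("mode must be 'lipschitz' or 'monotone'")


def _as_rate_fn(target):
    return target.rate if isinstance(target, IntensityModel) else target


def build_step_majorizer(rate_fn, interval, construction: MajorizerConstruction,
                         *, check_grid: int = 10_000) -> StepIntensity:
    """Endpoint-max (+ cone padding) step majorizer on equal subintervals.

    Exact for monotone rates; valid for K-Lipschitz rates by the cone
    bound.  Domination is additionally spot-checked on a dense grid and a
    failure suggests increasing ``K`` or ``M``.
    """
    fn = _as_rate_fn(rate_fn)
    iv = as_interval(interval)
    edges = np.linspace(iv.a, iv.b, construction.M + 1)
    width = iv.length / construction.M
    levels = np.maximum(np.asarray(fn(edges[:-1]), dtype=float),
                        np.asarray(fn(edges[1:]), dtype=float))
    if construction.mode == "lipschitz":
        levels = levels + construction.K * width / 2.0
    maj = StepIntensity(edges, levels)
    _spot_check(fn, maj, iv, check_grid,
                "increase K or the number of subintervals M")
    return maj


def build_tight_majorizer(rate_fn, interval, M: int, *,
                          points_per_bin: int = 1000) -> StepIntensity:
    """Least-upper-bound step majorizer: per-subinterval numeric supremum."""
    fn = _as_rate_fn(rate_fn)
    iv = as_interval(interval)
    edges = np.linspace(iv.a, iv.b, M + 1)
    levels = np.array([
        _grid_refine_max(fn, as_interval((lo, hi)), points_per_bin)
        for lo, hi in zip(edges[:-1], edges[1:])])
    return StepIntensity(edges, levels)


def _spot_check(fn, maj: StepIntensity, iv, n_grid, advice) -> None:
    ts = np.linspace(iv.a, iv.b, n_grid + 1)[1:]
    lam = np.asarray(fn(ts), dtype=float)
    star = maj.rate(ts)
    if np.any(lam > star * (1 + 1e-9) + 1e-12):
        t_bad = float(ts[np.argmax(lam > star * (1 + 1e-9) + 1e-12)])
        raise DominationError(
            f"constructed majorizer is below the target near t={t_bad:.6g}; "
            f"{advice}")


def _integral_of(target, iv) -> float:
    if isinstance(target, IntensityModel):
        try:
            return target.cumulative_between(iv.a, iv.b)
        except SpecError:
            target = target.rate
    val, _ = integrate.quad(lambda t: float(np.asarray(target(np.asarray(t)))),
                            iv.a, iv.b, limit=200)
    return val


def thinning_efficiency(target, majorizer, interval=None) -> float:
    """Expected thinning acceptance fraction ``int lambda / int lambda*``."""
    if interval is None:
        if isinstance(target, IntensityModel):
            interval = target.domain
        elif isinstance(majorizer, StepIntensity):
            interval = majorizer.domain
        else:
            raise SpecError("an interval is required")
    iv = as_interval(interval)
    numerator = _integral_of(target, iv)
    if isinstance(majorizer, StepIntensity):
        denominator = majorizer.cumulative_between(
            max(iv.a, majorizer.domain.a), min(iv.b, majorizer.domain.b))
    elif isinstance(majorizer, ConstantIntensity):
        denominator = majorizer.rate_value * iv.length
    elif np.isscalar(majorizer):
        denominator = float(majorizer) * iv.length
    else:
        raise SpecError("majorizer must be a step intensity or a constant")
    ratio = numerator / denominator
    if ratio > 1 + 1e-9:
        raise DominationError(
            f"efficiency {ratio:.6g} > 1: the majorizer does not dominate")
    return ratio


def estimate_lipschitz(rate_fn, interval, n_grid: int = 100_000) -> float:
    """Approximate ``max |dlambda/dt|`` by dense central finite differences.

    A convenience for callers without an analytic derivative; the result
    is approximate and should be padded before use as a cone coefficient.
    """
    fn = _as_rate_fn(rate_fn)
    iv = as_interval(interval)
    ts = np.linspace(iv.a, iv.b, n_grid + 1)
    vals = np.asarray(fn(ts), dtype=float)
    return float(np.max(np.abs(np.diff(vals))) / (iv.length / n_grid))
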