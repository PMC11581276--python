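"""Intensity representations for one-dimensional Poisson point processes.

Every model exposes a non-negative rate ``lambda(t)`` over a half-open
domain ``(a, b]``, its cumulative intensity ``Lambda(t) = int_a^t lambda``
and the inverse ``Lambda^{-1}(z)``.  Closed forms are used wherever they
exist (constant, step, linear, log-linear); otherwise the inverse falls
back to a bracketed bisection on a cached monotone grid, accurate to an
absolute time tolerance of ~1e-10.

Conventions
-----------
* Intervals are half-open ``(a, b]``: sampled event times satisfy
  ``a < t <= b``.
* Zero-rate regions are allowed.  Over a flat stretch of ``Lambda`` the
  inverse returns the *left edge* of the stretch (earliest preimage).
"""

from __future__ import annotations

import importlib
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DomainError, RangeError, SpecError

__all__ = [
    "Interval",
    "IntensityModel",
    "ConstantIntensity",
    "StepIntensity",
    "LinearIntensity",
    "LogLinearIntensity",
    "SinExpIntensity",
    "CallableIntensity",
    "supremum_rate",
    "supremum_abs_derivative",
    "intensity_to_config",
    "intensity_from_config",
]

_BETA_EPS = 1e-12  # below this |beta|, fall back to the constant-rate formulas


@dataclass(frozen=True)
class Interval:
    """The half-open carrier interval ``(a, b]``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        a, b = float(self.a), float(self.b)
        if not (math.isfinite(a) and math.isfinite(b)):
            raise DomainError("interval endpoints must be finite")
        if not a < b:
            raise DomainError(f"interval requires a < b, got ({a}, {b}]")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def length(self) -> float:
        return self.b - self.a

    def contains(self, t, tol: float = 1e-9):
        t = np.asarray(t, dtype=float)
        return (t > self.a - tol) & (t <= self.b + tol)


def as_interval(interval) -> Interval:
    if isinstance(interval, Interval):
        return interval
    a, b = interval
    return Interval(float(a), float(b))


class IntensityModel(ABC):
    """Base class: rate, cumulative intensity, and its inverse on a domain."""

    def __init__(self, domain) -> None:
        self._domain = as_interval(domain)
        self._grid_cache = None
        self._total = None

    @property
    def domain(self) -> Interval:
        return self._domain

    # -- abstract surface ------------------------------------------------
    @abstractmethod
    def rate(self, t):
        """lambda(t), vectorized; >= 0 everywhere on the domain."""

    @abstractmethod
    def _cumulative_from_start(self, t):
        """Lambda(t) measured from the domain start, without validation."""

    # -- cumulative ------------------------------------------------------
    def cumulative(self, t):
        """``Lambda(t) = int_a^t lambda(s) ds`` with ``a`` the domain start."""
        arr = np.asarray(t, dtype=float)
        if np.any(arr < self.domain.a - 1e-9) or np.any(arr > self.domain.b + 1e-9):
            raise DomainError(
                f"time outside domain ({self.domain.a}, {self.domain.b}]")
        out = self._cumulative_from_start(np.clip(arr, self.domain.a, self.domain.b))
        return float(out) if np.ndim(t) == 0 else out

    def cumulative_between(self, s: float, t: float) -> float:
        return self.cumulative(t) - self.cumulative(s)

    @property
    def total(self) -> float:
        """``Lambda(b)`` over the whole domain."""
        if self._total is None:
            self._total = float(self.cumulative(self.domain.b))
        return self._total

    # -- inverse ---------------------------------------------------------
    def inverse_cumulative(self, z):
        """Earliest ``t`` with ``Lambda(t) = z``; ``z`` in ``[0, Lambda(b)]``."""
        arr = np.atleast_1d(np.asarray(z, dtype=float))
        if self.total < 0:
            raise SpecError("cumulative intensity is not non-decreasing")
        tol = 1e-8 * max(1.0, abs(self.total))
        if np.any(arr < -tol) or np.any(arr > self.total + tol):
            raise RangeError(
                f"cumulative value outside [0, {self.total:.6g}]")
        out = self._inverse_impl(np.clip(arr, 0.0, self.total))
        return float(out[0]) if np.ndim(z) == 0 else out

    def _inverse_impl(self, z: np.ndarray) -> np.ndarray:
        return self._inverse_bisect(z)

    # Bracketed bisection on a cached grid.  Robust to flat stretches of
    # Lambda (converges to their left edge) and needs only a vectorized
    # cumulative.  32 halvings of a ~(length/4096) grid cell reach an
    # absolute width ~1e-12 * domain length, beyond the 1e-10 tolerance.
    def _inverse_bisect(self, z: np.ndarray) -> np.ndarray:
        tg, Lg = self._monotone_grid()
        idx = np.searchsorted(Lg, z, side="left")
        idx = np.clip(idx, 1, len(tg) - 1)
        lo = tg[idx - 1].copy()
        hi = tg[idx].copy()
        lo = np.where(z <= Lg[0], tg[0], lo)
        for _ in range(32):
            mid = 0.5 * (lo + hi)
            below = self._cumulative_from_start(mid) < z
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return hi

    def _monotone_grid(self, n: int = 4097):
        if self._grid_cache is None:
            tg = np.linspace(self.domain.a, self.domain.b, n)
            Lg = np.asarray(self._cumulative_from_start(tg), dtype=float)
            scale = max(1.0, abs(Lg[-1]))
            if np.any(np.diff(Lg) < -1e-9 * scale):
                raise SpecError("cumulative intensity is not non-decreasing")
            Lg = np.maximum.accumulate(Lg)
            self._grid_cache = (tg, Lg)
        return self._grid_cache

    # -- misc ------------------------------------------------------------
    def restricted_mass(self, interval) -> float:
        iv = as_interval(interval)
        return self.cumulative_between(iv.a, iv.b)


class ConstantIntensity(IntensityModel):
    """Homogeneous rate ``lambda(t) = c``."""

    kind = "constant"

    def __init__(self, rate: float, domain) -> None:
        super().__init__(domain)
        if rate < 0:
            raise SpecError("rate must be non-negative")
        self.rate_value = float(rate)

    def rate(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate_value)

    def _cumulative_from_start(self, t):
        return self.rate_value * (np.asarray(t, dtype=float) - self.domain.a)

    def _inverse_impl(self, z):
        if self.rate_value == 0.0:
            return np.full_like(z, self.domain.a)
        return self.domain.a + z / self.rate_value


class StepIntensity(IntensityModel):
    """Piecewise-constant rate: ``rates[m]`` on ``(breakpoints[m], breakpoints[m+1]]``.

    Doubles as the representation of piecewise-constant majorizers.  The
    cumulative intensity is continuous piecewise-linear, and its inverse
    is computed exactly by piecewise-linear inversion (no root finding).
    """

    kind = "step"

    def __init__(self, breakpoints, rates) -> None:
        bp = np.asarray(breakpoints, dtype=float)
        rt = np.asarray(rates, dtype=float)
        if bp.ndim != 1 or rt.ndim != 1 or len(rt) != len(bp) - 1:
            raise SpecError("need len(rates) == len(breakpoints) - 1")
        if np.any(np.diff(bp) <= 0):
            raise SpecError("breakpoints must be strictly increasing")
        if np.any(rt < 0):
            raise SpecError("rates must be non-negative")
        super().__init__((bp[0], bp[-1]))
        self.breakpoints = bp
        self.rates = rt
        self._cumknots = np.concatenate(([0.0], np.cumsum(rt * np.diff(bp))))

    @property
    def regular(self) -> bool:
        widths = np.diff(self.breakpoints)
        return bool(np.allclose(widths, widths[0], rtol=1e-9, atol=0.0))

    def _segment_index(self, t):
        idx = np.searchsorted(self.breakpoints, t, side="left") - 1
        return np.clip(idx, 0, len(self.rates) - 1)

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        return self.rates[self._segment_index(t)]

    def _cumulative_from_start(self, t):
        t = np.asarray(t, dtype=float)
        idx = self._segment_index(t)
        return self._cumknots[idx] + self.rates[idx] * (t - self.breakpoints[idx])

    def _inverse_impl(self, z):
        c = self._cumknots
        # first segment whose right knot reaches z -> earliest preimage
        idx = np.clip(np.searchsorted(c[1:], z, side="left"), 0, len(self.rates) - 1)
        r = self.rates[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.breakpoints[idx] + np.where(r > 0, (z - c[idx]) / np.where(r > 0, r, 1.0), 0.0)
        return np.minimum(t, self.breakpoints[idx + 1])

    def integral(self) -> float:
        """Total mass ``sum rates * widths`` (== ``Lambda(b)``)."""
        return float(self._cumknots[-1])


class LinearIntensity(IntensityModel):
    """Clamped linear rate ``lambda(t) = max(0, alpha + beta t)``."""

    kind = "linear"

    def __init__(self, alpha: float, beta: float, domain) -> None:
        super().__init__(domain)
        self.alpha = float(alpha)
        self.beta = float(beta)
        if abs(self.beta) < _BETA_EPS and self.alpha < 0:
            # constant negative line: identically-zero rate
            self.alpha = min(self.alpha, 0.0)

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        return np.maximum(0.0, self.alpha + self.beta * t)

    # start of the positive part within the domain (beta > 0), or its end
    # (beta < 0); cached for the closed forms below
    def _positive_bounds(self):
        a, b = self.domain.a, self.domain.b
        if abs(self.beta) < _BETA_EPS:
            return (a, b) if self.alpha > 0 else (a, a)
        t0 = -self.alpha / self.beta
        if self.beta > 0:
            return (min(max(a, t0), b), b)
        return (a, max(min(b, t0), a))

    def _cumulative_from_start(self, t):
        t = np.asarray(t, dtype=float)
        if abs(self.beta) < _BETA_EPS:
            return max(self.alpha, 0.0) * (t - self.domain.a)
        s0, e0 = self._positive_bounds()
        u = np.clip(t, s0, e0)
        return self.alpha * (u - s0) + 0.5 * self.beta * (u * u - s0 * s0)

    def _inverse_impl(self, z):
        if abs(self.beta) < _BETA_EPS:
            c = max(self.alpha, 0.0)
            if c == 0.0:
                return np.full_like(z, self.domain.a)
            return self.domain.a + z / c
        s0, e0 = self._positive_bounds()
        if e0 <= s0:
            return np.full_like(z, self.domain.a)
        disc = (self.alpha + self.beta * s0) ** 2 + 2.0 * self.beta * z
        t = (-self.alpha + np.sqrt(np.maximum(disc, 0.0))) / self.beta
        t = np.clip(t, s0, e0)
        # earliest preimage of z == 0 is the domain start (flat at zero there)
        return np.where(z <= 0.0, self.domain.a if self.beta > 0 else s0, t)


class LogLinearIntensity(IntensityModel):
    """Log-linear rate ``lambda(t) = exp(alpha + beta t) > 0``."""

    kind = "loglinear"

    def __init__(self, alpha: float, beta: float, domain) -> None:
        super().__init__(domain)
        self.alpha = float(alpha)
        self.beta = float(beta)
        peak = max(self.alpha + self.beta * self.domain.a,
                   self.alpha + self.beta * self.domain.b)
        if peak > 700.0:
            raise SpecError(
                f"exp overflow: alpha + beta*t reaches {peak:.1f} > 700 on the domain")

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(self.alpha + self.beta * t)

    def _cumulative_from_start(self, t):
        t = np.asarray(t, dtype=float)
        a = self.domain.a
        if abs(self.beta) < _BETA_EPS:
            return math.exp(self.alpha) * (t - a)
        ea = math.exp(self.alpha + self.beta * a)
        return (np.exp(self.alpha + self.beta * t) - ea) / self.beta

    def _inverse_impl(self, z):
        a = self.domain.a
        if abs(self.beta) < _BETA_EPS:
            return a + z / math.exp(self.alpha)
        ea = math.exp(self.alpha + self.beta * a)
        return (np.log(self.beta * z + ea) - self.alpha) / self.beta


class SinExpIntensity(IntensityModel):
    """Sinusoidal rate with exponential amplitude:
    ``lambda(t) = exp(r t) (1 + sin(w t))``.

    The cumulative intensity has the closed form

    ``Lambda(t) = [exp(r t)(r sin(w t) - w cos(w t)) + w] / (r^2 + w^2)
                  + (exp(r t) - 1) / r``

    anchored so that ``Lambda(0) = 0``; the domain may start elsewhere, in
    which case ``cumulative`` subtracts the value at the start.  There is
    no analytic inverse; inversion uses the grid-bracketed bisection of
    the base class.
    """

    kind = "sinexp"

    def __init__(self, r: float = 0.2, w: float = 1.0, domain=None) -> None:
        super().__init__(domain if domain is not None else (0.0, 6.0 * math.pi))
        self.r = float(r)
        self.w = float(w)
        if self.w == 0.0:
            raise SpecError("angular frequency w must be nonzero")

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(self.r * t) * (1.0 + np.sin(self.w * t))

    def rate_derivative(self, t):
        t = np.asarray(t, dtype=float)
        r, w = self.r, self.w
        return np.exp(r * t) * (r * (1.0 + np.sin(w * t)) + w * np.cos(w * t))

    def _antiderivative(self, t):
        t = np.asarray(t, dtype=float)
        r, w = self.r, self.w
        if r == 0.0:
            return t - np.cos(w * t) / w
        return ((np.exp(r * t) * (r * np.sin(w * t) - w * np.cos(w * t)) + w)
                / (r * r + w * w) + (np.exp(r * t) - 1.0) / r)

    def _cumulative_from_start(self, t):
        return self._antiderivative(t) - self._antiderivative(self.domain.a)


class CallableIntensity(IntensityModel):
    """Black-box intensity: user-supplied ``lambda(t)`` and, optionally,
    closed-form ``Lambda`` and ``Lambda^{-1}``."""

    kind = "callable"

    def __init__(self, rate_fn=None, domain=None, cumulative_fn=None,
                 inverse_fn=None) -> None:
        if domain is None:
            raise SpecError("a domain interval is required")
        if rate_fn is None and cumulative_fn is None:
            raise SpecError("need at least one of rate_fn, cumulative_fn")
        super().__init__(domain)
        self._rate_fn = _vectorize_if_needed(rate_fn, self.domain)
        self._cumulative_fn = _vectorize_if_needed(cumulative_fn, self.domain)
        self._inverse_fn = _vectorize_if_needed(inverse_fn, self.domain)
        if self._cumulative_fn is not None and self._inverse_fn is not None:
            self._check_inverse_roundtrip()

    def _check_inverse_roundtrip(self, n: int = 17) -> None:
        iv = self.domain
        ts = np.linspace(iv.a, iv.b, n + 1)[1:]
        zs = self._cumulative_fn(ts) - self._cumulative_fn(np.asarray(iv.a))
        back = self._inverse_fn(zs + self._offset_for_inverse())
        if self._rate_fn is not None:
            live = np.asarray(self._rate_fn(ts)) > 1e-12
        else:
            live = np.ones_like(ts, dtype=bool)
        if np.any(np.abs(np.asarray(back) - ts)[live] > 1e-6 * max(1.0, iv.length)):
            raise SpecError("inverse_fn(cumulative_fn(t)) != t on the domain")

    def _offset_for_inverse(self):
        # user inverse is of the raw cumulative, which may not vanish at a
        return float(self._cumulative_fn(np.asarray(self.domain.a)))

    def rate(self, t):
        if self._rate_fn is None:
            raise SpecError("this spec has no rate function")
        return np.maximum(0.0, np.asarray(self._rate_fn(np.asarray(t, dtype=float)),
                                          dtype=float))

    def _cumulative_from_start(self, t):
        if self._cumulative_fn is None:
            raise SpecError("this spec has no cumulative intensity function")
        t = np.asarray(t, dtype=float)
        return (np.asarray(self._cumulative_fn(t), dtype=float)
                - self._offset_for_inverse())

    def _inverse_impl(self, z):
        if self._inverse_fn is not None:
            return np.asarray(self._inverse_fn(z + self._offset_for_inverse()),
                              dtype=float)
        return self._inverse_bisect(z)

    @property
    def has_cumulative(self) -> bool:
        return self._cumulative_fn is not None

    @property
    def has_rate(self) -> bool:
        return self._rate_fn is not None


def _vectorize_if_needed(fn, domain):
    if fn is None:
        return None
    try:
        probe = fn(np.array([domain.a + 0.25 * domain.length,
                             domain.a + 0.75 * domain.length]))
        if np.shape(probe) == (2,):
            return fn
    except Exception:
        pass
    return np.vectorize(fn, otypes=[float])


# ---------------------------------------------------------------------------
# suprema by dense grid scan plus local golden-section refinement
# ---------------------------------------------------------------------------

def _grid_refine_max(f, interval: Interval, n_grid: int) -> float:
    ts = np.linspace(interval.a, interval.b, n_grid + 1)[1:]
    vals = np.asarray(f(ts), dtype=float)
    i = int(np.argmax(vals))
    step = interval.length / n_grid
    lo = max(interval.a, ts[i] - step)
    hi = min(interval.b, ts[i] + step)
    res = optimize.minimize_scalar(lambda t: -float(f(np.asarray(t))),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return max(float(vals[i]), -float(res.fun), float(f(np.asarray(interval.b))))


def supremum_rate(model, interval=None, n_grid: int = 100_000) -> float:
    """``sup lambda(t)`` over ``interval`` (default: the model's domain)."""
    iv = as_interval(interval) if interval is not None else model.domain
    return _grid_refine_max(model.rate, iv, n_grid)


def supremum_abs_derivative(model, interval=None, n_grid: int = 100_000) -> float:
    """``max |dlambda/dt|`` over ``interval`` — the Lipschitz bound.

    Uses the model's analytic ``rate_derivative`` when available and a
    central finite difference otherwise (approximate).
    """
    iv = as_interval(interval) if interval is not None else model.domain
    if hasattr(model, "rate_derivative"):
        return _grid_refine_max(lambda t: np.abs(model.rate_derivative(t)), iv, n_grid)
    h = iv.length * 1e-7

    def fd(t):
        t = np.asarray(t, dtype=float)
        lo = np.clip(t - h, iv.a, iv.b)
        hi = np.clip(t + h, iv.a, iv.b)
        return np.abs(model.rate(hi) - model.rate(lo)) / np.maximum(hi - lo, 1e-300)

    return _grid_refine_max(fd, iv, n_grid)


# ---------------------------------------------------------------------------
# JSON config dialect
# ---------------------------------------------------------------------------

_KIND_ALIASES = {"illustration": "sinexp", "log-linear": "loglinear"}


def intensity_to_config(model: IntensityModel) -> dict:
    """Serialize a model to the JSON config dialect."""
    iv = [model.domain.a, model.domain.b]
    if isinstance(model, ConstantIntensity):
        return {"kind": "constant", "rate": model.rate_value, "domain": iv}
    if isinstance(model, StepIntensity):
        return {"kind": "step", "breakpoints": model.breakpoints.tolist(),
                "rates": model.rates.tolist()}
    if isinstance(model, LinearIntensity):
        return {"kind": "linear", "alpha": model.alpha, "beta": model.beta,
                "domain": iv}
    if isinstance(model, LogLinearIntensity):
        return {"kind": "loglinear", "alpha": model.alpha, "beta": model.beta,
                "domain": iv}
    if isinstance(model, SinExpIntensity):
        return {"kind": "sinexp", "r": model.r, "w": model.w, "domain": iv}
    raise SpecError(f"cannot serialize {type(model).__name__}")


def intensity_from_config(cfg: dict) -> IntensityModel:
    """Build a model from the JSON config dialect.

    Recognized kinds: ``constant``, ``step``, ``linear``, ``loglinear``,
    ``sinexp`` (alias ``illustration``) and ``callable-ref`` (dotted
    ``module:attribute`` references to rate/cumulative/inverse callables).
    """
    if not isinstance(cfg, dict) or "kind" not in cfg:
        raise SpecError("intensity config must be a dict with a 'kind' key")
    kind = _KIND_ALIASES.get(cfg["kind"], cfg["kind"])
    try:
        if kind == "constant":
            return ConstantIntensity(cfg["rate"], cfg["domain"])
        if kind == "step":
            return StepIntensity(cfg["breakpoints"], cfg["rates"])
        if kind == "linear":
            return LinearIntensity(cfg["alpha"], cfg["beta"], cfg["domain"])
        if kind == "loglinear":
            return LogLinearIntensity(cfg["alpha"], cfg["beta"], cfg["domain"])
        if kind == "sinexp":
            return SinExpIntensity(cfg.get("r", 0.2), cfg.get("w", 1.0),
                                   cfg.get("domain"))
        if kind == "callable-ref":
            return CallableIntensity(
                rate_fn=_load_ref(cfg.get("rate_ref")),
                cumulative_fn=_load_ref(cfg.get("cumulative_ref")),
                inverse_fn=_load_ref(cfg.get("inverse_ref")),
                domain=cfg["domain"])
    except KeyError as exc:
        raise SpecError(f"intensity config missing field {exc}") from exc
    raise SpecError(f"unknown intensity kind {cfg['kind']!r}")


def _load_ref(ref):
    if ref is None:
        return None
    module, _, attr = ref.partition(":")
    return getattr(importlib.import_module(module), attr)
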