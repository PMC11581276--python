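"""General sampling algorithms for time-varying intensities.

Three routes are implemented:

* thinning — acceptance/rejection from a dominating (majorizing)
  intensity that has a closed-form sampler;
* inversion — unit-rate sequential sampling on the transformed axis
  ``tau = Lambda(t)`` mapped back through ``Lambda^{-1}``;
* order statistics — a Poisson (or truncated-Poisson) count followed by
  sorted uniforms mapped through ``Lambda^{-1}``.

Plus prior-event sampling (events before a known later event),
superposition attribution, and a ``draw()`` dispatcher that routes an
argument bundle to the right sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constant import (NO_TRUNCATION, sample_exactly_n,
                       sample_orderstat, sample_sequential,
                       sample_truncated_poisson_count, sample_zt)
from .errors import (AttributionError, DispatchError, DominationError,
                     SpecError)
from .intensity import (CallableIntensity, ConstantIntensity, IntensityModel,
                        LinearIntensity, LogLinearIntensity, StepIntensity,
                        as_interval)
from .rng import resolve_rng
from .special import sample_linear, sample_loglinear, sample_step

__all__ = [
    "MajorizerSpec",
    "sample_thinning",
    "sample_inversion",
    "sample_orderstats_general",
    "sample_prior_events",
    "superpose_and_attribute",
    "choose_route",
    "draw",
]

logger = logging.getLogger("ppsim")

_MAX_REDRAWS = 100_000


@dataclass
class MajorizerSpec:
    """A sampleable dominating intensity ``lambda*(t) >= lambda(t)``.

    ``model`` must be one of the closed-form representations (constant,
    linear, log-linear, step).  Domination against a given target is
    validated on a finite grid the first time the pair is used; a false
    pass between grid points is the caller's responsibility.
    """

    model: IntensityModel
    grid_points: int = 10_000
    _checked: set = field(default_factory=set, repr=False)

    @classmethod
    def constant(cls, value: float, interval) -> "MajorizerSpec":
        return cls(ConstantIntensity(value, as_interval(interval)))

    @property
    def form(self) -> str:
        return self.model.kind

    def validate_against(self, rate_fn, interval) -> None:
        iv = as_interval(interval)
        key = (id(rate_fn), iv.a, iv.b)
        if key in self._checked:
            return
        ts = np.linspace(iv.a, iv.b, self.grid_points + 1)[1:]
        lam = np.asarray(rate_fn(ts), dtype=float)
        star = np.asarray(self.model.rate(ts), dtype=float)
        bad = lam > star * (1 + 1e-9) + 1e-12
        if np.any(bad):
            t_bad = float(ts[np.argmax(bad)])
            raise DominationError(
                f"majorizer is below the target at t={t_bad:.6g} "
                f"({float(np.asarray(rate_fn(np.asarray(t_bad)))):.6g} > "
                f"{float(self.model.rate(np.asarray(t_bad))):.6g})")
        self._checked.add(key)

    def sample_proposals(self, interval, rng):
        m = self.model
        if isinstance(m, ConstantIntensity):
            return sample_orderstat(m.rate_value, interval, rng=rng)
        if isinstance(m, StepIntensity):
            return sample_step(m, interval, rng=rng)
        if isinstance(m, LinearIntensity):
            return sample_linear(m, interval, rng=rng)
        if isinstance(m, LogLinearIntensity):
            return sample_loglinear(m, interval, rng=rng)
        raise SpecError(
            f"majorizer form {type(m).__name__} has no closed-form sampler")


def _coerce_majorizer(majorizer, interval) -> MajorizerSpec:
    if isinstance(majorizer, MajorizerSpec):
        return majorizer
    if isinstance(majorizer, IntensityModel):
        return MajorizerSpec(majorizer)
    if np.isscalar(majorizer):
        return MajorizerSpec.constant(float(majorizer), interval)
    raise SpecError("majorizer must be a MajorizerSpec, model, or constant")


def _rate_fn_of(target):
    return target.rate if isinstance(target, IntensityModel) else target


def sample_thinning(target, majorizer, interval=None, truncation=None,
                    rng=None):
    """Thinning: propose from the majorizer, keep each proposal ``Z`` with
    probability ``lambda(Z) / lambda*(Z)``.

    With ``at_least_m >= 1`` the whole propose/accept pass is redrawn
    until at least ``m`` acceptances remain — the correct conditional
    law (acceptance can void every proposal of a non-empty pass, so
    conditioning must wrap the full pass).
    """
    if interval is None:
        interval = target.domain if isinstance(target, IntensityModel) else None
        if interval is None:
            raise SpecError("an interval is required for a bare rate function")
    iv = as_interval(interval)
    truncation = truncation or NO_TRUNCATION
    if truncation.exactly_n is not None:
        raise SpecError("exactly_n conditioning is not supported by thinning")
    rng = resolve_rng(rng)
    rate_fn = _rate_fn_of(target)
    spec = _coerce_majorizer(majorizer, iv)
    spec.validate_against(rate_fn, iv)

    for _ in range(_MAX_REDRAWS):
        proposals = spec.sample_proposals(iv, rng)
        if len(proposals):
            lam = np.asarray(rate_fn(proposals), dtype=float)
            star = np.asarray(spec.model.rate(proposals), dtype=float)
            if np.any(lam > star * (1 + 1e-9) + 1e-12):
                raise DominationError(
                    "target exceeds majorizer at a proposed time")
            accepted = proposals[rng.random(len(proposals)) * star < lam]
        else:
            accepted = proposals
        if len(accepted) >= truncation.at_least_m:
            break
    else:  # pragma: no cover
        raise SpecError("conditioning did not succeed within the redraw cap")
    if truncation.at_most_k is not None:
        accepted = accepted[:truncation.at_most_k]
    return accepted


def _transformed_bounds(model: IntensityModel, iv) -> tuple[float, float]:
    try:
        return float(model.cumulative(iv.a)), float(model.cumulative(iv.b))
    except SpecError as exc:
        raise SpecError(
            "inversion/order-statistics sampling needs a cumulative "
            "intensity") from exc


def sample_inversion(model: IntensityModel, interval=None, truncation=None,
                     rng=None):
    """Time-transformation sampling: unit-rate events on
    ``(Lambda(a), Lambda(b)]`` mapped back through ``Lambda^{-1}``.

    ``at_most_k`` exits after ``k`` unit-rate arrivals, so first-event
    queries never generate the full series.
    """
    iv = as_interval(interval) if interval is not None else model.domain
    truncation = truncation or NO_TRUNCATION
    rng = resolve_rng(rng)
    tau_a, tau_b = _transformed_bounds(model, iv)
    span = tau_b - tau_a
    if truncation.exactly_n is not None:
        arrivals = sample_exactly_n(truncation.exactly_n, (0.0, span), rng) \
            if span > 0 else _require_zero_mass_count(truncation.exactly_n)
    elif truncation.at_least_m >= 1:
        if span <= 0:
            raise SpecError("cannot condition on events in a zero-mass interval")
        arrivals = sample_zt(1.0, (0.0, span), rng=rng) \
            if truncation.at_least_m == 1 else _truncated_arrivals(
                span, truncation.at_least_m, rng)
    else:
        if span <= 0:
            return np.empty(0)
        arrivals = sample_sequential(1.0, (0.0, span),
                                     at_most_k=truncation.at_most_k, rng=rng)
    if truncation.at_most_k is not None:
        arrivals = arrivals[:truncation.at_most_k]
    if not len(arrivals):
        return np.empty(0)
    return np.sort(model.inverse_cumulative(tau_a + arrivals))


def _require_zero_mass_count(n):
    if n:
        raise SpecError("cannot place events in a zero-mass interval")
    return np.empty(0)


def _truncated_arrivals(span, m, rng):
    n = sample_truncated_poisson_count(span, m, rng)
    return np.sort(span * (1.0 - rng.random(n)))


def sample_orderstats_general(model: IntensityModel, interval=None,
                              truncation=None, rng=None):
    """Order-statistics sampling: ``N ~ Poisson(Lambda(b) - Lambda(a))``
    (truncated when conditioning), then sorted uniforms mapped through
    ``Lambda^{-1}``."""
    iv = as_interval(interval) if interval is not None else model.domain
    truncation = truncation or NO_TRUNCATION
    rng = resolve_rng(rng)
    tau_a, tau_b = _transformed_bounds(model, iv)
    span = tau_b - tau_a
    if truncation.exactly_n is not None:
        n = truncation.exactly_n
        if span <= 0 and n:
            raise SpecError("cannot place events in a zero-mass interval")
    elif truncation.at_least_m >= 1:
        if span <= 0:
            raise SpecError("cannot condition on events in a zero-mass interval")
        n = sample_truncated_poisson_count(span, truncation.at_least_m, rng)
    else:
        n = int(rng.poisson(span)) if span > 0 else 0
    if n == 0:
        return np.empty(0)
    zs = tau_a + span * (1.0 - rng.random(n))
    times = np.sort(model.inverse_cumulative(zs))
    if truncation.at_most_k is not None:
        times = times[:truncation.at_most_k]
    return times


def sample_prior_events(model: IntensityModel, anchor: float, i: int,
                        window_start=None, rng=None):
    """The ``i - 1`` events before a known event of order ``i``.

    Runs the clock backwards from ``anchor``: conditional on the event of
    order ``i`` occurring at ``anchor``, the earlier events are order
    statistics with CDF ``(Lambda(t) - Lambda(a)) / (Lambda(anchor) -
    Lambda(a))`` on ``(a, anchor)``.
    """
    if i < 2:
        raise SpecError("i must be >= 2: no prior events to sample")
    a = model.domain.a if window_start is None else float(window_start)
    rng = resolve_rng(rng)
    za = float(model.cumulative(a))
    zc = float(model.cumulative(anchor))
    if not zc > za:
        raise SpecError("anchor must carry positive mass above the window start")
    u = np.sort(rng.random(i - 1))
    times = np.sort(model.inverse_cumulative(za + u * (zc - za)))
    return np.minimum(times, anchor)


def superpose_and_attribute(components, merged_events, rng=None):
    """Label each merged event with the component that generated it.

    Event ``Z`` is assigned to component ``j`` with probability
    ``lambda_j(Z) / sum_j lambda_j(Z)``, independently across events.
    """
    merged_events = np.asarray(merged_events, dtype=float)
    rng = resolve_rng(rng)
    rates = np.stack([np.asarray(_rate_fn_of(c)(merged_events), dtype=float)
                      for c in components], axis=0)
    if np.any(rates < 0):
        raise SpecError("component rates must be non-negative")
    totals = rates.sum(axis=0)
    if np.any(totals <= 0):
        t_bad = float(merged_events[np.argmax(totals <= 0)])
        raise AttributionError(
            f"all component intensities vanish at event time {t_bad:.6g}")
    cdf = np.cumsum(rates / totals, axis=0)
    u = rng.random(len(merged_events))
    labels = (u[None, :] > cdf).sum(axis=0)
    return np.minimum(labels, len(components) - 1)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def choose_route(spec=None, *, rate_fn=None, majorizer=None,
                 cumulative_fn=None, inverse_fn=None) -> str:
    """Deterministic routing rule for :func:`draw`.

    Closed-form representations go to their special-case samplers; a
    cumulative intensity (with or without an explicit inverse) routes to
    inversion; a bare rate with a majorizer routes to thinning.
    """
    if spec is not None and (rate_fn or cumulative_fn or inverse_fn):
        raise DispatchError("pass either a spec object or bare functions, not both")
    if spec is not None:
        if isinstance(spec, StepIntensity):
            return "step"
        if isinstance(spec, LinearIntensity):
            return "linear"
        if isinstance(spec, LogLinearIntensity):
            return "loglinear"
        if isinstance(spec, ConstantIntensity):
            return "constant"
        if isinstance(spec, CallableIntensity) and not spec.has_cumulative:
            if majorizer is None:
                raise DispatchError("a rate-only spec needs a majorizer")
            return "thinning"
        if isinstance(spec, IntensityModel):
            return "inversion"
        raise DispatchError(f"cannot route {type(spec).__name__}")
    if cumulative_fn is not None:
        return "inversion"
    if rate_fn is not None:
        if majorizer is None:
            raise DispatchError("a bare rate function needs a majorizer")
        return "thinning"
    raise DispatchError("empty argument bundle: nothing to sample from")


def draw(spec=None, *, rate_fn=None, majorizer=None, cumulative_fn=None,
         inverse_fn=None, interval=None, truncation=None, rng=None):
    """Sample an event series, dispatching on the supplied arguments."""
    route = choose_route(spec, rate_fn=rate_fn, majorizer=majorizer,
                         cumulative_fn=cumulative_fn, inverse_fn=inverse_fn)
    logger.debug("draw() routed to %s", route)
    if spec is None and route == "inversion":
        iv = as_interval(interval)
        spec = CallableIntensity(rate_fn=rate_fn, domain=iv,
                                 cumulative_fn=cumulative_fn,
                                 inverse_fn=inverse_fn)
    if route == "step":
        return sample_step(spec, interval, truncation, rng)
    if route == "linear":
        return sample_linear(spec, interval or spec.domain, truncation, rng)
    if route == "loglinear":
        return sample_loglinear(spec, interval or spec.domain, truncation, rng)
    if route == "constant":
        return _constant_route(spec, interval, truncation, rng)
    if route == "thinning":
        target = spec if spec is not None else rate_fn
        return sample_thinning(target, majorizer, interval, truncation, rng)
    return sample_inversion(spec, interval, truncation, rng)


def _constant_route(spec, interval, truncation, rng):
    iv = as_interval(interval) if interval is not None else spec.domain
    truncation = truncation or NO_TRUNCATION
    if truncation.exactly_n is not None:
        return sample_exactly_n(truncation.exactly_n, iv, rng)
    if truncation.at_least_m >= 1:
        if truncation.at_least_m == 1:
            return sample_zt(spec.rate_value, iv, truncation.at_most_k, rng)
        return sample_orderstats_general(spec, iv, truncation, rng)
    return sample_orderstat(spec.rate_value, iv, truncation.at_most_k, rng)
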