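"""Constant-rate (homogeneous) Poisson cores.

These are the primitives the general samplers are built on: sequential
sampling from exponential gaps, order-statistics sampling from a Poisson
count plus sorted uniforms, exactly-n and next-n variants, and sampling
conditional on at least ``m`` events via the truncated Poisson count law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SpecError
from .intensity import as_interval
from .rng import resolve_rng

__all__ = [
    "TruncationSpec",
    "sample_sequential",
    "sample_orderstat",
    "sample_exactly_n",
    "sample_next_n",
    "sample_truncated_poisson_count",
    "sample_zt",
]


@dataclass(frozen=True)
class TruncationSpec:
    """Conditioning rules for a draw.

    ``at_least_m``: condition on >= m events in the interval.
    ``at_most_k``: return only the k earliest events.
    ``exactly_n``: condition on exactly n events.
    """

    at_least_m: int = 0
    at_most_k: int | None = None
    exactly_n: int | None = None

    def __post_init__(self) -> None:
        if self.at_least_m < 0:
            raise SpecError("at_least_m must be >= 0")
        if self.exactly_n is not None and self.at_least_m > 0:
            raise SpecError("exactly_n is mutually exclusive with at_least_m > 0")
        if self.at_most_k is not None and self.at_most_k < 1:
            raise SpecError("at_most_k must be >= 1 when present")
        if self.exactly_n is not None and self.exactly_n < 0:
            raise SpecError("exactly_n must be >= 0")


NO_TRUNCATION = TruncationSpec()


def _uniform_times(interval, n, rng):
    # u in [0,1) mapped through 1-u so times land in (a, b]
    iv = interval
    return iv.a + iv.length * (1.0 - rng.random(n))


def sample_sequential(rate, interval, at_most_k=None, rng=None):
    """Events in ``(a, b]`` from exponential inter-arrival gaps.

    Vectorized in blocks; distributionally identical to the one-gap-at-a-
    time loop because exponential gaps are i.i.d.
    """
    if rate < 0:
        raise SpecError("rate must be non-negative")
    iv = as_interval(interval)
    rng = resolve_rng(rng)
    if rate == 0.0:
        return np.empty(0)
    length = iv.length
    mean_n = rate * length
    block = max(16, int(mean_n + 6.0 * np.sqrt(mean_n) + 10))
    gaps = rng.exponential(1.0 / rate, block)
    arrivals = np.cumsum(gaps)
    while arrivals[-1] < length and (at_most_k is None or len(arrivals) < at_most_k):
        more = rng.exponential(1.0 / rate, block)
        arrivals = np.concatenate([arrivals, arrivals[-1] + np.cumsum(more)])
    times = iv.a + arrivals[arrivals < length]
    if at_most_k is not None:
        times = times[:at_most_k]
    return times


def sample_orderstat(rate, interval, at_most_k=None, rng=None):
    """Events in ``(a, b]`` via a Poisson count and sorted uniforms."""
    if rate < 0:
        raise SpecError("rate must be non-negative")
    iv = as_interval(interval)
    rng = resolve_rng(rng)
    if rate == 0.0:
        return np.empty(0)
    n = int(rng.poisson(rate * iv.length))
    times = np.sort(_uniform_times(iv, n, rng))
    if at_most_k is not None:
        times = times[:at_most_k]
    return times


def sample_exactly_n(n, interval, rng=None):
    """Exactly ``n`` sorted uniform event times on ``(a, b]``."""
    if n < 0:
        raise SpecError("n must be >= 0")
    iv = as_interval(interval)
    rng = resolve_rng(rng)
    return np.sort(_uniform_times(iv, int(n), rng))


def sample_next_n(n, start, rate, rng=None):
    """The next ``n`` events after ``start`` on an unbounded horizon."""
    if rate <= 0:
        raise SpecError("rate must be positive for an unbounded horizon")
    if n < 1:
        raise SpecError("n must be >= 1")
    rng = resolve_rng(rng)
    return float(start) + np.cumsum(rng.exponential(1.0 / rate, int(n)))


def sample_truncated_poisson_count(mean, m=1, rng=None, size=None):
    """Counts from the ``(m-1)``-truncated Poisson law: ``N >= m``.

    Inverse-CDF on the renormalized tail; when the tail mass underflows,
    walks the tail pmf with a stable log-space recurrence instead of
    rejection (which would stall).
    """
    if mean <= 0:
        raise SpecError("mean must be positive")
    if m < 1:
        raise SpecError("m must be >= 1")
    rng = resolve_rng(rng)
    if size is None and mean < 500.0 and m < 1000:
        return _truncated_scalar_walk(mean, m, rng)
    u = np.atleast_1d(rng.random(size))
    tail = float(stats.poisson.sf(m - 1, mean))
    if tail > 1e-12:
        head = 1.0 - tail
        n = stats.poisson.ppf(head + u * tail, mean).astype(np.int64)
        n = np.maximum(n, m)
    else:
        n = _truncated_tail_walk(mean, m, u)
    if size is None:
        return int(n[0])
    return n


def _truncated_scalar_walk(mean, m, rng):
    # pure-float pmf recurrence; much faster than scipy scalar calls
    pk = float(np.exp(-mean))  # pmf(0)
    head = 0.0
    for k in range(m):
        head += pk
        pk *= mean / (k + 1)
    # head == cdf(m-1), pk == pmf(m)
    tail = 1.0 - head
    if tail < 1e-12:
        return int(_truncated_tail_walk(mean, m, np.atleast_1d(rng.random()))[0])
    target = head + float(rng.random()) * tail
    acc = head + pk
    k = m
    cap = int(m + mean + 20.0 * np.sqrt(mean) + 100)
    while acc < target and k < cap:
        k += 1
        pk *= mean / k
        acc += pk
    return k


def _truncated_tail_walk(mean, m, u):
    # pmf(n+1)/pmf(n) = mean/(n+1); normalize by the (log) tail mass
    log_tail = float(stats.poisson.logsf(m - 1, mean))
    out = np.empty(len(u), dtype=np.int64)
    for i, ui in enumerate(u):
        n = m
        p = float(np.exp(stats.poisson.logpmf(m, mean) - log_tail))
        acc = p
        while acc < ui and n < m + 10_000:
            n += 1
            p *= mean / n
            acc += p
        out[i] = n
    return out


def sample_zt(rate, interval, at_most_k=None, rng=None):
    """Events in ``(a, b]`` conditional on at least one event occurring."""
    if rate <= 0:
        raise SpecError("rate must be positive to condition on >= 1 event")
    iv = as_interval(interval)
    rng = resolve_rng(rng)
    n = sample_truncated_poisson_count(rate * iv.length, 1, rng)
    times = np.sort(_uniform_times(iv, n, rng))
    if at_most_k is not None:
        times = times[:at_most_k]
    return times
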