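"""Closed-form samplers: piecewise-constant, linear, and log-linear
intensities, with zero-/m-truncated variants and vectorized batch
versions over regular grids.

All scalar samplers are inversion/order-statistics samplers routed
through the exact closed-form cumulative intensity and its inverse — no
root finding and no approximation of the target law.
"""

from __future__ import annotations

import numpy as np

from .constant import (NO_TRUNCATION, TruncationSpec,
                       sample_truncated_poisson_count)
from .errors import DominationError, SpecError
from .intensity import (IntensityModel, LinearIntensity,
                        LogLinearIntensity, StepIntensity, as_interval)
from .rng import resolve_rng

__all__ = [
    "sample_step",
    "sample_linear",
    "sample_loglinear",
    "sample_step_matrix",
    "sample_intensity_matrix",
    "event_matrix_to_csv",
    "event_matrix_to_ndjson",
]


def _draw_count(mass: float, truncation: TruncationSpec, rng) -> int:
    if truncation.exactly_n is not None:
        return truncation.exactly_n
    if truncation.at_least_m >= 1:
        if mass <= 0:
            raise SpecError(
                "cannot condition on events in an interval with zero mass")
        return sample_truncated_poisson_count(mass, truncation.at_least_m, rng)
    return int(rng.poisson(mass)) if mass > 0 else 0


def _orderstat_through_inverse(model: IntensityModel, interval, truncation, rng):
    """Count-first sampling mapped through the model's closed-form inverse."""
    iv = as_interval(interval) if interval is not None else model.domain
    truncation = truncation or NO_TRUNCATION
    rng = resolve_rng(rng)
    za = model.cumulative(iv.a)
    zb = model.cumulative(iv.b)
    n = _draw_count(zb - za, truncation, rng)
    zs = za + (zb - za) * (1.0 - rng.random(n))
    times = np.sort(model.inverse_cumulative(np.atleast_1d(zs))) if n else np.empty(0)
    if truncation.at_most_k is not None:
        times = times[:truncation.at_most_k]
    return times


def sample_step(spec, interval=None, truncation=None, rng=None):
    """Events from a piecewise-constant intensity (exact inversion).

    ``spec`` is a :class:`StepIntensity` or a ``(breakpoints, rates)``
    pair.  ``interval`` defaults to the spec's full span and must lie
    within it.
    """
    if not isinstance(spec, StepIntensity):
        spec = StepIntensity(*spec)
    return _orderstat_through_inverse(spec, interval, truncation, rng)


def sample_linear(params, interval=None, truncation=None, rng=None):
    """Events from ``lambda(t) = max(0, alpha + beta t)`` on ``interval``."""
    if isinstance(params, LinearIntensity):
        model = params if interval is None else LinearIntensity(
            params.alpha, params.beta, interval)
    else:
        if interval is None:
            raise SpecError("an interval is required with bare coefficients")
        alpha, beta = params
        model = LinearIntensity(alpha, beta, interval)
    return _orderstat_through_inverse(model, model.domain, truncation, rng)


def sample_loglinear(params, interval=None, truncation=None, rng=None):
    """Events from ``lambda(t) = exp(alpha + beta t)`` on ``interval``."""
    if isinstance(params, LogLinearIntensity):
        model = params if interval is None else LogLinearIntensity(
            params.alpha, params.beta, interval)
    else:
        if interval is None:
            raise SpecError("an interval is required with bare coefficients")
        alpha, beta = params
        model = LogLinearIntensity(alpha, beta, interval)
    return _orderstat_through_inverse(model, model.domain, truncation, rng)


# ---------------------------------------------------------------------------
# batch (vectorized) sampling over a shared regular grid
# ---------------------------------------------------------------------------

def sample_step_matrix(rate_matrix, interval, truncation=None, rng=None):
    """One independent step-intensity draw per row of ``rate_matrix``.

    ``rate_matrix`` has shape ``(n_rows, M)``: row ``i`` holds the rates
    on ``M`` equal-length subintervals of ``interval``.  Returns a float
    matrix with one draw per row, event times sorted and right-padded
    with NaN; the number of columns is the largest event count (possibly
    zero).  Memory scales with the widest row; ``at_most_k`` caps it.
    """
    rates = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    if np.any(rates < 0):
        raise SpecError("rates must be non-negative")
    iv = as_interval(interval)
    truncation = truncation or NO_TRUNCATION
    rng = resolve_rng(rng)
    n_rows, m = rates.shape
    width = iv.length / m
    edges = iv.a + width * np.arange(m + 1)
    cumknots = np.concatenate(
        [np.zeros((n_rows, 1)), np.cumsum(rates * width, axis=1)], axis=1)
    masses = cumknots[:, -1]

    counts = _draw_counts_batch(masses, truncation, rng, n_rows)
    ncol = int(counts.max()) if n_rows else 0
    if truncation.at_most_k is not None:
        ncol = min(ncol, truncation.at_most_k)
    out = np.full((n_rows, max(ncol, 0)), np.nan)
    for i in range(n_rows):
        n = int(counts[i])
        if n == 0:
            continue
        z = masses[i] * (1.0 - rng.random(n))
        idx = np.clip(np.searchsorted(cumknots[i, 1:], z, side="left"), 0, m - 1)
        r = rates[i, idx]
        t = edges[idx] + np.where(r > 0, (z - cumknots[i, idx]) / np.where(r > 0, r, 1.0), 0.0)
        t = np.sort(np.minimum(t, edges[idx + 1]))
        keep = min(n, ncol) if truncation.at_most_k is not None else n
        out[i, :keep] = t[:keep]
    return out


def _draw_counts_batch(masses, truncation, rng, n_rows):
    if truncation.exactly_n is not None:
        return np.full(n_rows, truncation.exactly_n, dtype=np.int64)
    if truncation.at_least_m >= 1:
        if np.any(masses <= 0):
            bad = int(np.argmax(masses <= 0))
            raise SpecError(
                f"row {bad} has zero mass; cannot condition on >= "
                f"{truncation.at_least_m} events")
        return np.array([
            sample_truncated_poisson_count(float(mu), truncation.at_least_m, rng)
            for mu in masses], dtype=np.int64)
    return rng.poisson(np.maximum(masses, 0.0)).astype(np.int64)


def sample_intensity_matrix(rate_fn, majorizer_matrix, interval,
                            truncation=None, rng=None, *, dominance_grid=256,
                            max_redraws=10_000):
    """Batch thinning: per-row proposals from a regular step majorizer,
    rowwise acceptance with probability ``lambda(t, i) / lambda*_i(t)``.

    ``rate_fn(t, row_indices)`` evaluates the target intensity at times
    ``t`` for the given row indices, letting rows carry their own
    covariates; a single-argument ``rate_fn(t)`` is also accepted.
    """
    maj = np.atleast_2d(np.asarray(majorizer_matrix, dtype=float))
    iv = as_interval(interval)
    truncation = truncation or NO_TRUNCATION
    rng = resolve_rng(rng)
    n_rows, m = maj.shape
    width = iv.length / m
    edges = iv.a + width * np.arange(m + 1)
    fn = _rowwise_rate_fn(rate_fn)

    _check_rowwise_domination(fn, maj, edges, dominance_grid)

    base_trunc = TruncationSpec(at_most_k=None)
    accepted = [np.empty(0) for _ in range(n_rows)]
    pending = np.arange(n_rows)
    for _ in range(max_redraws):
        proposals = sample_step_matrix(maj[pending], iv, base_trunc, rng)
        still = []
        for j, row in enumerate(pending):
            t = proposals[j]
            t = t[~np.isnan(t)]
            if len(t):
                lam = np.asarray(fn(t, np.full(len(t), row)), dtype=float)
                star = maj[row, np.clip(((t - iv.a) / width).astype(int), 0, m - 1)]
                if np.any(lam > star * (1 + 1e-9)):
                    raise DominationError(
                        f"target exceeds majorizer at runtime in row {row}")
                keep = rng.random(len(t)) * star < lam
                t = t[keep]
            if truncation.at_least_m >= 1 and len(t) < truncation.at_least_m:
                still.append(row)
            else:
                accepted[row] = t
        if not still:
            break
        pending = np.asarray(still)
    else:  # pragma: no cover
        raise SpecError("conditioning did not succeed within max_redraws")

    k = truncation.at_most_k
    if k is not None:
        accepted = [t[:k] for t in accepted]
    ncol = max((len(t) for t in accepted), default=0)
    out = np.full((n_rows, ncol), np.nan)
    for i, t in enumerate(accepted):
        out[i, :len(t)] = t
    return out


def _rowwise_rate_fn(rate_fn):
    def fn(t, rows):
        try:
            return rate_fn(t, rows)
        except TypeError:
            return rate_fn(t)
    return fn


def _check_rowwise_domination(fn, maj, edges, n_grid):
    m = maj.shape[1]
    ts = np.linspace(edges[0], edges[-1], n_grid + 1)[1:]
    seg = np.clip(np.searchsorted(edges, ts, side="left") - 1, 0, m - 1)
    for i in range(maj.shape[0]):
        lam = np.asarray(fn(ts, np.full(len(ts), i)), dtype=float)
        if np.any(lam > maj[i, seg] * (1 + 1e-9)):
            raise DominationError(f"majorizer fails to dominate target in row {i}")


# ---------------------------------------------------------------------------
# event-matrix serialization: NaN padding becomes an empty field
# ---------------------------------------------------------------------------

def event_matrix_to_csv(matrix, path) -> None:
    """Write one draw per line; padded cells serialize as empty fields."""
    matrix = np.atleast_2d(matrix)
    with open(path, "w") as fh:
        for row in matrix:
            fields = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(",".join(fields) + "\n")


def event_matrix_to_ndjson(matrix, path) -> None:
    """Write one JSON time-list per line, padding dropped."""
    import json

    matrix = np.atleast_2d(matrix)
    with open(path, "w") as fh:
        for row in matrix:
            fh.write(json.dumps([float(v) for v in row if not np.isnan(v)]) + "\n")
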