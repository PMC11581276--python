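"""Validation harness: count- and time-distribution metrics.

Compares empirical event-count and event-time distributions from
repeated simulation runs against the theoretical Poisson law implied by
the target's cumulative intensity:

* bias in mean and variance of counts (relative biases reported per
  1000, i.e. multiplied by 10^3);
* equal-tailed empirical count quantile intervals at 95/90/75/50%;
* a chi-square goodness-of-fit statistic over count bins
  ``[0, L), [L, L+1), ..., [U, inf)`` with ``L``/``U`` the 0.001/0.999
  Poisson quantiles, referred to a chi-square law with ``U - L + 1``
  degrees of freedom; both the left-tail and the conventional upper-tail
  p-value are reported;
* the Wasserstein-1 distance between count CDFs, with a
  parametric-bootstrap p-value (counts resampled from the theoretical
  Poisson law — labeled as such, not an asymptotic p-value);
* a 70-bin chi-square test and a Wasserstein-1 distance for pooled event
  times against ``F(t) = (Lambda(t) - Lambda(a)) / (Lambda(b) - Lambda(a))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import SpecError
from .intensity import IntensityModel, SinExpIntensity, as_interval, \
    supremum_abs_derivative, supremum_rate
from .majorizers import MajorizerConstruction, build_step_majorizer, \
    build_tight_majorizer
from .rng import resolve_rng
from .samplers import MajorizerSpec, sample_inversion, \
    sample_orderstats_general, sample_thinning

__all__ = [
    "CountMetrics",
    "TimeGof",
    "count_metrics",
    "wasserstein1_counts",
    "count_w1",
    "analytic_poisson_ci",
    "event_time_gof",
    "illustration_model",
    "illustration_samplers",
    "negative_control_sampler",
    "run_illustration_study",
    "format_study_report",
]

CI_LEVELS = (95, 90, 75, 50)


@dataclass
class CountMetrics:
    """Summary statistics for per-run event counts against Poisson(N)."""

    j: int
    theoretical_mean: float
    sample_mean: float
    bias_mean: float
    rel_bias_mean_per_1000: float
    sample_var: float
    bias_var: float
    rel_bias_var_per_1000: float
    ci: dict
    gof_stat: float
    gof_df: int
    gof_p_left: float
    gof_p_upper: float
    w1: float
    w1_p_bootstrap: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "j", "theoretical_mean", "sample_mean", "bias_mean",
            "rel_bias_mean_per_1000", "sample_var", "bias_var",
            "rel_bias_var_per_1000", "gof_stat", "gof_df", "gof_p_left",
            "gof_p_upper", "w1", "w1_p_bootstrap")}
        d["ci"] = {str(k): list(v) for k, v in self.ci.items()}
        return d


@dataclass
class TimeGof:
    """70-bin chi-square and W1 summary for pooled event times."""

    n_events: int
    n_bins: int
    gof_stat: float
    gof_df: int
    gof_p_left: float
    gof_p_upper: float
    w1: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_events", "n_bins", "gof_stat", "gof_df", "gof_p_left",
            "gof_p_upper", "w1")}


def _count_bins(mean: float):
    """Bin edges [0, L), [L, L+1), ..., [U, inf) and their Poisson masses."""
    L = int(stats.poisson.ppf(0.001, mean))
    U = int(stats.poisson.ppf(0.999, mean))
    probs = np.concatenate((
        [stats.poisson.cdf(L - 1, mean)],
        stats.poisson.pmf(np.arange(L, U), mean),
        [stats.poisson.sf(U - 1, mean)]))
    return L, U, probs


def _bin_counts(counts: np.ndarray, L: int, U: int) -> np.ndarray:
    clipped = np.clip(counts, L - 1, U)
    return np.bincount(clipped - (L - 1), minlength=U - L + 2).astype(float)


def count_w1(counts, mean: float) -> float:
    """W1 between the empirical count CDF and Poisson(mean), as the sum of
    absolute CDF differences over the integers."""
    counts = np.sort(np.asarray(counts))
    kmax = int(max(counts.max(initial=0), stats.poisson.isf(1e-13, mean))) + 1
    ks = np.arange(kmax + 1)
    f_emp = np.searchsorted(counts, ks, side="right") / len(counts)
    f_theo = stats.poisson.cdf(ks, mean)
    return float(np.abs(f_emp - f_theo).sum())


def wasserstein1_counts(empirical_cdf, theoretical_cdf) -> float:
    """W1 between two count CDFs tabulated on a common integer support."""
    empirical_cdf = np.asarray(empirical_cdf, dtype=float)
    theoretical_cdf = np.asarray(theoretical_cdf, dtype=float)
    if empirical_cdf.shape != theoretical_cdf.shape:
        raise SpecError("CDFs must share a support grid")
    return float(np.abs(empirical_cdf - theoretical_cdf).sum())


def analytic_poisson_ci(mean: float, levels=CI_LEVELS) -> dict:
    """Equal-tailed quantile intervals of the Poisson(mean) law: the
    smallest integers whose CDF reaches each tail probability."""
    out = {}
    for level in levels:
        alpha = (100 - level) / 200.0
        out[level] = (int(stats.poisson.ppf(alpha, mean)),
                      int(stats.poisson.ppf(1 - alpha, mean)))
    return out


def count_metrics(observed_counts, theoretical_mean: float, *,
                  bootstrap: int | None = 999, rng=None) -> CountMetrics:
    """All count-distribution metrics for per-run totals ``observed_counts``
    against Poisson(``theoretical_mean``)."""
    counts = np.asarray(observed_counts, dtype=np.int64)
    if counts.size < 2:
        raise SpecError("need at least 2 runs for count metrics")
    j = counts.size
    n = float(theoretical_mean)
    mean = counts.mean()
    var = counts.var(ddof=0)
    bias_mu = mean - n
    bias_v = var - n  # theoretical variance equals the mean

    ci = {}
    for level in CI_LEVELS:
        alpha = (100 - level) / 200.0
        ci[level] = (int(np.quantile(counts, alpha, method="inverted_cdf")),
                     int(np.quantile(counts, 1 - alpha, method="inverted_cdf")))

    L, U, probs = _count_bins(n)
    observed = _bin_counts(counts, L, U)
    expected = j * probs
    gof = float(((observed - expected) ** 2 / expected).sum())
    df = U - L + 1
    w1 = count_w1(counts, n)

    w1_p = None
    if bootstrap:
        gen = resolve_rng(rng)
        repl = np.array([count_w1(gen.poisson(n, j), n) for _ in range(bootstrap)])
        w1_p = float((1 + (repl >= w1).sum()) / (bootstrap + 1))

    return CountMetrics(
        j=j, theoretical_mean=n, sample_mean=float(mean),
        bias_mean=float(bias_mu), rel_bias_mean_per_1000=float(1e3 * bias_mu / n),
        sample_var=float(var), bias_var=float(bias_v),
        rel_bias_var_per_1000=float(1e3 * bias_v / n),
        ci=ci, gof_stat=gof, gof_df=df,
        gof_p_left=float(stats.chi2.cdf(gof, df)),
        gof_p_upper=float(stats.chi2.sf(gof, df)),
        w1=w1, w1_p_bootstrap=w1_p)


def event_time_gof(pooled_times, model: IntensityModel, interval=None,
                   n_bins: int = 70, w1_grid: int = 2001) -> TimeGof:
    """Chi-square over equal-width time bins plus the W1 distance between
    the empirical and theoretical time CDFs (trapezoid integration)."""
    times = np.sort(np.asarray(pooled_times, dtype=float))
    if times.size == 0:
        raise SpecError("no event times supplied")
    iv = as_interval(interval) if interval is not None else model.domain
    mass = model.cumulative_between(iv.a, iv.b)
    edges = np.linspace(iv.a, iv.b, n_bins + 1)
    cdf_edges = (np.asarray(model.cumulative(edges)) - model.cumulative(iv.a)) / mass
    expected = times.size * np.diff(cdf_edges)
    observed, _ = np.histogram(times, bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    gof = float(terms[expected > 0].sum())
    df = n_bins - 1

    grid = np.linspace(iv.a, iv.b, w1_grid)
    f_emp = np.searchsorted(times, grid, side="right") / times.size
    f_theo = (np.asarray(model.cumulative(grid)) - model.cumulative(iv.a)) / mass
    w1 = float(np.trapezoid(np.abs(f_emp - f_theo), grid))

    return TimeGof(n_events=int(times.size), n_bins=n_bins, gof_stat=gof,
                   gof_df=df, gof_p_left=float(stats.chi2.cdf(gof, df)),
                   gof_p_upper=float(stats.chi2.sf(gof, df)), w1=w1)


# ---------------------------------------------------------------------------
# the built-in numerical study
# ---------------------------------------------------------------------------

def illustration_model() -> SinExpIntensity:
    """The study's target: ``exp(0.2 t)(1 + sin t)`` on ``(0, 6 pi]``."""
    return SinExpIntensity(r=0.2, w=1.0)


def illustration_samplers(model=None, M: int = 20):
    """The five samplers exercised by the numerical study.

    Three thinning variants (constant majorizer at sup lambda; automatic
    endpoint+cone step majorizer; least-upper-bound step majorizer), the
    inversion sampler, and the order-statistics sampler.  Returns a dict
    of ``name -> callable(rng) -> event times``.
    """
    model = model or illustration_model()
    iv = model.domain
    lam_max = supremum_rate(model)
    k_lip = supremum_abs_derivative(model)
    maj_const = MajorizerSpec.constant(lam_max, iv)
    maj_cone = MajorizerSpec(build_step_majorizer(
        model.rate, iv, MajorizerConstruction(M=M, K=k_lip)))
    maj_lub = MajorizerSpec(build_tight_majorizer(model.rate, iv, M))
    return {
        "thinning_const": lambda rng: sample_thinning(model, maj_const, iv, rng=rng),
        "thinning_cone_step": lambda rng: sample_thinning(model, maj_cone, iv, rng=rng),
        "thinning_lub_step": lambda rng: sample_thinning(model, maj_lub, iv, rng=rng),
        "inversion": lambda rng: sample_inversion(model, iv, rng=rng),
        "order_statistics": lambda rng: sample_orderstats_general(model, iv, rng=rng),
    }


def negative_control_sampler(model=None):
    """A deliberately miscalibrated thinning sampler (acceptance halved);
    the study gates must flag it."""
    model = model or illustration_model()
    iv = model.domain
    lam_max = supremum_rate(model)

    def sampler(rng):
        rng = resolve_rng(rng)
        from .constant import sample_orderstat
        proposals = sample_orderstat(lam_max, iv, rng=rng)
        if not len(proposals):
            return proposals
        lam = model.rate(proposals)
        keep = rng.random(len(proposals)) * (2.0 * lam_max) < lam
        return proposals[keep]

    return sampler


def run_illustration_study(samplers=None, J: int = 100, *, time_draws=None,
                           rng=None, bootstrap: int | None = 199,
                           model=None):
    """Run every sampler ``max(J, time_draws)`` times; compute count
    metrics over the first ``J`` runs and pooled-time GoF over
    ``time_draws`` runs.  Returns a JSON-ready report with pass/fail
    gates: upper-tail count GoF p > 0.01 and ``|B_mu| < 3 sqrt(N / J)``.
    """
    if J < 10:
        raise SpecError("J too small for variance metrics (need J >= 10)")
    model = model or illustration_model()
    samplers = samplers or illustration_samplers(model)
    time_draws = time_draws or J
    total_runs = max(J, time_draws)
    gen = resolve_rng(rng)
    n_theory = model.total

    report = {"J": J, "time_draws": time_draws,
              "theoretical_mean": n_theory,
              "analytic_ci": {str(k): list(v) for k, v in
                              analytic_poisson_ci(n_theory).items()},
              "samplers": {}, "gates": [], "passed": True}
    for name, fn in samplers.items():
        counts = np.empty(total_runs, dtype=np.int64)
        pooled = []
        for rep in range(total_runs):
            times = fn(gen)
            counts[rep] = len(times)
            if rep < time_draws:
                pooled.append(times)
        cm = count_metrics(counts[:J], n_theory, bootstrap=bootstrap, rng=gen)
        pooled_times = np.concatenate(pooled) if pooled else np.empty(0)
        tg = event_time_gof(pooled_times, model)
        gate_gof = cm.gof_p_upper > 0.01
        gate_bias = abs(cm.bias_mean) < 3.0 * np.sqrt(n_theory / J)
        gate_time = tg.gof_p_upper > 0.01
        for label, ok in (("count_gof", gate_gof), ("mean_bias", gate_bias),
                          ("time_gof", gate_time)):
            if not ok:
                report["gates"].append(f"{name}:{label}")
                report["passed"] = False
        report["samplers"][name] = {"counts": cm.to_dict(),
                                    "time_gof": tg.to_dict()}
    return report


_ROW_LABELS = [
    ("sample_mean", "Sample mean"),
    ("bias_mean", "Bias in mean"),
    ("rel_bias_mean_per_1000", "Relative bias in mean (per 1000)"),
    ("sample_var", "Sample variance"),
    ("bias_var", "Bias in variance"),
    ("rel_bias_var_per_1000", "Relative bias in variance (per 1000)"),
]


def format_study_report(report: dict) -> str:
    """Plain-text rendering of a study report (one column per sampler)."""
    names = list(report["samplers"])
    width = max(18, max((len(n) for n in names), default=18) + 2)
    lines = [f"Theoretical mean counts: {report['theoretical_mean']:.3f} "
             f"(J = {report['J']}, time draws = {report['time_draws']})"]
    header = " " * 38 + "".join(f"{n:>{width}}" for n in names)
    lines.append(header)
    for key, label in _ROW_LABELS:
        vals = [report["samplers"][n]["counts"][key] for n in names]
        lines.append(f"{label:<38}" + "".join(f"{v:>{width}.3f}" for v in vals))
    for key, label in (("gof_stat", "Count GoF chi2"),
                       ("gof_p_upper", "Count GoF p (upper tail)"),
                       ("gof_p_left", "Count GoF p (left tail)"),
                       ("w1", "Count W1"),
                       ("w1_p_bootstrap", "Count W1 p (bootstrap)")):
        vals = [report["samplers"][n]["counts"][key] for n in names]
        lines.append(f"{label:<38}" + "".join(
            f"{'--' if v is None else format(v, '.3f'):>{width}}" for v in vals))
    for level, bounds in report["analytic_ci"].items():
        label = f"Equal tail {level}% CI = {bounds}"
        vals = [report["samplers"][n]["counts"]["ci"][level] for n in names]
        lines.append(f"{label:<38}" + "".join(f"{str(v):>{width}}" for v in vals))
    for key, label in (("gof_stat", "Time GoF chi2"),
                       ("gof_p_upper", "Time GoF p (upper tail)"),
                       ("w1", "Time W1")):
        vals = [report["samplers"][n]["time_gof"][key] for n in names]
        lines.append(f"{label:<38}" + "".join(f"{v:>{width}.3f}" for v in vals))
    lines.append("Gates: " + ("all passed" if report["passed"]
                              else "FAILED " + ", ".join(report["gates"])))
    return "\n".join(lines)
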