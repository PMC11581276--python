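import math

import numpy as np
import pytest
from scipy import stats

from ppsim import (AttributionError, CallableIntensity, ConstantIntensity,
                   DispatchError, DominationError, LinearIntensity,
                   LogLinearIntensity, MajorizerSpec, SpecError, StepIntensity,
                   TruncationSpec, choose_route, draw, sample_inversion,
                   sample_orderstat, sample_orderstats_general,
                   sample_prior_events, sample_thinning,
                   sample_truncated_poisson_count, superpose_and_attribute,
                   thinning_efficiency)
from util_stats import tv_distance, two_sample_count_chi2

SIX_PI = 6 * math.pi


class TestMajorizerSpec:
    def test_violation_detected(self, sinexp):
        too_low = MajorizerSpec.constant(10.0, sinexp.domain)
        with pytest.raises(DominationError):
            sample_thinning(sinexp, too_low, rng=np.random.default_rng(0))

    def test_unsupported_form(self, sinexp):
        bad = MajorizerSpec(CallableIntensity(rate_fn=lambda t: t * 0 + 50,
                                              domain=sinexp.domain))
        with pytest.raises(SpecError):
            sample_thinning(sinexp, bad, rng=np.random.default_rng(0))


class TestThinning:
    def test_accept_all_when_equal(self, rng):
        target = ConstantIntensity(2.0, (0, 5))
        maj = MajorizerSpec.constant(2.0, (0, 5))
        c1 = [len(sample_thinning(target, maj, rng=rng)) for _ in range(5_000)]
        c2 = [len(sample_orderstat(2.0, (0, 5), rng=rng)) for _ in range(5_000)]
        assert two_sample_count_chi2(c1, c2) > 0.01

    def test_acceptance_fraction_constant_majorizer(self, sinexp, sinexp_sup,
                                                    rng):
        maj = MajorizerSpec.constant(sinexp_sup, sinexp.domain)
        n_draws = 300
        accepted = sum(len(sample_thinning(sinexp, maj, rng=rng))
                       for _ in range(n_draws))
        proposal_mass = sinexp_sup * SIX_PI
        frac = accepted / (n_draws * proposal_mass)
        assert frac == pytest.approx(
            thinning_efficiency(sinexp, maj.model), abs=0.01)

    def test_count_mean_matches_cumulative(self, sinexp, sinexp_sup, rng):
        maj = MajorizerSpec.constant(sinexp_sup, sinexp.domain)
        counts = [len(sample_thinning(sinexp, maj, rng=rng))
                  for _ in range(100)]
        se = math.sqrt(sinexp.total / 100)
        assert np.mean(counts) == pytest.approx(sinexp.total, abs=3 * se)

    def test_at_most_k(self, sinexp, sinexp_sup, rng):
        maj = MajorizerSpec.constant(sinexp_sup, sinexp.domain)
        trunc = TruncationSpec(at_most_k=3)
        for _ in range(50):
            t = sample_thinning(sinexp, maj, truncation=trunc, rng=rng)
            assert len(t) <= 3

    def test_zero_truncated_never_empty(self, rng):
        # thin target with tiny mass; conditioning must still return >= 1
        target = ConstantIntensity(0.05, (0, 1))
        maj = MajorizerSpec.constant(0.5, (0, 1))
        trunc = TruncationSpec(at_least_m=1)
        for _ in range(300):
            assert len(sample_thinning(target, maj, truncation=trunc,
                                       rng=rng)) >= 1

    def test_zero_truncated_count_law_vs_rejection_oracle(self, rng):
        target = ConstantIntensity(1.2, (0, 1))
        maj = MajorizerSpec.constant(2.0, (0, 1))
        trunc = TruncationSpec(at_least_m=1)
        zt = [len(sample_thinning(target, maj, truncation=trunc, rng=rng))
              for _ in range(20_000)]
        raw = rng.poisson(1.2, 100_000)
        oracle = raw[raw >= 1][:20_000]
        assert tv_distance(zt, oracle) < 0.02

    def test_exactly_n_unsupported(self, sinexp, sinexp_sup, rng):
        maj = MajorizerSpec.constant(sinexp_sup, sinexp.domain)
        with pytest.raises(SpecError):
            sample_thinning(sinexp, maj,
                            truncation=TruncationSpec(exactly_n=3), rng=rng)


class TestInversion:
    def test_identity_transform_is_unit_rate(self, rng):
        unit = CallableIntensity(rate_fn=lambda t: np.ones_like(t),
                                 cumulative_fn=lambda t: t,
                                 inverse_fn=lambda z: z, domain=(0, 10))
        c1 = [len(sample_inversion(unit, rng=rng)) for _ in range(5_000)]
        c2 = [len(sample_orderstat(1.0, (0, 10), rng=rng)) for _ in range(5_000)]
        assert two_sample_count_chi2(c1, c2) > 0.01

    def test_sinexp_times_match_density(self, sinexp, rng):
        from ppsim import event_time_gof
        pooled = np.concatenate([sample_inversion(sinexp, rng=rng)
                                 for _ in range(300)])
        assert event_time_gof(pooled, sinexp).gof_p_upper > 0.01

    def test_no_events_in_zero_rate_stretch(self, rng):
        s = StepIntensity([0, 2, 4, 6], [3.0, 0.0, 3.0])
        for _ in range(400):
            t = sample_inversion(s, rng=rng)
            assert not np.any((t > 2.0) & (t <= 4.0))

    def test_missing_cumulative_raises(self, rng):
        bare = CallableIntensity(rate_fn=lambda t: np.ones_like(t),
                                 domain=(0, 1))
        with pytest.raises(SpecError):
            sample_inversion(bare, rng=rng)

    def test_first_event_early_exit_law(self, sinexp, rng):
        # at_most_k=1 must reproduce the first-event law of the full series
        trunc = TruncationSpec(at_most_k=1)
        early = [sample_inversion(sinexp, truncation=trunc, rng=rng)
                 for _ in range(2_000)]
        full = [sample_inversion(sinexp, rng=rng)[:1] for _ in range(2_000)]
        early = np.concatenate([e for e in early if len(e)])
        full = np.concatenate([f for f in full if len(f)])
        assert stats.ks_2samp(early, full).pvalue > 0.01


class TestOrderstatsGeneral:
    def test_constant_reduces_to_core_sampler(self, rng):
        c = ConstantIntensity(1.5, (2, 8))
        g = [len(sample_orderstats_general(c, rng=rng)) for _ in range(5_000)]
        h = [len(sample_orderstat(1.5, (2, 8), rng=rng)) for _ in range(5_000)]
        assert two_sample_count_chi2(g, h) > 0.01
        tg = np.concatenate([sample_orderstats_general(c, rng=rng)
                             for _ in range(2_000)])
        th = np.concatenate([sample_orderstat(1.5, (2, 8), rng=rng)
                             for _ in range(2_000)])
        assert stats.ks_2samp(tg, th).pvalue > 0.01

    def test_zero_truncated_low_mass_tail(self, sinexp, rng):
        window = (SIX_PI - 0.05, SIX_PI)
        mass = sinexp.cumulative_between(*window)
        trunc = TruncationSpec(at_least_m=1)
        counts = [len(sample_orderstats_general(sinexp, window, trunc, rng))
                  for _ in range(15_000)]
        counts = np.asarray(counts)
        assert np.all(counts >= 1)
        oracle = sample_truncated_poisson_count(mass, 1, rng=rng, size=15_000)
        assert tv_distance(counts, oracle) < 0.02

    def test_mean_count(self, sinexp, rng):
        counts = [len(sample_orderstats_general(sinexp, rng=rng))
                  for _ in range(2_000)]
        se = math.sqrt(sinexp.total / 2_000)
        assert np.mean(counts) == pytest.approx(sinexp.total, abs=3 * se)


class TestPriorEvents:
    def test_constant_rate_single_prior_uniform(self, rng):
        c = ConstantIntensity(2.0, (0, 10))
        priors = [sample_prior_events(c, anchor=7.0, i=2, rng=rng)[0]
                  for _ in range(10_000)]
        assert stats.kstest(np.array(priors) / 7.0, "uniform").pvalue > 0.01

    def test_count_contract(self, rng):
        c = ConstantIntensity(2.0, (0, 10))
        for _ in range(100):
            t = sample_prior_events(c, anchor=8.0, i=3, rng=rng)
            assert len(t) == 2 and np.all(t < 8.0) and np.all(np.diff(t) >= 0)

    def test_sinexp_prior_cdf(self, sinexp, rng):
        priors = np.array([sample_prior_events(sinexp, SIX_PI, 2, rng=rng)[0]
                           for _ in range(5_000)])
        cdf = lambda t: np.asarray(sinexp.cumulative(t)) / sinexp.total
        assert stats.kstest(priors, cdf).pvalue > 0.01

    def test_i_below_two_rejected(self, sinexp, rng):
        with pytest.raises(SpecError):
            sample_prior_events(sinexp, SIX_PI, 1, rng=rng)


class TestAttribution:
    def test_single_component(self, rng):
        c = ConstantIntensity(1.0, (0, 10))
        labels = superpose_and_attribute([c], np.linspace(0.1, 9.9, 50), rng)
        assert np.all(labels == 0)

    def test_equal_split(self, rng):
        comps = [ConstantIntensity(1.0, (0, 10)), ConstantIntensity(1.0, (0, 10))]
        labels = superpose_and_attribute(comps, np.linspace(0.1, 9.9, 10_000), rng)
        se = math.sqrt(0.25 / 1e4)
        assert np.mean(labels) == pytest.approx(0.5, abs=3 * se)

    def test_three_to_one_split(self, rng):
        comps = [ConstantIntensity(1.0, (0, 10)), ConstantIntensity(3.0, (0, 10))]
        labels = superpose_and_attribute(comps, np.linspace(0.1, 9.9, 10_000), rng)
        se = math.sqrt(0.75 * 0.25 / 1e4)
        assert np.mean(labels == 1) == pytest.approx(0.75, abs=3 * se)

    def test_all_zero_rates_error(self, rng):
        z = ConstantIntensity(0.0, (0, 10))
        with pytest.raises(AttributionError):
            superpose_and_attribute([z, z], np.array([5.0]), rng)


class TestDispatch:
    def test_cumulative_routes_to_inversion(self):
        assert choose_route(cumulative_fn=lambda t: t,
                            inverse_fn=lambda z: z) == "inversion"

    def test_rate_plus_majorizer_routes_to_thinning(self):
        assert choose_route(rate_fn=lambda t: t, majorizer=5.0) == "thinning"

    def test_step_params_route_to_special_case(self):
        assert choose_route(StepIntensity([0, 1], [2.0])) == "step"

    def test_model_with_cumulative_routes_to_inversion(self, sinexp):
        assert choose_route(sinexp) == "inversion"

    def test_empty_bundle_rejected(self):
        with pytest.raises(DispatchError):
            choose_route()

    def test_ambiguous_bundle_rejected(self, sinexp):
        with pytest.raises(DispatchError):
            choose_route(sinexp, rate_fn=lambda t: t)

    def test_rate_only_needs_majorizer(self):
        with pytest.raises(DispatchError):
            choose_route(rate_fn=lambda t: t)

    @pytest.mark.parametrize("spec_builder,expect_len_ok", [
        (lambda: StepIntensity([0, 1, 2], [1.0, 2.0]), True),
        (lambda: LinearIntensity(1.0, 0.1, (0, 5)), True),
        (lambda: LogLinearIntensity(0.0, 0.1, (0, 5)), True),
        (lambda: ConstantIntensity(2.0, (0, 5)), True),
    ], ids=["step", "linear", "loglinear", "constant"])
    def test_draw_executes_each_route(self, spec_builder, expect_len_ok, rng):
        t = draw(spec_builder(), rng=rng)
        assert np.all(np.diff(t) >= 0)

    def test_draw_thinning_route(self, rng):
        t = draw(rate_fn=lambda x: np.ones_like(x), majorizer=2.0,
                 interval=(0, 5), rng=rng)
        assert np.all((t > 0) & (t <= 5))

    def test_draw_inversion_route_bare_functions(self, rng):
        t = draw(cumulative_fn=lambda x: 0.5 * x ** 2,
                 inverse_fn=lambda z: np.sqrt(2 * z),
                 interval=(0, 4), rng=rng)
        assert np.all((t > 0) & (t <= 4))


class TestCrossAlgorithmAgreement:
    def test_loglinear_closed_form_vs_generic_orderstats(self, rng):
        # dual route: the special-case sampler vs the generic algorithm fed
        # independently written closed-form Lambda / inverse callables
        alpha, beta, iv = 0.5, 0.15, (0, 8)
        from ppsim import sample_loglinear
        ea = math.exp(alpha)
        generic_model = CallableIntensity(
            rate_fn=lambda t: np.exp(alpha + beta * t),
            cumulative_fn=lambda t: ea * (np.exp(beta * t) - 1.0) / beta,
            inverse_fn=lambda z: np.log(beta * z / ea + 1.0) / beta,
            domain=iv)
        c1 = [len(sample_loglinear((alpha, beta), iv, rng=rng))
              for _ in range(4_000)]
        c2 = [len(sample_orderstats_general(generic_model, rng=rng))
              for _ in range(4_000)]
        assert two_sample_count_chi2(c1, c2) > 0.01
        t1 = np.concatenate([sample_loglinear((alpha, beta), iv, rng=rng)
                             for _ in range(1_500)])
        t2 = np.concatenate([sample_orderstats_general(generic_model, rng=rng)
                             for _ in range(1_500)])
        assert stats.ks_2samp(t1, t2).pvalue > 0.01

    def test_inversion_vs_orderstats_on_sinexp_counts(self, sinexp, rng):
        c1 = [len(sample_inversion(sinexp, rng=rng)) for _ in range(1_000)]
        c2 = [len(sample_orderstats_general(sinexp, rng=rng))
              for _ in range(1_000)]
        assert two_sample_count_chi2(c1, c2) > 0.01
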