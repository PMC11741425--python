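import numpy as np
import pytest

from repeatflux.mutation_kernel import (ContextRates, InstabilityParams,
                                        JointState, RateModel, ScheduleStage,
                                        _fast_step, _rate_vectors, _step_core,
                                        build_rate_curves, check_linear_bound,
                                        evolve, flux_decomposition, iid_state,
                                        step_deterministic, step_stochastic,
                                        substitution_only_model, uniform_state)
from repeatflux.synthetic_data import DEFAULT_CONTEXT_RATES, DEFAULT_TRUTH

LB = 30


def empty_state(lb=LB):
    return JointState(np.zeros(lb + 1), np.zeros(lb + 1), lb)


def single_process_model(lb=LB, **curves):
    zeros = np.zeros(lb + 1)
    ctx = ContextRates(0, 0, 0, 0, 0, 0)
    model = {"expansion": zeros.copy(), "contraction": zeros.copy(),
             "insertion": zeros.copy()}
    for name, (length, value) in curves.items():
        model[name][length] = value
    return RateModel(ctx, l_boundary=lb, **model)


class TestRateCurves:
    def test_powerlaw_extension(self):
        base = np.full(8, 1e-6)
        rates = build_rate_curves(base, base, base,
                                  InstabilityParams(2.0, 1.0, 1.0),
                                  ContextRates(0, 0, 0, 0, 0, 0), 60)
        assert rates.expansion[9] == pytest.approx(2e-6)
        assert rates.expansion[18] == pytest.approx(4e-6)

    def test_zero_exponent_constant(self):
        base = np.full(8, 1e-6)
        rates = build_rate_curves(base, base, base,
                                  InstabilityParams(3.0, 0.0, 0.0),
                                  ContextRates(0, 0, 0, 0, 0, 0), 60)
        assert np.allclose(rates.expansion[9:], 3e-6)

    def test_cap_saturates(self):
        base = np.full(8, 1e-3)
        rates = build_rate_curves(base, base, base,
                                  InstabilityParams(32.0, 5.0, 5.0),
                                  ContextRates(0, 0, 0, 0, 0, 0), 60)
        assert rates.expansion.max() == pytest.approx(0.1)
        assert np.all(np.diff(rates.expansion[9:]) >= 0)

    def test_missing_denovo_rejected(self):
        with pytest.raises(ValueError):
            build_rate_curves(np.full(5, 1e-6), np.full(8, 1e-6),
                              np.full(8, 1e-6),
                              InstabilityParams(1, 1, 1),
                              ContextRates(0, 0, 0, 0, 0, 0), 60)


class TestStepRules:
    def test_zero_rates_identity(self):
        state = empty_state()
        state.counts_a[5] = 100.0
        state.counts_b[3] = 50.0
        new, flux = step_deterministic(state, single_process_model())
        assert np.array_equal(new.counts_a, state.counts_a)
        assert np.array_equal(new.counts_b, state.counts_b)
        assert flux.net() == pytest.approx(0)

    def test_substitution_fission_spread(self):
        """Fission of L=5 at rate 1e-3: 3 expected events, two fragments
        spread evenly over bins 1..3, one new B1, total length conserved."""
        ctx = ContextRates(0, 0, 0, 0.001, 0, 0)
        rates = substitution_only_model(ctx, LB)
        state = empty_state()
        state.counts_a[5] = 1000.0
        new, _ = step_deterministic(state, rates)
        assert new.counts_a[5] == pytest.approx(997.0)
        assert new.counts_a[1] == new.counts_a[2] == new.counts_a[3] == \
            pytest.approx(2.0)
        assert new.counts_b[1] == pytest.approx(3.0)
        assert new.total_length() == pytest.approx(state.total_length())

    def test_expansion_moves_one_count_up(self):
        rates = single_process_model(expansion=(10, 1e-4))
        state = empty_state()
        state.counts_a[10] = 1000.0
        new, _ = step_deterministic(state, rates)
        assert new.counts_a[10] == pytest.approx(999.0)
        assert new.counts_a[11] == pytest.approx(1.0)
        assert new.total_length() == pytest.approx(state.total_length() + 1)

    def test_fission_and_insertion_length_budget(self):
        """Substitution fission of L yields fragments totalling L-1 plus one
        B unit; insertion fission yields L plus one B unit."""
        for channel, gain in (("fission", 0), ("insertion", 1)):
            state = empty_state()
            state.counts_a[9] = 1000.0
            before = state.total_length()
            if channel == "fission":
                rates = substitution_only_model(
                    ContextRates(0, 0, 0, 1e-4, 0, 0), LB)
            else:
                rates = single_process_model(insertion=(9, 1e-4))
            new, _ = step_deterministic(state, rates)
            assert new.total_length() == pytest.approx(
                before + gain * (1e-4 * 9 * 1000))

    def test_fusion_bookkeeping(self):
        """Fusion consumes one B1 and merges two repeats into j+k+1."""
        ctx = ContextRates(0, 0, 1e-4, 0, 0, 0)
        rates = substitution_only_model(ctx, LB)
        state = empty_state()
        state.counts_a[4] = 1000.0
        state.counts_b[1] = 500.0
        new, _ = step_deterministic(state, rates)
        events = 1e-4 * 500
        assert state.counts_a[1:].sum() - new.counts_a[1:].sum() == \
            pytest.approx(events)
        assert new.counts_a[9] == pytest.approx(events)   # 4 + 4 + 1
        assert new.counts_b[1] == pytest.approx(500 - events)
        assert new.total_length() == pytest.approx(state.total_length())

    def test_reflective_boundary_keeps_mass(self):
        rates = single_process_model(expansion=(LB, 1e-3))
        state = empty_state()
        state.counts_a[LB] = 100.0
        new, _ = step_deterministic(state, rates)
        assert new.counts_a[LB] == pytest.approx(100.0)

    def test_negative_counts_raise_without_clip(self):
        rates = single_process_model(expansion=(10, 0.1))
        state = empty_state()
        state.counts_a[10] = 10.0
        with pytest.raises(RuntimeError):
            step_deterministic(state, rates, r=2, clip=False)

    def test_clip_floors_at_zero(self):
        rates = single_process_model(expansion=(10, 0.1))
        state = empty_state()
        state.counts_a[10] = 10.0
        new, _ = step_deterministic(state, rates, r=2, clip=True)
        assert new.counts_a.min() >= 0


class TestConservationAndEquilibrium:
    def test_substitutions_conserve_length(self):
        rates = substitution_only_model(DEFAULT_CONTEXT_RATES, 60)
        state = iid_state(1e7, 0.37, 60)
        before = state.total_length()
        res = evolve(state, rates, [ScheduleStage(0, 2000)])
        assert abs(res.state.total_length() - before) / before < 1e-12

    def test_iid_state_is_substitution_fixed_point(self):
        alpha, beta = 1.0e-4, 0.6e-4
        rates = substitution_only_model(
            ContextRates.from_two_way(alpha, beta), 60)
        state = iid_state(1e6, beta / (alpha + beta), 60)
        new, _ = step_deterministic(state, rates)
        rel = np.abs(new.counts_a[1:] - state.counts_a[1:]) / \
            np.maximum(state.counts_a[1:], 1e-300)
        assert rel[state.counts_a[1:] > 1e-6].max() < 1e-10

    def test_equilibrium_independent_of_initial_condition(self):
        alpha, beta = 1.0e-4, 0.6e-4
        rates = substitution_only_model(
            ContextRates.from_two_way(alpha, beta), 40)
        sched = [ScheduleStage(1, 60000)]
        res_u = evolve(uniform_state(1e6, 1e6, 40), rates, sched)
        res_g = evolve(iid_state(2.6e6, 0.5, 40), rates, sched)
        a_u = res_u.state.counts_a[1:20] / res_u.state.total_repeats()
        a_g = res_g.state.counts_a[1:20] / res_g.state.total_repeats()
        assert np.allclose(a_u, a_g, rtol=1e-4)

    def test_boundary_accumulation_monotone_when_unstable(self):
        truth = DEFAULT_TRUTH
        rates = build_rate_curves(truth.denovo_eps * 100,
                                  truth.denovo_kappa * 100,
                                  truth.denovo_iota * 100,
                                  InstabilityParams(2.0, 2.0, 1.0),
                                  ContextRates.from_two_way(1e-5, 6e-6), 40)
        state = iid_state(1e8, 0.375, 40)
        state.counts_a[1:] += 1.0
        levels = []
        current = state
        for _ in range(40):
            res = evolve(current, rates, [ScheduleStage(1, 500)],
                         boundary_trigger=np.inf)
            levels.append(res.state.counts_a[-1])
            current = res.state
        assert np.all(np.diff(levels) >= 0)


class TestFastStepEquivalence:
    @pytest.mark.parametrize("r", [0, 2, 5])
    def test_fast_step_matches_reference(self, r):
        truth = DEFAULT_TRUTH.scaled(1e3)
        rates = truth.rate_model(60)
        rng = np.random.default_rng(0)
        state = JointState(rng.uniform(0, 1e5, 61), rng.uniform(0, 1e5, 61),
                           60)
        state.counts_a[0] = state.counts_b[0] = 0
        ref_a, ref_b, _, _, _ = _step_core(state, rates, r, clip=True)
        fast_a, fast_b = _fast_step(state.counts_a, state.counts_b,
                                    10.0 ** r, *_rate_vectors(rates))
        scale = max(np.abs(ref_a).max(), 1.0)
        assert np.abs(np.maximum(ref_a, 0) - fast_a).max() / scale < 1e-12
        scale_b = max(np.abs(ref_b).max(), 1.0)
        assert np.abs(np.maximum(ref_b, 0) - fast_b).max() / scale_b < 1e-12


class TestLinearBound:
    def test_zero_rates_pass(self):
        state = empty_state()
        state.counts_a[5] = 10
        ok, bins = check_linear_bound(state, single_process_model(), 5)
        assert ok and bins == []

    def test_violation_detected_and_rescaled(self):
        rates = single_process_model(expansion=(10, 0.05))
        state = empty_state()
        state.counts_a[10] = 5.0
        ok, bins = check_linear_bound(state, rates, r=0)
        assert not ok and bins == [10]            # 0.05 * 10 = 0.5 > 0.1
        ok2, _ = check_linear_bound(state, rates, r=-1)
        assert ok2


class TestFlux:
    def test_single_process_influx_equals_outflux_shifted(self):
        rates = single_process_model(expansion=(10, 1e-4))
        state = empty_state()
        state.counts_a[10] = 1000.0
        table = flux_decomposition(state, rates, normalized=False)
        assert table.outflux["expansion"][10] == \
            pytest.approx(table.influx["expansion"][11])

    def test_normalized_table_sums_to_one_per_bin(self):
        truth = DEFAULT_TRUTH.scaled(100)
        rates = truth.rate_model(40)
        state = iid_state(1e6, 0.37, 40)
        table = flux_decomposition(state, rates, normalized=True)
        gross = table.gross()
        active = np.abs(gross) > 0
        assert np.allclose(gross[active], 1.0)

    def test_equilibrated_substitution_state_has_no_net_flux(self):
        alpha, beta = 1.0e-4, 0.6e-4
        rates = substitution_only_model(
            ContextRates.from_two_way(alpha, beta), 40)
        state = iid_state(1e6, beta / (alpha + beta), 40)
        table = flux_decomposition(state, rates, normalized=False)
        rel = np.abs(table.net()) / np.maximum(table.gross(), 1e-300)
        assert rel[state.counts_a >= 1].max() < 1e-6


class TestStochastic:
    def test_zero_rates_identity(self):
        state = empty_state()
        state.counts_a[5] = 100.0
        new = step_stochastic(state, single_process_model(), seed=0)
        assert np.array_equal(new.counts_a, state.counts_a)

    def test_seed_reproducible(self):
        truth = DEFAULT_TRUTH.scaled(1e4)
        rates = truth.rate_model(40)
        state = iid_state(1e5, 0.37, 40)
        a = step_stochastic(state, rates, seed=7)
        b = step_stochastic(state, rates, seed=7)
        assert np.array_equal(a.counts_a, b.counts_a)
        assert np.array_equal(a.counts_b, b.counts_b)

    def test_evolve_stochastic_reproducible(self):
        truth = DEFAULT_TRUTH.scaled(1e4)
        rates = truth.rate_model(40)
        state = iid_state(1e5, 0.37, 40)
        r1 = evolve(state, rates, [ScheduleStage(0, 50)], stochastic=True,
                    seed=3)
        r2 = evolve(state, rates, [ScheduleStage(0, 50)], stochastic=True,
                    seed=3)
        assert np.array_equal(r1.state.counts_a, r2.state.counts_a)
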