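"""The adaptive controller: selection, learning, the pulse clock, guessing."""

import collections
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refgame.agent import (
    AgentParams,
    UtilityState,
    guess,
    noisy_select,
    pulses_elapsed,
    run_experiment,
    run_trial,
    seconds_for_pulses,
    update_utilities,
)
from refgame.strategies import Strategy, StrategyOutcome, TimingParams
from refgame.task_model import Message, Referent, build_design, make_trial

R = Referent.from_code
M = Message.of

SIMPLE = make_trial(M("red"), (R("square-red"), R("triangle-red"), R("circle-blue")))
COMPLEX = make_trial(M("red"), (R("circle-red"), R("triangle-red"), R("circle-green")))
UNAMB = make_trial(M("green"), (R("circle-green"), R("square-red"), R("triangle-blue")))


def params(**kw):
    defaults = dict(f_neg=5.0, persistence=28)
    defaults.update(kw)
    return AgentParams(**defaults)


class TestNoisySelect:
    def test_zero_noise_is_argmax(self):
        u = {Strategy.A: 5.0, Strategy.B: -2.5, Strategy.C: -5.0}
        assert noisy_select(u, 0.0, random.Random(0)) is Strategy.A

    def test_equal_utilities_select_uniformly(self):
        rng = random.Random(1)
        u = {s: 0.0 for s in Strategy}
        counts = collections.Counter(noisy_select(u, 0.6, rng) for _ in range(9000))
        for s in Strategy:
            assert abs(counts[s] / 9000 - 1 / 3) < 0.03

    def test_matches_vectorized_monte_carlo_oracle(self):
        """Empirical selection frequencies agree with an independent numpy
        simulation of the logistic-noise argmax."""
        utilities = (0.0, 0.6, -10.0)
        s = 0.6
        rng = random.Random(2)
        counts = collections.Counter(
            noisy_select(utilities, s, rng) for _ in range(30000)
        )
        gen = np.random.default_rng(3)
        noisy = np.asarray(utilities)[None, :] + gen.logistic(0, s, size=(200000, 3))
        oracle = np.bincount(np.argmax(noisy, axis=1), minlength=3) / 200000
        for k, strat in enumerate(Strategy):
            assert abs(counts[strat] / 30000 - oracle[k]) < 0.015
        assert counts[Strategy.B] > counts[Strategy.A]


class TestUtilityLearning:
    def test_single_step_update(self):
        state = UtilityState(utilities={s: 0.0 for s in Strategy})
        state.fired.append((Strategy.A, 10.0))
        update_utilities(state, 5.0, now=10.0, learning_rate=0.2)
        assert state.utilities[Strategy.A] == pytest.approx(1.0)
        assert state.fired == []

    def test_update_requires_fired_productions(self):
        state = UtilityState(utilities={s: 0.0 for s in Strategy})
        with pytest.raises(ValueError):
            update_utilities(state, 5.0, now=0.0, learning_rate=0.2)

    def test_fixed_point_certain_success_with_delay(self):
        """A strategy rewarded +5 after a 10 s delay converges to utility -5."""
        state = UtilityState(utilities={s: 0.0 for s in Strategy})
        for _ in range(10000):
            state.fired.append((Strategy.B, 0.0))
            update_utilities(state, 5.0, now=10.0, learning_rate=0.2)
        assert state.utilities[Strategy.B] == pytest.approx(-5.0, abs=1e-6)

    def test_fixed_point_coin_flip_success_with_delay(self):
        """Equal-probability +5/-5 rewards at a 5 s delay average to -5."""
        state = UtilityState(utilities={s: 0.0 for s in Strategy})
        rng = random.Random(4)
        trace = []
        for i in range(10000):
            state.fired.append((Strategy.B, 0.0))
            magnitude = 5.0 if rng.random() < 0.5 else -5.0
            update_utilities(state, magnitude, now=5.0, learning_rate=0.2)
            if i >= 1000:
                trace.append(state.utilities[Strategy.B])
        assert abs(np.mean(trace) - (-5.0)) < 0.1


class TestPulseClock:
    def test_boundaries(self):
        assert pulses_elapsed(0.0, 0.1, 1.1) == 0
        assert pulses_elapsed(0.1, 0.1, 1.1) == 1
        assert pulses_elapsed(0.0999, 0.1, 1.1) == 0

    def test_geometric_sum(self):
        # 24 pulses of a 0.1 s clock growing by 1.1 complete at ~8.85 s
        assert seconds_for_pulses(24, 0.1, 1.1) == pytest.approx(8.8497, abs=1e-3)
        assert pulses_elapsed(8.85, 0.1, 1.1) == 24
        assert pulses_elapsed(8.84, 0.1, 1.1) == 23

    def test_constant_clock(self):
        assert pulses_elapsed(1.0, 0.1, 1.0) == 10

    @settings(max_examples=80, deadline=None)
    @given(
        s1=st.floats(0, 30),
        s2=st.floats(0, 30),
        start=st.floats(0.01, 0.5),
        mult=st.floats(1.0, 1.5),
    )
    def test_monotone_in_seconds(self, s1, s2, start, mult):
        lo, hi = sorted((s1, s2))
        assert pulses_elapsed(lo, start, mult) <= pulses_elapsed(hi, start, mult)


class TestGuess:
    def _outcome(self, accepted):
        return StrategyOutcome(
            strategy=Strategy.A,
            accepted=frozenset(accepted),
            solved=len(accepted) == 1,
            duration=1.0,
        )

    def test_two_candidates_split_evenly(self):
        rng = random.Random(5)
        last = self._outcome({0, 1})
        picks = collections.Counter(guess(SIMPLE, last, rng) for _ in range(4000))
        assert abs(picks[0] / 4000 - 0.5) < 0.03
        assert picks[2] == 0

    def test_empty_outcome_uses_literal_matches(self):
        rng = random.Random(6)
        last = self._outcome(set())
        picks = {guess(SIMPLE, last, rng) for _ in range(200)}
        assert picks == {0, 1}  # the two red referents

    def test_unambiguous_returns_single_match(self):
        assert guess(UNAMB, None, random.Random(0)) == 0


class TestRunTrial:
    def test_unambiguous_single_literal_attempt(self):
        state = UtilityState.fresh(params())
        res = run_trial(state, params(), UNAMB, random.Random(0))
        assert res.correct and not res.guessed
        assert [a[0] for a in res.attempts] == ["A"]
        assert res.rt > 0

    def test_timeout_guess_on_simple_trial(self):
        """With no noise and a persistence budget too short for the
        first-order strategy, the model fails literally, times out, and
        guesses between the two matches."""
        p = params(
            f_neg=5.0,
            persistence=10,
            utility_noise_s=1e-9,
            timing=TimingParams(noise_sd=0.0, p_retrieve=1.0),
            p_remember=1.0,
        )
        hits = 0
        for seed in range(200):
            state = UtilityState.fresh(p)
            res = run_trial(state, p, SIMPLE, random.Random(seed))
            assert res.guessed
            assert set(a[0] for a in res.attempts) == {"A"}
            assert res.response_role in ("target", "competitor")
            hits += res.correct
        assert abs(hits / 200 - 0.5) < 0.1

    def test_dominant_second_order_solves_complex(self):
        p = params(persistence=40, utility_noise_s=1e-9)
        state = UtilityState.fresh(p)
        state.utilities[Strategy.C] = 20.0
        res = run_trial(state, p, COMPLEX, random.Random(1))
        assert res.correct and not res.guessed
        assert [a[0] for a in res.attempts] == ["A", "C"]
        durations = [a[1] for a in res.attempts]
        assert res.rt == pytest.approx(
            sum(durations), abs=4.0
        )  # plus selection overheads

    def test_response_is_never_a_nonmatching_referent(self):
        for seed in range(60):
            p = params(f_neg=float(1 + seed % 9), persistence=24 + seed % 10)
            state = UtilityState.fresh(p)
            for trial in (SIMPLE, COMPLEX, UNAMB):
                res = run_trial(state, p, trial, random.Random(seed))
                assert res.response_index in trial.literal_matches()

    def test_literal_utility_decreases_toward_penalty_fixed_point(self):
        """Consecutive critical-trial failures with zero selection noise drive
        the literal strategy's utility monotonically down while it sits above
        the penalty fixed point (-F_NEG minus the temporal discount)."""
        p = params(f_neg=2.0, utility_noise_s=1e-9)
        state = UtilityState.fresh(p)
        values = [state.utilities[Strategy.A]]
        rng = random.Random(3)
        for _ in range(10):
            run_trial(state, p, COMPLEX, rng)
            values.append(state.utilities[Strategy.A])
        for a, b in zip(values, values[1:]):
            if a > -p.f_neg:
                assert b < a
        assert min(values) < values[0]
        assert all(v <= values[0] for v in values)


class TestRunExperiment:
    def test_deterministic_under_seed(self, d36_design):
        p = params()
        r1 = run_experiment(p, d36_design, rng=42)
        r2 = run_experiment(p, d36_design, rng=42)
        assert [(t.response_index, t.rt) for t in r1] == [
            (t.response_index, t.rt) for t in r2
        ]

    def test_strong_adaptor_reaches_high_late_accuracy(self, d66_design):
        p = params(f_neg=10.0, persistence=33)
        correct = []
        for seed in range(25):
            res = run_experiment(p, d66_design, rng=seed)
            n = len(res)
            correct += [
                t.correct
                for t in res
                if t.condition == "simple" and t.trial_index >= 3 * n // 4
            ]
        assert np.mean(correct) > 0.85

    def test_weak_adaptor_stays_near_chance_on_complex(self, d66_design):
        p = params(f_neg=0.5, persistence=24)
        correct = []
        for seed in range(25):
            res = run_experiment(p, d66_design, rng=seed)
            correct += [t.correct for t in res if t.condition == "complex"]
        assert abs(np.mean(correct) - 0.5) < 0.12


def test_agent_params_validation():
    with pytest.raises(ValueError):
        AgentParams(f_neg=0.0, persistence=24)
    with pytest.raises(ValueError):
        AgentParams(f_neg=1.0, persistence=0)
    with pytest.raises(ValueError):
        AgentParams(f_neg=1.0, persistence=24, learning_rate=1.5)


def test_agent_config_round_trip():
    p = AgentParams(f_neg=3.5, persistence=29, timing=TimingParams(t_scan=0.8))
    cfg = p.to_config()
    assert cfg["timing"]["t_scan"] == 0.8
    import json

    back = AgentParams.from_config(json.loads(json.dumps(cfg)))
    assert back == p
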