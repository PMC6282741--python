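"""Tests of the competing-hazards behavior sequence model."""

import numpy as np
import pytest

from fecalflow.behavior import (
    ANY_PREV,
    FEASIBLE_STATES,
    HORIZON_MIN,
    START_STATE,
    BehaviorSequence,
    State,
    TransitionRateSet,
    next_transition,
    simulate_day,
)
from fecalflow.synthetic import default_transition_rates


def simple_rates(hazard="weibull", shape=4.48):
    a = State("playing", "dirt_floor")
    b = State("eating", "dirt_floor")
    c = State("sleeping", "off_ground")
    return TransitionRateSet(
        rates={
            (ANY_PREV, a.key): {b.key: 30.0, c.key: 60.0},
            (ANY_PREV, b.key): {a.key: 20.0},
            (ANY_PREV, c.key): {a.key: 40.0},
        },
        shape=shape,
        hazard=hazard,
    )


class TestTransitionRateSet:
    def test_infeasible_states_rejected(self):
        with pytest.raises(ValueError, match="not feasible"):
            TransitionRateSet(rates={(ANY_PREV, "sleeping@open_drain"):
                                     {State("playing", "dirt_floor").key: 10.0}})
        with pytest.raises(ValueError, match="not feasible"):
            TransitionRateSet(rates={(ANY_PREV, State("playing", "dirt_floor").key):
                                     {"bathing@dirt_floor": 10.0}})

    def test_negative_scale_and_dead_ends_rejected(self):
        a = State("playing", "dirt_floor").key
        b = State("eating", "dirt_floor").key
        with pytest.raises(ValueError, match="negative scale"):
            TransitionRateSet(rates={(ANY_PREV, a): {b: -1.0}})
        with pytest.raises(ValueError, match="no positive exit rate"):
            TransitionRateSet(rates={(ANY_PREV, a): {b: 0.0}})

    def test_exact_previous_state_overrides_wildcard(self):
        a = State("playing", "dirt_floor")
        b = State("eating", "dirt_floor")
        c = State("defecating", "dirt_floor")
        rates = TransitionRateSet(rates={
            (ANY_PREV, a.key): {b.key: 30.0},
            (c.key, a.key): {b.key: 1.0},
            (ANY_PREV, b.key): {a.key: 10.0},
            (ANY_PREV, c.key): {a.key: 10.0},
        })
        assert rates.candidates(None, a) == {b.key: 30.0}
        assert rates.candidates(b, a) == {b.key: 30.0}
        assert rates.candidates(c, a) == {b.key: 1.0}

    def test_unknown_state_raises(self):
        rates = simple_rates()
        with pytest.raises(KeyError):
            rates.candidates(None, State("bathing", "concrete_floor"))

    def test_invalid_hazard_and_shape(self):
        with pytest.raises(ValueError):
            simple_rates(hazard="gompertz")
        with pytest.raises(ValueError):
            simple_rates(shape=0.0)


class TestNextTransition:
    def test_exponential_win_probabilities_are_rate_proportional(self, rng):
        # with shape 1 the candidates are exponentials with rates 1/scale:
        # P(win) = rate_i / sum(rates) = (1/30) / (1/30 + 1/60) = 2/3
        rates = simple_rates(hazard="exponential")
        a = State("playing", "dirt_floor")
        wins = sum(
            next_transition(None, a, rates, rng).next_state.behavior == "eating"
            for _ in range(30_000)
        )
        p = wins / 30_000
        assert abs(p - 2.0 / 3.0) < 3 * np.sqrt(p * (1 - p) / 30_000) + 0.005

    def test_weibull_win_probabilities_scale_to_the_shape_power(self, rng):
        # P(i wins) = scale_i**-k / sum(scale_j**-k)
        k = 4.48
        rates = simple_rates(shape=k)
        a = State("playing", "dirt_floor")
        expect = 30.0**-k / (30.0**-k + 60.0**-k)
        wins = sum(
            next_transition(None, a, rates, rng).next_state.behavior == "eating"
            for _ in range(30_000)
        )
        assert wins / 30_000 == pytest.approx(expect, abs=0.01)

    def test_winning_time_distribution(self, rng):
        # min of independent Weibulls with common shape k is Weibull with
        # scale (sum scale_j**-k)**(-1/k); check the mean
        from math import gamma as gamma_fn
        k = 4.48
        rates = simple_rates(shape=k)
        a = State("playing", "dirt_floor")
        lam_min = (30.0**-k + 60.0**-k) ** (-1.0 / k)
        times = np.array([next_transition(None, a, rates, rng).dwell_min
                          for _ in range(30_000)])
        assert times.mean() == pytest.approx(lam_min * gamma_fn(1 + 1 / k), rel=0.02)

    def test_dwell_is_always_positive(self, rng):
        rates = simple_rates()
        a = State("playing", "dirt_floor")
        assert all(next_transition(None, a, rates, rng).dwell_min > 0 for _ in range(1000))


class TestBehaviorSequence:
    def test_time_validation(self):
        s = State("playing", "dirt_floor")
        with pytest.raises(ValueError):
            BehaviorSequence(np.array([1.0, 2.0]), [s, s])
        with pytest.raises(ValueError):
            BehaviorSequence(np.array([0.0, 2.0, 2.0]), [s, s, s])
        with pytest.raises(ValueError):
            BehaviorSequence(np.array([0.0]), [s, s])

    def test_durations_truncate_at_horizon(self):
        s = State("playing", "dirt_floor")
        seq = BehaviorSequence(np.array([0.0, 100.0]), [s, s], horizon=840.0)
        np.testing.assert_allclose(seq.durations(), [100.0, 740.0])
        assert seq.total_time() == pytest.approx(840.0)

    def test_occupancy_sums_to_horizon(self, rng):
        seq = simulate_day(default_transition_rates(), rng)
        assert seq.occupancy().sum() == pytest.approx(HORIZON_MIN)

    def test_to_frame_layout(self, rng):
        seq = simulate_day(default_transition_rates(), rng)
        df = seq.to_frame(child_id=7)
        assert list(df.columns) == ["child_id", "t_start", "t_end", "behavior", "compartment"]
        assert (df["child_id"] == 7).all()
        assert (df["t_end"] > df["t_start"]).all()
        np.testing.assert_allclose(df["t_start"].to_numpy()[1:], df["t_end"].to_numpy()[:-1])


class TestSimulateDay:
    def test_day_starts_asleep_and_off_ground(self, rng):
        seq = simulate_day(default_transition_rates(), rng)
        assert seq.states[0] == START_STATE
        assert seq.times[0] == 0.0

    def test_states_are_feasible_and_consecutive_states_differ(self, rng):
        seq = simulate_day(default_transition_rates(), rng)
        feasible = set(FEASIBLE_STATES)
        assert all(s in feasible for s in seq.states)
        assert all(a != b for a, b in zip(seq.states, seq.states[1:]))

    def test_zero_horizon_returns_initial_state_only(self, rng):
        seq = simulate_day(default_transition_rates(), rng, horizon=0.0)
        assert seq.states == [START_STATE]
        assert seq.total_time() == 0.0

    def test_reproducible_for_equal_seeds(self):
        rates = default_transition_rates()
        a = simulate_day(rates, np.random.default_rng(5))
        b = simulate_day(rates, np.random.default_rng(5))
        assert a.states == b.states
        np.testing.assert_array_equal(a.times, b.times)

    def test_defecation_is_followed_by_handwashing_more_often(self):
        # the second-order rate entries should make post-defecation
        # handwashing far more frequent than baseline handwashing
        rates = default_transition_rates()
        rng = np.random.default_rng(99)
        after_def = 0
        n_def = 0
        base = 0
        n_base = 0
        for _ in range(300):
            seq = simulate_day(rates, rng)
            for prev, curr, nxt in zip(seq.states, seq.states[1:], seq.states[2:]):
                if curr.behavior == "defecating":
                    continue
                washed = nxt.behavior == "handwashing"
                if prev.behavior == "defecating":
                    n_def += 1
                    after_def += washed
                else:
                    n_base += 1
                    base += washed
        assert n_def > 50 and n_base > 500
        assert after_def / n_def > 3 * (base / n_base)

    def test_typical_day_composition(self):
        # broad sanity: meals happen, sleep happens, play dominates
        rates = default_transition_rates()
        rng = np.random.default_rng(123)
        meals, sleep_min, play_min = [], [], []
        for _ in range(100):
            seq = simulate_day(rates, rng)
            meals.append(sum(1 for s in seq.states if s.behavior == "eating"))
            occ = seq.occupancy()
            sleep_min.append(occ.filter(like="sleeping").sum())
            play_min.append(occ.filter(like="playing").sum())
        assert 1.0 < np.mean(meals) < 8.0
        assert 60.0 < np.mean(sleep_min) < 420.0
        assert np.mean(play_min) > np.mean(sleep_min)
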