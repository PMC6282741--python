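"""Competing-hazards simulation of a child's 14-hour day.

A child's day is a sequence of states, each a (behavior, compartment)
pair: six behaviors (playing/sitting, sleeping, handwashing, bathing,
defecating, eating) across five compartments (dirt floor, concrete floor,
off-ground, stagnant water/trash area, open drain).  Every feasible next
state competes for the transition: each candidate draws an event time from
its own hazard, and the earliest candidate wins, fixing both the dwell in
the current state and the next state.  Hazards may depend on the previous
state as well as the current one (second-order dependence), which lets
sequences such as defecation -> handwashing occur more often than a
first-order chain would allow.

Transition rates were never published for the field study this model
emulates; all shipped rate sets are synthetic (see
:func:`fecalflow.synthetic.default_transition_rates`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "State",
    "BEHAVIORS",
    "COMPARTMENTS",
    "FEASIBLE_STATES",
    "TransitionRateSet",
    "BehaviorSequence",
    "next_transition",
    "simulate_day",
    "HORIZON_MIN",
]

#: Length of the simulated daytime period, minutes (14 h).
HORIZON_MIN = 14 * 60.0

PLAYING = "playing"
SLEEPING = "sleeping"
HANDWASHING = "handwashing"
BATHING = "bathing"
DEFECATING = "defecating"
EATING = "eating"
BEHAVIORS = (PLAYING, SLEEPING, HANDWASHING, BATHING, DEFECATING, EATING)

DIRT_FLOOR = "dirt_floor"
CONCRETE_FLOOR = "concrete_floor"
OFF_GROUND = "off_ground"
STAGNANT_WATER = "stagnant_water"
OPEN_DRAIN = "open_drain"
COMPARTMENTS = (DIRT_FLOOR, CONCRETE_FLOOR, OFF_GROUND, STAGNANT_WATER, OPEN_DRAIN)


class State(NamedTuple):
    """One behavioral state: what the child is doing and where."""

    behavior: str
    compartment: str

    @property
    def key(self) -> str:
        return f"{self.behavior}@{self.compartment}"

    @classmethod
    def from_key(cls, key: str) -> "State":
        behavior, compartment = key.split("@")
        return cls(behavior, compartment)


#: Default feasibility mask: behavior x compartment pairs a child can occupy.
#: Washing/bathing happen at the (concrete) washing area; sleeping is
#: off-ground; play can happen anywhere, including the risky drain and
#: stagnant-water areas.
FEASIBLE_STATES: tuple[State, ...] = tuple(
    [State(PLAYING, c) for c in COMPARTMENTS]
    + [
        State(SLEEPING, OFF_GROUND),
        State(HANDWASHING, CONCRETE_FLOOR),
        State(BATHING, CONCRETE_FLOOR),
        State(DEFECATING, DIRT_FLOOR),
        State(DEFECATING, CONCRETE_FLOOR),
        State(EATING, DIRT_FLOOR),
        State(EATING, CONCRETE_FLOOR),
        State(EATING, OFF_GROUND),
    ]
)

START_STATE = State(SLEEPING, OFF_GROUND)

#: wildcard previous-state key for first-order rate entries
ANY_PREV = "*"


@dataclass
class TransitionRateSet:
    """Hazard scales for the competing next-state draws.

    ``rates`` maps ``(previous_state_key, current_state_key)`` to a mapping
    of candidate next-state keys onto Weibull scale parameters in minutes
    (smaller scale = stronger motivation = earlier candidate time).  The
    previous-state key may be the wildcard ``"*"``; an exact
    ``(prev, curr)`` entry overrides the wildcard, which is how
    second-order (previous-state-dependent) behavior is expressed.  All
    candidate hazards share one Weibull shape (``shape = 1`` makes them
    exponential).
    """

    rates: dict[tuple[str, str], dict[str, float]]
    shape: float = 4.48
    hazard: str = "weibull"
    feasible: tuple[State, ...] = FEASIBLE_STATES

    def __post_init__(self) -> None:
        if self.hazard not in ("weibull", "exponential"):
            raise ValueError("hazard must be 'weibull' or 'exponential'")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        feasible_keys = {s.key for s in self.feasible}
        for (prev, curr), cands in self.rates.items():
            if curr not in feasible_keys:
                raise ValueError(f"current state {curr!r} is not feasible")
            for nxt, scale in cands.items():
                if nxt not in feasible_keys:
                    raise ValueError(f"candidate next state {nxt!r} is not feasible")
                if scale < 0:
                    raise ValueError(f"negative scale for {curr!r} -> {nxt!r}")
            if not any(s > 0 for s in cands.values()):
                raise ValueError(f"state {curr!r} (after {prev!r}) has no positive exit rate")

    def candidates(self, prev: State | None, curr: State) -> dict[str, float]:
        prev_key = prev.key if prev is not None else ANY_PREV
        exact = self.rates.get((prev_key, curr.key))
        if exact is not None:
            return exact
        wild = self.rates.get((ANY_PREV, curr.key))
        if wild is not None:
            return wild
        raise KeyError(f"no transition rates for current state {curr.key!r} (prev {prev_key!r})")

    @property
    def effective_shape(self) -> float:
        return 1.0 if self.hazard == "exponential" else self.shape


class Transition(NamedTuple):
    next_state: State
    dwell_min: float


def next_transition(
    prev: State | None,
    curr: State,
    rates: TransitionRateSet,
    rng: np.random.Generator,
) -> Transition:
    """Resolve the competing hazards out of ``curr``.

    Each candidate next state draws an event time from a Weibull with the
    shared shape and its own scale; the earliest draw wins and its time is
    the dwell in the current state.
    """
    cands = rates.candidates(prev, curr)
    shape = rates.effective_shape
    best_state: str | None = None
    best_time = np.inf
    for key, scale in cands.items():
        if scale <= 0:
            continue
        t = scale * rng.weibull(shape)
        if t < best_time:
            best_time = t
            best_state = key
    if best_state is None:
        raise RuntimeError(f"state {curr.key!r} has no positive exit rate: stuck")
    # Weibull(shape>0) has an atom-free positive distribution; a literal 0.0
    # draw would stall the clock, so nudge it.
    if best_time <= 0.0:
        best_time = np.finfo(float).tiny
    return Transition(State.from_key(best_state), float(best_time))


@dataclass
class BehaviorSequence:
    """An ordered day of states: ``states[i]`` occupies [times[i], times[i+1])."""

    times: np.ndarray  # segment start times, minutes; times[0] == 0
    states: list[State]
    horizon: float = HORIZON_MIN

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) and (self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must start at 0 and be strictly increasing")

    def durations(self) -> np.ndarray:
        """Per-segment durations; the final segment is truncated at the horizon."""
        ends = np.append(self.times[1:], self.horizon)
        return ends - self.times

    def segments(self) -> Iterable[tuple[float, float, State]]:
        for t0, d, s in zip(self.times, self.durations(), self.states):
            yield float(t0), float(d), s

    def total_time(self) -> float:
        return float(self.durations().sum())

    def occupancy(self) -> pd.Series:
        """Total minutes per state key."""
        out: dict[str, float] = {}
        for _, d, s in self.segments():
            out[s.key] = out.get(s.key, 0.0) + d
        return pd.Series(out).sort_index()

    def to_frame(self, child_id: int | str = 0) -> pd.DataFrame:
        rows = [
            {
                "child_id": child_id,
                "t_start": t0,
                "t_end": t0 + d,
                "behavior": s.behavior,
                "compartment": s.compartment,
            }
            for t0, d, s in self.segments()
        ]
        return pd.DataFrame(rows)


def simulate_day(
    rates: TransitionRateSet,
    rng: np.random.Generator,
    *,
    horizon: float = HORIZON_MIN,
    start: State = START_STATE,
) -> BehaviorSequence:
    """Simulate one child-day of behavior.

    The day starts in the sleeping/off-ground state at time zero and runs
    until the first transition past ``horizon`` minutes; the final state is
    truncated there.  With ``horizon=0`` only the initial state is
    returned.
    """
    times = [0.0]
    states = [start]
    prev: State | None = None
    t = 0.0
    while True:
        if t >= horizon:
            break
        trans = next_transition(prev, states[-1], rates, rng)
        t_next = t + trans.dwell_min
        if t_next >= horizon:
            break
        prev = states[-1]
        times.append(t_next)
        states.append(trans.next_state)
        t = t_next
    return BehaviorSequence(np.asarray(times), states, horizon=horizon)
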