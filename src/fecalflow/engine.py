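"""Agent-based exposure engine: walk a behavior sequence, move microbes.

The engine interleaves a simulated day of behavior with stochastic microbe
transfers.  Seven exposure modules cover every contact type a state can
generate:

=================  =====================================================
``hand.fomites``   repeated hand-surface touches (attach + detach)
``hand.mouthing``  hand-to-mouth contacts (detach only, into the mouth)
``hand.drain``     immersion-like contact with drain/stagnant water
                   (attach only)
``hand.defecation`` rare direct contact with the child's own feces,
                   plus (ages 2-5) fomite touches in the current
                   compartment
``hand.washing`` / ``hand.bathing``  binomial removal of hand microbes,
                   effectiveness driven by duration and soap use
``eating``         breastfeeding / raw produce / prepared food, with
                   hand-food contacts when eaten by hand
``drinking``       daily tap or sachet water volume, split over meals
=================  =====================================================

Every transferred microbe keeps its origin label (soil, drain, food, ...),
so the full source-to-sink network is known and the day passes an exact
integer conservation audit: per source, microbes entering the child system
equal those ingested, removed by washing/bathing, returned to surfaces,
discarded with food skins, or still on the hands at day end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (
    BATHING,
    DEFECATING,
    EATING,
    HANDWASHING,
    PLAYING,
    SLEEPING,
    BehaviorSequence,
    State,
    simulate_day,
)
from .concentration import draw_concentration
from .config import ConfigurationError, RunConfig
from .factors import CUP_ML, SACHET_ML, wash_fraction_remaining
from .transfer import mouthing_transfer

__all__ = [
    "SOURCES",
    "HandLoad",
    "TransferEvent",
    "ExposureLedger",
    "dispatch",
    "run_state",
    "simulate_child_day",
    "simulate_population",
]

SOURCE_SOIL = "soil"
SOURCE_CONCRETE = "concrete_floor"
SOURCE_OFFGROUND = "off_ground"
SOURCE_DRAIN = "drain"
SOURCE_FECES = "own_feces"
SOURCE_FOOD = "food"
SOURCE_TAP = "tap_water"
SOURCE_SACHET = "sachet_water"

SOURCES = (
    SOURCE_SOIL,
    SOURCE_CONCRETE,
    SOURCE_OFFGROUND,
    SOURCE_DRAIN,
    SOURCE_FECES,
    SOURCE_FOOD,
    SOURCE_TAP,
    SOURCE_SACHET,
)

#: Hard cap on the total hand load.  Attachments that would push the load
#: past it are clamped (and the day flagged ``overflow``); this keeps the
#: exact hypergeometric subpool machinery within its integer range while
#: still accounting for every microbe that does enter the system.
HAND_POOL_CAP = 10**8

# compartment -> (source label, contamination stratum) for surface contact
_SURFACE_OF = {
    "dirt_floor": (SOURCE_SOIL, "soil"),
    "concrete_floor": (SOURCE_CONCRETE, "concrete_floor"),
    "off_ground": (SOURCE_OFFGROUND, "off_ground"),
}

MOUTH = "mouth"
HANDS = "hands"
WASH_SINK = "wash_sink"
BATH_SINK = "bath_sink"
SURFACE = "surface"
FOOD_NODE = "food"


class HandLoad(dict):
    """Integer microbe counts on the hands, keyed by origin source."""

    def total(self) -> int:
        return sum(self.values())

    def add(self, source: str, count: int) -> None:
        if count < 0:
            raise ValueError("cannot add a negative count")
        if count:
            self[source] = self.get(source, 0) + int(count)

    def nonzero(self) -> list[tuple[str, int]]:
        return [(s, c) for s, c in self.items() if c > 0]

    def draw_subpool(self, n: int, rng: np.random.Generator) -> dict[str, int]:
        """Pick ``n`` microbes uniformly at random without replacement.

        Returns counts per source (multivariate hypergeometric), honoring
        the assumption that microbes are uniformly distributed over the
        hand surface.
        """
        items = self.nonzero()
        if n <= 0 or not items:
            return {}
        counts = np.array([c for _, c in items], dtype=np.int64)
        n = min(int(n), int(counts.sum()))
        picked = rng.multivariate_hypergeometric(counts, n)
        return {s: int(k) for (s, _), k in zip(items, picked) if k > 0}

    def remove(self, by_source: dict[str, int]) -> None:
        for s, c in by_source.items():
            left = self.get(s, 0) - c
            if left < 0:
                raise ValueError(f"removing more {s!r} microbes than present")
            if left:
                self[s] = left
            else:
                self.pop(s, None)


@dataclass(frozen=True)
class TransferEvent:
    """One recorded microbe transfer between two network nodes."""

    time: float
    src: str
    dst: str
    count: int
    source: str
    direct: bool | None = None  # meaningful only for ingestion events


def _zero_by_source() -> dict[str, int]:
    return {s: 0 for s in SOURCES}


@dataclass
class ExposureLedger:
    """Source-to-sink accounting for one simulated child-day.

    Counters are exact integers per origin source.  ``events`` holds the
    full transfer log when the config requests it; the conserving totals
    and the hand-load time series are always kept.
    """

    child_id: int | str = 0
    age_group: str = "2-5"
    neighborhood: str = "bukom"
    horizon_min: float = 840.0
    record_events: bool = True

    events: list[TransferEvent] = field(default_factory=list)
    emitted: dict[str, int] = field(default_factory=_zero_by_source)
    ingested_direct: dict[str, int] = field(default_factory=_zero_by_source)
    ingested_indirect: dict[str, int] = field(default_factory=_zero_by_source)
    washed: dict[str, int] = field(default_factory=_zero_by_source)
    bathed: dict[str, int] = field(default_factory=_zero_by_source)
    returned_surface: dict[str, int] = field(default_factory=_zero_by_source)
    discarded_food: dict[str, int] = field(default_factory=_zero_by_source)
    hand_end: dict[str, int] = field(default_factory=_zero_by_source)
    nh_times: list[float] = field(default_factory=list)
    nh_values: list[int] = field(default_factory=list)
    overflow: bool = False

    # -- recording ----------------------------------------------------------

    def _log(self, ev: TransferEvent) -> None:
        if self.record_events and ev.count > 0:
            self.events.append(ev)

    def record_emission(self, time: float, source: str, dst: str, count: int) -> None:
        if count:
            self.emitted[source] += count
            self._log(TransferEvent(time, f"source:{source}", dst, count, source))

    def record_ingestion(self, time: float, src: str, by_source: dict[str, int], direct: bool) -> None:
        for s, c in by_source.items():
            if not c:
                continue
            (self.ingested_direct if direct else self.ingested_indirect)[s] += c
            self._log(TransferEvent(time, src, MOUTH, c, s, direct))

    def record_removal(self, time: float, sink: str, by_source: dict[str, int]) -> None:
        tgt = self.washed if sink == WASH_SINK else self.bathed
        for s, c in by_source.items():
            if not c:
                continue
            tgt[s] += c
            self._log(TransferEvent(time, HANDS, sink, c, s))

    def record_return(self, time: float, by_source: dict[str, int], *, to_food: bool = False) -> None:
        tgt = self.discarded_food if to_food else self.returned_surface
        dst = FOOD_NODE if to_food else SURFACE
        for s, c in by_source.items():
            if not c:
                continue
            tgt[s] += c
            self._log(TransferEvent(time, HANDS, dst, c, s))

    def record_hop(self, time: float, src: str, dst: str, by_source: dict[str, int]) -> None:
        """Log an intermediate transfer (e.g. hands -> food); no counter changes."""
        for s, c in by_source.items():
            if c:
                self._log(TransferEvent(time, src, dst, c, s))

    def record_direct_ingestion(self, time: float, source: str, count: int) -> None:
        """Microbes that pass straight from an environmental source to the mouth."""
        if count:
            self.emitted[source] += count
            self.ingested_direct[source] += count
            self._log(TransferEvent(time, f"source:{source}", MOUTH, count, source, True))

    def record_nh(self, time: float, nh: int) -> None:
        self.nh_times.append(time)
        self.nh_values.append(nh)

    def finalize(self, hand: HandLoad) -> None:
        for s, c in hand.items():
            self.hand_end[s] = self.hand_end.get(s, 0) + c
        self.record_nh(self.horizon_min, hand.total())

    # -- derived quantities --------------------------------------------------

    def ingested_by_source(self) -> dict[str, int]:
        return {s: self.ingested_direct[s] + self.ingested_indirect[s] for s in SOURCES}

    def total_ingested(self) -> int:
        return sum(self.ingested_by_source().values())

    def fraction_direct(self) -> float | None:
        """Direct share of total ingestion; ``None`` on zero-ingestion days."""
        total = self.total_ingested()
        if total == 0:
            return None
        return sum(self.ingested_direct.values()) / total

    def nh_at(self, time: float) -> int:
        """Hand load (all sources) at ``time``, stepwise-constant between events."""
        if not self.nh_times:
            return 0
        idx = np.searchsorted(np.asarray(self.nh_times), time, side="right") - 1
        if idx < 0:
            return 0
        return int(self.nh_values[idx])

    def audit(self) -> None:
        """Exact per-source conservation check; raises on any imbalance."""
        for s in SOURCES:
            sinks = (
                self.ingested_direct[s]
                + self.ingested_indirect[s]
                + self.washed[s]
                + self.bathed[s]
                + self.returned_surface[s]
                + self.discarded_food[s]
                + self.hand_end.get(s, 0)
            )
            if sinks != self.emitted[s]:
                raise AssertionError(
                    f"conservation violated for source {s!r}: emitted {self.emitted[s]} "
                    f"but sinks account for {sinks}"
                )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time": e.time,
                    "from": e.src,
                    "to": e.dst,
                    "count": e.count,
                    "source": e.source,
                    "direct": e.direct,
                }
                for e in self.events
            ],
            columns=["time", "from", "to", "count", "source", "direct"],
        )


# ---------------------------------------------------------------------------
# module dispatch
# ---------------------------------------------------------------------------

_DRAIN_COMPARTMENTS = ("stagnant_water", "open_drain")


def dispatch(state: State) -> tuple[str, ...]:
    """Exposure modules active in a behavioral state.

    Playing on a floor surface touches fomites and mouths hands; playing at
    the drain or stagnant-water area contacts drain water only; sleeping
    permits only hand mouthing; defecation may contact feces and (older
    children) nearby fomites.
    """
    b, c = state.behavior, state.compartment
    if b == PLAYING:
        if c in _DRAIN_COMPARTMENTS:
            return ("hand.drain",)
        if c in _SURFACE_OF:
            return ("hand.fomites", "hand.mouthing")
    if b == SLEEPING:
        return ("hand.mouthing",)
    if b == HANDWASHING:
        return ("hand.washing",)
    if b == BATHING:
        return ("hand.bathing",)
    if b == DEFECATING:
        return ("hand.defecation", "hand.fomites")
    if b == EATING:
        return ("eating",)
    raise ConfigurationError(f"no exposure modules mapped for state {state.key!r}")


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------

@dataclass
class _DayContext:
    """Day-level draws shared across a child-day."""

    env: dict[str, float]           # stratum -> concentration for this day
    exclusive_bf: bool
    sachet_user: bool
    daily_water_ml: float
    n_drinking_events: int


def _poisson_capped(mean: float, rng: np.random.Generator, config: RunConfig,
                    ledger: ExposureLedger) -> int:
    if mean <= 0:
        return 0
    if mean > config.event_cap:
        ledger.overflow = True
        return int(config.event_cap)
    n = int(rng.poisson(mean))
    if n > config.event_cap:
        ledger.overflow = True
        return int(config.event_cap)
    return n


def _attach_capped(hand: HandLoad, source: str, count: int, ledger: ExposureLedger) -> int:
    """Add microbes to the hands, clamping at :data:`HAND_POOL_CAP`.

    Returns the number actually added; the caller must record exactly this
    many as emitted so conservation stays exact.
    """
    room = HAND_POOL_CAP - hand.total()
    if count > room:
        ledger.overflow = True
        count = max(room, 0)
    if count:
        hand.add(source, count)
    return count


def _contact_fraction(config: RunConfig, rng: np.random.Generator) -> tuple[float, float]:
    """(contact area cm^2, fraction of total hand area), capped at the whole hand."""
    area = config.registry.sample("hand_contact_area_cm2", rng)
    frac = min(1.0, area / config.hand_area_cm2)
    return area, frac


def _fomite_touch(
    time: float,
    surface_source: str,
    conc_per_cm2: float,
    hand: HandLoad,
    config: RunConfig,
    ledger: ExposureLedger,
    rng: np.random.Generator,
) -> None:
    """One hand-surface touch: simultaneous binomial attach/detach."""
    reg = config.registry
    area, frac = _contact_fraction(config, rng)
    p = reg.sample("detachment_coefficient", rng)
    q = reg.sample("attachment_coefficient", rng)

    n_on_contact = int(rng.binomial(hand.total(), frac)) if hand.total() else 0
    contact_pool = hand.draw_subpool(n_on_contact, rng)
    n_contact = sum(contact_pool.values())
    detached_total = int(rng.binomial(n_contact, p)) if n_contact else 0
    if detached_total:
        items = list(contact_pool.items())
        counts = np.array([c for _, c in items], dtype=np.int64)
        alloc = rng.multivariate_hypergeometric(counts, detached_total)
        detached = {s: int(k) for (s, _), k in zip(items, alloc) if k > 0}
        hand.remove(detached)
        ledger.record_return(time, detached)

    m_surface = _poisson_capped(conc_per_cm2 * area, rng, config, ledger)
    attached = int(rng.binomial(m_surface, q)) if m_surface else 0
    attached = _attach_capped(hand, surface_source, attached, ledger)
    if attached:
        ledger.record_emission(time, surface_source, HANDS, attached)
    if detached_total or attached:
        ledger.record_nh(time, hand.total())


def _mouthing_event(
    time: float,
    hand: HandLoad,
    config: RunConfig,
    ledger: ExposureLedger,
    rng: np.random.Generator,
) -> None:
    if not hand.total():
        return
    reg = config.registry
    frac_mouth = reg.sample("hand_fraction_in_mouth", rng)
    removal = reg.sample("mouthing_removal_fraction", rng)
    ingested, remaining = mouthing_transfer(hand, frac_mouth, removal, rng)
    if ingested:
        hand.clear()
        hand.update({s: c for s, c in remaining.items() if c > 0})
        ledger.record_ingestion(time, HANDS, ingested, direct=False)
        ledger.record_nh(time, hand.total())


def _event_times(t0: float, duration: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.sort(t0 + rng.uniform(0.0, duration, size=n))


def _play_segment(
    t0: float,
    duration: float,
    state: State,
    hand: HandLoad,
    day: _DayContext,
    config: RunConfig,
    ledger: ExposureLedger,
    rng: np.random.Generator,
) -> None:
    """Interleaved fomite touches and hand mouthing while playing/sitting."""
    reg = config.registry
    source, stratum = _SURFACE_OF[state.compartment]
    if stratum == "soil":
        # soil carried per area via the adherence coefficient (mg/cm^2)
        adher = reg.sample("soil_adherence_mg_cm2", rng)
        conc_per_cm2 = day.env["soil"] * adher
    else:
        conc_per_cm2 = day.env[stratum]

    hours = duration / 60.0
    touch_rate = reg.sample("surface_contact_per_hour", rng)
    mouth_key = (
        "mouthing_per_hour_outdoor"
        if state.compartment in config.outdoor_compartments
        else "mouthing_per_hour_indoor"
    )
    mouth_rate = reg.sample(mouth_key, rng)
    n_touch = int(rng.poisson(touch_rate * hours))
    n_mouth = int(rng.poisson(mouth_rate * hours))
    times = np.concatenate([_event_times(t0, duration, n_touch, rng),
                            _event_times(t0, duration, n_mouth, rng)])
    kinds = np.concatenate([np.zeros(n_touch, dtype=int), np.ones(n_mouth, dtype=int)])
    order = np.argsort(times, kind="stable")
    for t, kind in zip(times[order], kinds[order]):
        if kind == 0:
            _fomite_touch(t, source, conc_per_cm2, hand, config, ledger, rng)
        else:
            _mouthing_event(t, hand, config, ledger, rng)


def _sleep_segment(t0, duration, hand, day, config, ledger, rng) -> None:
    # no surface contact during sleep; mouthing continues at the indoor rate
    reg = config.registry
    rate = reg.sample("mouthing_per_hour_indoor", rng)
    n = int(rng.poisson(rate * duration / 60.0))
    for t in _event_times(t0, duration, n, rng):
        _mouthing_event(t, hand, config, ledger, rng)


def _drain_segment(t0, duration, hand, day, config, ledger, rng) -> None:
    """Attachment-only pickup from drain/stagnant water; no detachment."""
    reg = config.registry
    rate = reg.sample("surface_contact_per_hour", rng)
    n = int(rng.poisson(rate * duration / 60.0))
    c_drain = day.env["drain_water"]
    for t in _event_times(t0, duration, n, rng):
        area, _ = _contact_fraction(config, rng)
        film_ul = reg.sample("water_adherence_ul_cm2", rng)
        mean = c_drain * film_ul * 1e-3 * area  # CFU/mL * mL
        attached = _poisson_capped(mean, rng, config, ledger)
        attached = _attach_capped(hand, SOURCE_DRAIN, attached, ledger)
        if attached:
            ledger.record_emission(t, SOURCE_DRAIN, HANDS, attached)
            ledger.record_nh(t, hand.total())


def _defecation_segment(t0, duration, state, hand, day, config, ledger, rng) -> None:
    reg = config.registry
    # rare direct contact with own feces (attach only)
    p_touch = reg.sample("prob_touch_own_feces", rng)
    if rng.random() < p_touch:
        t = t0 + rng.uniform(0.0, duration)
        area, _ = _contact_fraction(config, rng)
        adher = reg.sample("soil_adherence_mg_cm2", rng)
        mean = day.env["feces"] * adher * area  # CFU/mg * mg
        attached = _poisson_capped(mean, rng, config, ledger)
        attached = _attach_capped(hand, SOURCE_FECES, attached, ledger)
        if attached:
            ledger.record_emission(t, SOURCE_FECES, HANDS, attached)
            ledger.record_nh(t, hand.total())
    # only 2-5 year olds touch surrounding fomites while defecating
    if config.age_group == "2-5" and state.compartment in _SURFACE_OF:
        p_contact = reg.sample("prob_surface_contact_defecation", rng)
        if rng.random() < p_contact:
            freq = reg.sample("surface_contacts_defecation_per_hour", rng)
            n = int(rng.poisson(freq * duration / 60.0))
            source, stratum = _SURFACE_OF[state.compartment]
            if stratum == "soil":
                adher = reg.sample("soil_adherence_mg_cm2", rng)
                conc = day.env["soil"] * adher
            else:
                conc = day.env[stratum]
            for t in _event_times(t0, duration, n, rng):
                _fomite_touch(t, source, conc, hand, config, ledger, rng)


def _washing_segment(t0, duration, hand, day, config, ledger, rng, *, bathing: bool) -> None:
    reg = config.registry
    if not hand.total():
        return
    dur_s = reg.sample("bathing_duration_s" if bathing else "handwash_duration_s", rng)
    p_soap = reg.sample("prob_bathing_soap" if bathing else "prob_handwash_soap", rng)
    soap = rng.random() < p_soap
    remaining = wash_fraction_remaining(dur_s, soap)
    removed: dict[str, int] = {}
    for s, c in hand.nonzero():
        r = int(rng.binomial(c, 1.0 - remaining))
        if r:
            removed[s] = r
    if removed:
        hand.remove(removed)
        t = t0 + min(dur_s / 60.0, duration)
        ledger.record_removal(t, BATH_SINK if bathing else WASH_SINK, removed)
        ledger.record_nh(t, hand.total())


def _hand_food_touch(time, hand, food_pool: int, food_is_emitted: bool, config, ledger, rng
                     ) -> tuple[int, dict[str, int]]:
    """One touch between the hand and a food item.

    Returns ``(m_attached_to_hand, detached_by_source)``.  The detached
    microbes now sit on the food; the caller decides whether they are
    ingested (inner, prepared food) or discarded (outer skin).  When the
    food pool is not yet counted as emitted (outer skins), only the
    attached part is emitted.
    """
    reg = config.registry
    _, frac = _contact_fraction(config, rng)
    p = reg.sample("detachment_coefficient", rng)
    q = reg.sample("attachment_coefficient", rng)

    n_on_contact = int(rng.binomial(hand.total(), frac)) if hand.total() else 0
    contact_pool = hand.draw_subpool(n_on_contact, rng)
    n_contact = sum(contact_pool.values())
    detached_total = int(rng.binomial(n_contact, p)) if n_contact else 0
    detached: dict[str, int] = {}
    if detached_total:
        items = list(contact_pool.items())
        counts = np.array([c for _, c in items], dtype=np.int64)
        alloc = rng.multivariate_hypergeometric(counts, detached_total)
        detached = {s: int(k) for (s, _), k in zip(items, alloc) if k > 0}
        hand.remove(detached)

    m = int(rng.binomial(food_pool, q)) if food_pool else 0
    m = _attach_capped(hand, SOURCE_FOOD, m, ledger)
    if m:
        if food_is_emitted:
            ledger.record_hop(time, FOOD_NODE, HANDS, {SOURCE_FOOD: m})
        else:
            ledger.record_emission(time, SOURCE_FOOD, HANDS, m)
    if detached:
        ledger.record_hop(time, HANDS, FOOD_NODE, detached)
    if m or detached_total:
        ledger.record_nh(time, hand.total())
    return m, detached


def _eating_segment(t0, duration, hand, day, config, ledger, rng) -> None:
    reg = config.registry
    ag = config.age_group
    if day.exclusive_bf:
        return  # breast milk carries no fecal microbes
    if rng.random() < reg.sample("prob_breastfeeding", rng, age_group=ag):
        return
    t = t0 + 0.5 * duration
    if rng.random() < reg.sample("prob_raw_or_bought_food", rng, age_group=ag):
        # raw produce: outer skin handled first, inner (clean) part eaten
        serving_g = reg.sample("raw_produce_serving_g", rng)
        skin_load = _poisson_capped(day.env["produce"] * serving_g, rng, config, ledger)
        _m, detached = _hand_food_touch(t, hand, skin_load, False, config, ledger, rng)
        if detached:
            # discarded with the skin (counters only; the hop was logged)
            for s, c in detached.items():
                ledger.discarded_food[s] += c
        # breaking the skin: a second hand contact deposits microbes on the
        # clean inner part, which is then ingested
        _m2, inner = _hand_food_touch(t, hand, 0, True, config, ledger, rng)
        if inner:
            ledger.record_ingestion(t, FOOD_NODE, inner, direct=False)
    else:
        serving_g = reg.sample("prepared_food_serving_g", rng)
        food_load = _poisson_capped(day.env["prepared_food"] * serving_g, rng, config, ledger)
        if food_load:
            ledger.record_emission(t, SOURCE_FOOD, FOOD_NODE, food_load)
        from_hands: dict[str, int] = {}
        attached = 0
        if rng.random() < reg.sample("prob_eat_with_hands", rng):
            attached, from_hands = _hand_food_touch(t, hand, food_load, True, config, ledger, rng)
        direct_part = food_load - attached
        if direct_part:
            ledger.record_ingestion(t, FOOD_NODE, {SOURCE_FOOD: direct_part}, direct=True)
        if from_hands:
            ledger.record_ingestion(t, FOOD_NODE, from_hands, direct=False)


def _drinking_event(t, day, config, ledger, rng) -> None:
    if day.n_drinking_events <= 0:
        return
    vol = day.daily_water_ml / day.n_drinking_events
    stratum = "sachet_water" if day.sachet_user else "tap_water"
    source = SOURCE_SACHET if day.sachet_user else SOURCE_TAP
    count = _poisson_capped(day.env[stratum] * vol, rng, config, ledger)
    ledger.record_direct_ingestion(t, source, count)


def run_state(
    state: State,
    t0: float,
    duration: float,
    hand: HandLoad,
    day: _DayContext,
    config: RunConfig,
    ledger: ExposureLedger,
    rng: np.random.Generator,
) -> None:
    """Run every exposure module active in one state occupancy."""
    if duration <= 0:
        return
    modules = dispatch(state)
    for mod in modules:
        if mod == "hand.mouthing" and state.behavior == PLAYING:
            continue  # handled jointly with hand.fomites to interleave events
        if mod == "hand.fomites" and state.behavior == PLAYING:
            _play_segment(t0, duration, state, hand, day, config, ledger, rng)
        elif mod == "hand.fomites" and state.behavior == DEFECATING:
            continue  # folded into the defecation module below
        elif mod == "hand.mouthing":
            _sleep_segment(t0, duration, hand, day, config, ledger, rng)
        elif mod == "hand.drain":
            _drain_segment(t0, duration, hand, day, config, ledger, rng)
        elif mod == "hand.defecation":
            _defecation_segment(t0, duration, state, hand, day, config, ledger, rng)
        elif mod == "hand.washing":
            _washing_segment(t0, duration, hand, day, config, ledger, rng, bathing=False)
        elif mod == "hand.bathing":
            _washing_segment(t0, duration, hand, day, config, ledger, rng, bathing=True)
        elif mod == "eating":
            _eating_segment(t0, duration, hand, day, config, ledger, rng)
            _drinking_event(t0 + 0.5 * duration, day, config, ledger, rng)


def _make_day_context(config: RunConfig, rng: np.random.Generator,
                      n_drinking_events: int) -> _DayContext:
    reg = config.registry
    env = {k: draw_concentration(g, rng) for k, g in config.concentrations.items()}
    p_excl = reg.sample("prob_exclusive_breastfeeding", rng, age_group=config.age_group)
    exclusive_bf = rng.random() < p_excl
    p_sachet = reg.sample("prob_sachet_water", rng, neighborhood=config.neighborhood)
    sachet_user = rng.random() < p_sachet
    if sachet_user:
        units = reg.sample("sachet_water_daily_sachets", rng, age_group=config.age_group)
        daily_ml = units * SACHET_ML
    else:
        units = reg.sample("tap_water_daily_cups", rng, age_group=config.age_group)
        daily_ml = units * CUP_ML
    return _DayContext(
        env=env,
        exclusive_bf=exclusive_bf,
        sachet_user=sachet_user,
        daily_water_ml=daily_ml,
        n_drinking_events=n_drinking_events,
    )


def simulate_child_day(
    config: RunConfig,
    rng: np.random.Generator,
    *,
    child_id: int | str = 0,
    sequence: BehaviorSequence | None = None,
) -> ExposureLedger:
    """Simulate one 14-hour child-day and return its exposure ledger.

    A behavior sequence is generated (or taken from ``sequence``), the
    day's environmental concentrations are drawn from their gamma
    distributions, and every state occupancy is run through its exposure
    modules.  The returned ledger passes :meth:`ExposureLedger.audit`.
    """
    seq = sequence if sequence is not None else simulate_day(
        config.rates, rng, horizon=config.horizon_min
    )
    n_meals = sum(1 for s in seq.states if s.behavior == EATING)
    day = _make_day_context(config, rng, n_drinking_events=max(n_meals, 1))
    ledger = ExposureLedger(
        child_id=child_id,
        age_group=config.age_group,
        neighborhood=config.neighborhood,
        horizon_min=config.horizon_min,
        record_events=config.record_events,
    )
    hand = HandLoad()
    ledger.record_nh(0.0, 0)
    for t0, dur, state in seq.segments():
        run_state(state, t0, dur, hand, day, config, ledger, rng)
    if n_meals == 0:
        # the daily water volume is a day-level constraint: drink at day end
        _drinking_event(config.horizon_min, day, config, ledger, rng)
    ledger.finalize(hand)
    return ledger


def child_rng(root_seed: int, child_index: int) -> np.random.Generator:
    """Independent, order-invariant stream for one child (counter-based split)."""
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(child_index,)))


def simulate_population(
    config: RunConfig,
    n_children: int = 10_000,
    *,
    root_seed: int = 0,
) -> list[ExposureLedger]:
    """Simulate ``n_children`` independent child-days.

    Each child gets its own counter-derived random stream, so results do
    not depend on execution order.  When ``config.strata`` is set, children
    cycle through the configured age-group x neighborhood strata.
    """
    if n_children < 1:
        raise ValueError("need at least one child")
    from dataclasses import replace

    ledgers = []
    strata = config.strata
    for i in range(n_children):
        cfg = config
        if strata:
            st = strata[i % len(strata)]
            cfg = replace(config, age_group=st.get("age_group", config.age_group),
                          neighborhood=st.get("neighborhood", config.neighborhood))
        ledgers.append(simulate_child_day(cfg, child_rng(root_seed, i), child_id=i))
    return ledgers
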