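"""Synthetic-data generators: every input the pipeline needs, no downloads.

The field campaign this model was designed around collected environmental
replicate counts, household survey responses and structured observations;
none of those microdata are distributable.  This module generates
statistically faithful stand-ins:

* :func:`gen_count_table` -- gamma-distributed concentrations observed
  through Poisson dilution counts, in the reader's CSV layout;
* :func:`gen_survey` -- binary behavior responses and interval-censored
  water-intake reports (integer cups/sachets);
* :func:`default_config` -- a complete run configuration: the full factor
  registry, synthetic behavioral transition rates, and synthetic gamma
  concentration strata.

Every quantity that the source literature does not publish (transition
rates, concentration strata, the total hand area) is synthetic and flagged
as such where it is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .behavior import (
    BATHING,
    CONCRETE_FLOOR,
    DEFECATING,
    DIRT_FLOOR,
    EATING,
    HANDWASHING,
    OFF_GROUND,
    OPEN_DRAIN,
    PLAYING,
    SLEEPING,
    STAGNANT_WATER,
    State,
    TransitionRateSet,
)
from .concentration import GammaConcentration, ReplicateSample
from .config import RunConfig
from .factors import IntervalObservation, default_registry

__all__ = [
    "SyntheticDesign",
    "gen_count_table",
    "gen_survey",
    "default_transition_rates",
    "default_concentrations",
    "default_config",
]


@dataclass
class SyntheticDesign:
    """Design of a synthetic sampling campaign.

    ``strata`` maps (sample_type, location) to the true gamma concentration
    parameters used to generate counts.  ``dilutions`` are the fractions of
    ``base_amount`` plated per dilution step, each with ``replicates``
    plates.
    """

    strata: dict[tuple[str, str], GammaConcentration]
    n_samples_per_stratum: int = 50
    replicates: int = 2
    dilutions: tuple[float, ...] = (1.0, 0.1, 0.01)
    base_amount: float = 1.0
    n_respondents: int = 200
    true_binary_prob: float = 0.3
    true_intake_mu: float = 0.9
    true_intake_sigma: float = 0.6
    seed: int = 0

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "n_samples_per_stratum": self.n_samples_per_stratum,
            "replicates": self.replicates,
            "dilutions": list(self.dilutions),
        }


def gen_count_table(design: SyntheticDesign) -> list[ReplicateSample]:
    """Generate replicate dilution counts from the design's gamma strata.

    Per sample a concentration ``c ~ Gamma(rho, lam)`` is drawn, then every
    plated replicate observes ``k ~ Poisson(c * V)`` with ``V`` the
    equivalent amount of that dilution.  The output is reader-compatible
    (see :func:`fecalflow.concentration.write_counts_csv`).
    """
    rng = np.random.default_rng(design.seed)
    amounts = tuple(
        float(design.base_amount * d) for d in design.dilutions for _ in range(design.replicates)
    )
    samples: list[ReplicateSample] = []
    for (stype, loc), g in design.strata.items():
        for i in range(design.n_samples_per_stratum):
            c = rng.gamma(g.shape, g.scale)
            counts = tuple(int(k) for k in rng.poisson(c * np.asarray(amounts)))
            samples.append(
                ReplicateSample(
                    counts=counts,
                    equiv_amounts=amounts,
                    sample_type=stype,
                    location=loc,
                    sample_id=f"{stype}-{loc}-{i:04d}",
                )
            )
    return samples


def gen_survey(design: SyntheticDesign) -> tuple[np.ndarray, list[IntervalObservation]]:
    """Generate binary responses and interval-censored intake reports.

    Binary responses are Bernoulli draws with the design's true
    probability.  Intakes are lognormal draws binned to whole cups: a
    respondent reporting ``n`` cups is recorded as the interval
    ``(n-1, n]`` for n >= 1 and ``(0, 1]`` for intakes under one cup; the
    top category is open-ended.
    """
    rng = np.random.default_rng(design.seed + 1)
    binary = (rng.random(design.n_respondents) < design.true_binary_prob).astype(int)
    intakes = rng.lognormal(design.true_intake_mu, design.true_intake_sigma, design.n_respondents)
    top = 10  # "10 or more cups" is open-ended
    obs = []
    for x in intakes:
        n = max(int(math.ceil(x)), 1)
        if n >= top:
            obs.append(IntervalObservation(float(top - 1), math.inf))
        else:
            obs.append(IntervalObservation(float(n - 1), float(n)))
    return binary, obs


_SHAPE = 4.48

#: compartment split of the playing behavior (risky drain/trash areas rare)
_PLAY_SPLIT = {
    DIRT_FLOOR: 0.32,
    CONCRETE_FLOOR: 0.32,
    OFF_GROUND: 0.32,
    STAGNANT_WATER: 0.02,
    OPEN_DRAIN: 0.02,
}


def _scales_from_weights(weights: dict[str, float], dwell_scale: float,
                         shape: float = _SHAPE) -> dict[str, float]:
    """Candidate Weibull scales realizing given win probabilities.

    With shared shape ``k`` and scales ``lam_i``, candidate ``i`` wins the
    competing-hazard race with probability ``lam_i**-k / sum(lam_j**-k)``,
    and the winning time is Weibull with scale ``(sum lam_j**-k)**(-1/k)``.
    Inverting: ``lam_i = dwell_scale * (w_i / sum w)**(-1/k)`` gives win
    probabilities proportional to the weights and a dwell whose scale is
    ``dwell_scale`` (mean dwell ~ 0.91 * dwell_scale at k = 4.48).
    """
    total = sum(weights.values())
    return {
        key: dwell_scale * (w / total) ** (-1.0 / shape)
        for key, w in weights.items()
        if w > 0
    }


def default_transition_rates() -> TransitionRateSet:
    """Synthetic competing-hazard scales over the feasible state space.

    No transition rates were ever published for the behavior model this
    generator emulates, so these are invented to produce a plausible
    child-day: mostly playing/sitting (floor surfaces far more than the
    drain or trash areas), a nap, about three meals, occasional defecation,
    and hygiene events that become far more likely right after defecation
    (a genuinely second-order effect).  Per current behavior a typical
    dwell scale (minutes) and next-state weights are chosen, then converted
    to per-candidate Weibull scales by :func:`_scales_from_weights`.
    """
    def spread(behavior_weights: dict[str, float]) -> dict[str, float]:
        """Expand behavior-level weights onto state keys."""
        out: dict[str, float] = {}
        for b, w in behavior_weights.items():
            if b == PLAYING:
                for c, share in _PLAY_SPLIT.items():
                    out[State(PLAYING, c).key] = w * share
            elif b == SLEEPING:
                out[State(SLEEPING, OFF_GROUND).key] = w
            elif b == HANDWASHING:
                out[State(HANDWASHING, CONCRETE_FLOOR).key] = w
            elif b == BATHING:
                out[State(BATHING, CONCRETE_FLOOR).key] = w
            elif b == DEFECATING:
                for c in (DIRT_FLOOR, CONCRETE_FLOOR):
                    out[State(DEFECATING, c).key] = w / 2
            elif b == EATING:
                for c in (DIRT_FLOOR, CONCRETE_FLOOR, OFF_GROUND):
                    out[State(EATING, c).key] = w / 3
        return out

    # (dwell scale in minutes, next-behavior weights) per current behavior
    plans = {
        PLAYING: (45.0, {PLAYING: 0.55, SLEEPING: 0.08, EATING: 0.18,
                         HANDWASHING: 0.05, BATHING: 0.03, DEFECATING: 0.11}),
        SLEEPING: (80.0, {PLAYING: 0.78, EATING: 0.15, HANDWASHING: 0.02,
                          BATHING: 0.02, DEFECATING: 0.03}),
        HANDWASHING: (2.0, {PLAYING: 0.65, EATING: 0.30, SLEEPING: 0.05}),
        BATHING: (12.0, {PLAYING: 0.80, EATING: 0.10, SLEEPING: 0.10}),
        DEFECATING: (8.0, {PLAYING: 0.70, HANDWASHING: 0.20, BATHING: 0.05,
                           EATING: 0.05}),
        EATING: (25.0, {PLAYING: 0.75, SLEEPING: 0.15, HANDWASHING: 0.10}),
    }

    rates: dict[tuple[str, str], dict[str, float]] = {}
    all_keys: list[str] = []
    for behavior, (dwell, weights) in plans.items():
        cand_weights = spread(weights)
        if behavior == PLAYING:
            keys = [State(PLAYING, c).key for c in _PLAY_SPLIT]
        elif behavior == SLEEPING:
            keys = [State(SLEEPING, OFF_GROUND).key]
        elif behavior == HANDWASHING:
            keys = [State(HANDWASHING, CONCRETE_FLOOR).key]
        elif behavior == BATHING:
            keys = [State(BATHING, CONCRETE_FLOOR).key]
        elif behavior == DEFECATING:
            keys = [State(DEFECATING, c).key for c in (DIRT_FLOOR, CONCRETE_FLOOR)]
        else:
            keys = [State(EATING, c).key for c in (DIRT_FLOOR, CONCRETE_FLOOR, OFF_GROUND)]
        all_keys.extend(keys)
        for key in keys:
            w = {k: v for k, v in cand_weights.items() if k != key}
            rates[("*", key)] = _scales_from_weights(w, dwell)

    # second-order conditioning: coming out of defecation, the urge to wash
    # hands dominates the next transition from wherever the child went
    hw = State(HANDWASHING, CONCRETE_FLOOR).key
    defecating_keys = [k for k in all_keys if State.from_key(k).behavior == DEFECATING]
    for prev_key in defecating_keys:
        for curr_key in all_keys:
            if curr_key == prev_key:
                continue
            behavior = State.from_key(curr_key).behavior
            dwell, weights = plans[behavior]
            boosted = dict(weights)
            boosted[HANDWASHING] = boosted.get(HANDWASHING, 0.0) + 3.0
            cand_weights = spread(boosted)
            w = {k: v for k, v in cand_weights.items() if k != curr_key}
            if behavior != HANDWASHING and hw in w:
                rates[(prev_key, curr_key)] = _scales_from_weights(w, dwell * 0.3)
    return TransitionRateSet(rates=rates, shape=_SHAPE, hazard="weibull")


def default_concentrations() -> dict[str, GammaConcentration]:
    """Synthetic gamma concentration strata (shape, scale; mean = shape*scale).

    The study's fitted neighborhood values were never published; these
    magnitudes only respect the ordering reported for dense urban
    neighborhoods -- heavily contaminated drains, feces and street food,
    moderately contaminated soil, and relatively clean piped and sachet
    water.
    """
    return {
        "soil": GammaConcentration(0.5, 40.0),            # CFU/mg, mean 20
        "concrete_floor": GammaConcentration(0.6, 20.0),  # CFU/cm2, mean 12
        "off_ground": GammaConcentration(0.6, 5.0),       # CFU/cm2, mean 3
        "drain_water": GammaConcentration(0.3, 1.0e4),    # CFU/mL, mean 3000
        "feces": GammaConcentration(1.0, 1.0e5),          # CFU/mg, mean 1e5
        "produce": GammaConcentration(0.5, 100.0),        # CFU/g, mean 50
        "prepared_food": GammaConcentration(0.4, 250.0),  # CFU/g, mean 100
        "tap_water": GammaConcentration(0.5, 2.0),        # CFU/mL, mean 1
        "sachet_water": GammaConcentration(0.3, 1.0),     # CFU/mL, mean 0.3
    }


def default_config(**overrides) -> RunConfig:
    """A complete, validated run configuration usable out of the box.

    Combines the full exposure-factor registry with synthetic transition
    rates and synthetic concentration strata.  Keyword overrides are passed
    to :class:`fecalflow.config.RunConfig`.
    """
    cfg = RunConfig(
        registry=default_registry(),
        rates=default_transition_rates(),
        concentrations=default_concentrations(),
        **overrides,
    )
    return cfg
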