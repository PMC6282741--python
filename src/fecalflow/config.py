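"""Run configuration: factors, behavior rates, contamination strata, constants.

A :class:`RunConfig` bundles everything one simulated child-day needs:

* the exposure-factor registry (:mod:`fecalflow.factors`),
* a behavioral transition-rate set (:mod:`fecalflow.behavior`),
* gamma concentration distributions per contamination stratum -- either
  fixed parameters or medians of a fitted posterior,
* demographic context (age group, neighborhood) and physical constants.

Configs round-trip through YAML so a whole study is reproducible from one
file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import yaml

from .behavior import FEASIBLE_STATES, HORIZON_MIN, State, TransitionRateSet
from .concentration import GammaConcentration
from .factors import FactorRegistry

__all__ = ["RunConfig", "CONCENTRATION_STRATA", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a run configuration is incomplete or inconsistent."""


#: Contamination strata the engine consumes, with their concentration units.
CONCENTRATION_STRATA: dict[str, str] = {
    "soil": "CFU/mg",
    "concrete_floor": "CFU/cm2",
    "off_ground": "CFU/cm2",
    "drain_water": "CFU/mL",
    "feces": "CFU/mg",
    "produce": "CFU/g",
    "prepared_food": "CFU/g",
    "tap_water": "CFU/mL",
    "sachet_water": "CFU/mL",
}


@dataclass
class RunConfig:
    """Complete configuration for simulating child-days."""

    registry: FactorRegistry
    rates: TransitionRateSet
    concentrations: dict[str, GammaConcentration]
    age_group: str = "2-5"
    neighborhood: str = "bukom"
    horizon_min: float = HORIZON_MIN
    #: total two-hand surface area of a young child, cm^2 (synthetic constant)
    hand_area_cm2: float = 420.0
    #: per-event integer cap; larger transfers are capped and flagged
    event_cap: int = 10**9
    #: keep the full per-event ledger (False keeps only conserving totals
    #: and the hand-load time series)
    record_events: bool = True
    #: compartments whose hand-mouthing uses the outdoor frequency
    outdoor_compartments: tuple[str, ...] = ("dirt_floor", "stagnant_water", "open_drain")
    #: optional population strata: list of {"age_group": ..., "neighborhood": ...}
    strata: list[dict[str, str]] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in CONCENTRATION_STRATA if s not in self.concentrations]
        if missing:
            raise ConfigurationError(f"missing concentration strata: {missing}")

    def with_concentrations_scaled(self, factor: float) -> "RunConfig":
        """A copy with every stratum's concentration scale multiplied by ``factor``."""
        scaled = {
            k: GammaConcentration(g.shape, g.scale * factor) for k, g in self.concentrations.items()
        }
        return replace(self, concentrations=scaled)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "registry": self.registry.to_list(),
            "rates": {
                "shape": self.rates.shape,
                "hazard": self.rates.hazard,
                "entries": [
                    {"prev": prev, "curr": curr, "next": dict(cands)}
                    for (prev, curr), cands in self.rates.rates.items()
                ],
                "feasible": [s.key for s in self.rates.feasible],
            },
            "concentrations": {
                k: {"shape": g.shape, "scale": g.scale, "unit": CONCENTRATION_STRATA[k]}
                for k, g in self.concentrations.items()
            },
            "age_group": self.age_group,
            "neighborhood": self.neighborhood,
            "horizon_min": self.horizon_min,
            "hand_area_cm2": self.hand_area_cm2,
            "event_cap": self.event_cap,
            "record_events": self.record_events,
            "outdoor_compartments": list(self.outdoor_compartments),
            "strata": self.strata,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        rates_d = d["rates"]
        feasible = tuple(State.from_key(k) for k in rates_d.get("feasible", [])) or FEASIBLE_STATES
        rates = TransitionRateSet(
            rates={(e["prev"], e["curr"]): dict(e["next"]) for e in rates_d["entries"]},
            shape=rates_d.get("shape", 4.48),
            hazard=rates_d.get("hazard", "weibull"),
            feasible=feasible,
        )
        conc = {
            k: GammaConcentration(v["shape"], v["scale"]) for k, v in d["concentrations"].items()
        }
        return cls(
            registry=FactorRegistry.from_list(d["registry"]),
            rates=rates,
            concentrations=conc,
            age_group=d.get("age_group", "2-5"),
            neighborhood=d.get("neighborhood", "bukom"),
            horizon_min=d.get("horizon_min", HORIZON_MIN),
            hand_area_cm2=d.get("hand_area_cm2", 420.0),
            event_cap=d.get("event_cap", 10**9),
            record_events=d.get("record_events", True),
            outdoor_compartments=tuple(d.get("outdoor_compartments", ("dirt_floor", "stagnant_water", "open_drain"))),
            strata=d.get("strata"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
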