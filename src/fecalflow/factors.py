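"""Exposure-factor registry and the two survey estimators.

Every tunable exposure factor of the simulator -- contacted hand areas,
attachment/detachment coefficients, hand-mouth frequencies, handwashing
behavior, food choice probabilities, water consumption -- is described by a
:class:`FactorSpec` naming a distribution family and its parameters.  The
shipped default registry (:func:`default_registry`) carries the full set of
factors used by the exposure model, each with a provenance note; entries
whose values are not backed by published estimates are flagged
``synthetic``.

Two estimators turn raw survey data into factor parameters:

* :func:`beta_posterior` -- conjugate Beta posterior for binary behavior
  attributes (e.g. washing with vs. without soap) under a uniform prior.
* :func:`fit_interval_lognormal` -- maximum likelihood for a lognormal
  daily water intake observed only as "how many cups/sachets", i.e. as
  interval-censored data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FactorSpec",
    "FactorRegistry",
    "BetaPosterior",
    "IntervalObservation",
    "beta_posterior",
    "fit_interval_lognormal",
    "sample_factor",
    "wash_fraction_remaining",
    "default_registry",
    "CUP_ML",
    "SACHET_ML",
]

#: Volume of a single cup of drinking water (mL).
CUP_ML = 237.0
#: Volume of a single sachet of drinking water (mL).
SACHET_ML = 500.0

AGE_GROUPS = ("0-1", "1-2", "2-5")
NEIGHBORHOODS = ("alajo", "bukom", "old_fadama", "shiabu")

_FAMILIES = {
    "lognormal",     # params: mu, sigma (log scale)
    "beta",          # params: alpha, beta
    "triangle",      # params: a (min), c (mode), b (max)
    "gamma",         # params: shape, scale
    "gamma_offset",  # params: shape, scale, offset
    "weibull",       # params: shape, scale
    "normal",        # params: mu, sigma (redrawn until positive)
    "uniform",       # params: a, b
    "linlog",        # params: b0, b1  (log10 fraction = b0 + b1*ln(duration))
    "constant_by_age",  # params: one value per age group
}


@dataclass
class FactorSpec:
    """One exposure factor: a named distribution with provenance.

    ``context`` restricts the entry to an age group and/or neighborhood
    (empty means the factor applies to everyone).
    """

    name: str
    family: str
    params: dict[str, float | dict[str, float]]
    source: str = ""
    context: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r} for factor {self.name!r}")
        self._validate()

    def _validate(self) -> None:
        p = self.params
        f = self.family
        if f == "triangle":
            if not (p["a"] <= p["c"] <= p["b"]):
                raise ValueError(f"triangle needs a <= c <= b in factor {self.name!r}")
        elif f == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError(f"beta needs positive shapes in factor {self.name!r}")
        elif f in ("gamma", "gamma_offset", "weibull"):
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError(f"{f} needs positive shape/scale in factor {self.name!r}")
        elif f in ("lognormal", "normal"):
            if p["sigma"] <= 0:
                raise ValueError(f"{f} needs sigma > 0 in factor {self.name!r}")
        elif f == "uniform":
            if not p["a"] < p["b"]:
                raise ValueError(f"uniform needs a < b in factor {self.name!r}")
        elif f == "constant_by_age":
            missing = [g for g in AGE_GROUPS if g not in p["values"]]
            if missing:
                raise ValueError(f"constant_by_age factor {self.name!r} missing age groups {missing}")

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "family": self.family, "params": self.params}
        if self.source:
            d["source"] = self.source
        if self.context:
            d["context"] = self.context
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(
            name=d["name"],
            family=d["family"],
            params=d["params"],
            source=d.get("source", ""),
            context=d.get("context", {}),
        )


class FactorRegistry:
    """Lookup table of :class:`FactorSpec` entries keyed by name and context."""

    def __init__(self, specs: Sequence[FactorSpec] = ()):
        self._specs: list[FactorSpec] = list(specs)

    def add(self, spec: FactorSpec) -> None:
        self._specs.append(spec)

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self):
        return iter(self._specs)

    def get(self, name: str, *, age_group: str | None = None, neighborhood: str | None = None) -> FactorSpec:
        """Resolve a factor, preferring the most specific context match."""
        context = {"age_group": age_group, "neighborhood": neighborhood}
        best: FactorSpec | None = None
        best_rank = -1
        for spec in self._specs:
            if spec.name != name:
                continue
            ok = all(context.get(k) == v for k, v in spec.context.items())
            if not ok:
                continue
            rank = len(spec.context)
            if rank > best_rank:
                best, best_rank = spec, rank
        if best is None:
            raise KeyError(
                f"no factor named {name!r} for age_group={age_group!r}, neighborhood={neighborhood!r}"
            )
        return best

    def sample(self, name: str, rng: np.random.Generator, *, age_group: str | None = None,
               neighborhood: str | None = None, duration: float | None = None) -> float:
        return sample_factor(self.get(name, age_group=age_group, neighborhood=neighborhood),
                             rng, age_group=age_group, duration=duration)

    def to_list(self) -> list[dict]:
        return [s.to_dict() for s in self._specs]

    @classmethod
    def from_list(cls, entries: Sequence[dict]) -> "FactorRegistry":
        return cls([FactorSpec.from_dict(e) for e in entries])


def sample_factor(spec: FactorSpec, rng: np.random.Generator, *, age_group: str | None = None,
                  duration: float | None = None) -> float:
    """Draw one value from a factor's distribution.

    ``duration`` (seconds) is required for the ``linlog`` family, which is a
    deterministic model of the fraction of microbes remaining after washing;
    ``age_group`` is required for ``constant_by_age`` entries.
    """
    p = spec.params
    f = spec.family
    if f == "lognormal":
        return float(rng.lognormal(p["mu"], p["sigma"]))
    if f == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if f == "triangle":
        if p["a"] == p["b"]:
            return float(p["a"])
        return float(rng.triangular(p["a"], p["c"], p["b"]))
    if f == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    if f == "gamma_offset":
        return float(rng.gamma(p["shape"], p["scale"]) + p["offset"])
    if f == "weibull":
        return float(p["scale"] * rng.weibull(p["shape"]))
    if f == "normal":
        # physical quantities (serving weights): redraw the rare negative
        for _ in range(1000):
            x = rng.normal(p["mu"], p["sigma"])
            if x > 0:
                return float(x)
        raise RuntimeError(f"normal factor {spec.name!r} failed to yield a positive draw")
    if f == "uniform":
        return float(rng.uniform(p["a"], p["b"]))
    if f == "linlog":
        if duration is None:
            raise ValueError(f"factor {spec.name!r} needs a duration (seconds)")
        return _linlog_fraction(duration, p["b0"], p["b1"])
    if f == "constant_by_age":
        if age_group is None:
            raise ValueError(f"factor {spec.name!r} needs an age_group")
        try:
            return float(p["values"][age_group])
        except KeyError as exc:
            raise KeyError(f"factor {spec.name!r} has no value for age group {age_group!r}") from exc
    raise AssertionError(f"unhandled family {f!r}")


def _linlog_fraction(duration_s: float, b0: float, b1: float) -> float:
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    frac = 10.0 ** (b0 + b1 * math.log(duration_s))
    return min(1.0, max(0.0, frac))


# linear-log coefficients for the log10 fraction of microbes remaining on
# hands after washing/bathing, by soap use
_WASH_COEFFS = {True: (2.18, -1.18), False: (0.68, -0.80)}


def wash_fraction_remaining(duration_s: float, with_soap: bool, *, log_base: str = "natural") -> float:
    """Fraction of hand microbes remaining after washing for ``duration_s`` seconds.

    The model is ``fraction = 10^(b0 + b1 * log(duration))`` with soap-specific
    coefficients, clamped to [0, 1]; longer washing removes more.  The inner
    log defaults to natural: with base-10 the with-soap fraction would exceed
    one for any wash shorter than about 70 s, which is unusable as a
    "remaining fraction".  ``log_base="10"`` is available for sensitivity
    work.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    b0, b1 = _WASH_COEFFS[bool(with_soap)]
    if log_base == "natural":
        logd = math.log(duration_s)
    elif log_base == "10":
        logd = math.log10(duration_s)
    else:
        raise ValueError("log_base must be 'natural' or '10'")
    return min(1.0, max(0.0, 10.0 ** (b0 + b1 * logd)))


# ---------------------------------------------------------------------------
# survey estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaPosterior:
    """Beta posterior for a binary behavior probability."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


def beta_posterior(y: int, n: int) -> BetaPosterior:
    """Posterior of a behavior probability from ``y`` successes in ``n`` trials.

    Uses the uninformed uniform prior Beta(1, 1), so the posterior is
    Beta(y + 1, n - y + 1).  The conjugacy makes batching irrelevant:
    splitting the data and updating twice gives the same posterior.
    """
    if y != int(y) or n != int(n):
        raise ValueError("y and n must be integers")
    y, n = int(y), int(n)
    if not 0 <= y <= n:
        raise ValueError(f"need 0 <= y <= n; got y={y}, n={n}")
    return BetaPosterior(y + 1.0, n - y + 1.0)


@dataclass(frozen=True)
class IntervalObservation:
    """One interval-censored intake report: the true intake lies in (lower, upper]."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError("lower bound must be >= 0")
        if not self.upper > self.lower:
            raise ValueError("upper bound must exceed lower bound")


def fit_interval_lognormal(
    observations: Sequence[IntervalObservation],
) -> tuple[float, float]:
    """MLE of lognormal intake parameters from interval-censored reports.

    Maximizes the product over observations of
    ``Phi((log U - mu)/sigma) - Phi((log L - mu)/sigma)`` where ``Phi`` is
    the standard normal CDF; ``L = 0`` contributes a lower CDF of zero and
    ``U = inf`` an upper CDF of one.  Returns ``(mu, sigma)`` on the log
    scale.  If every interval is identical the likelihood is maximized on
    the ``sigma -> 0`` boundary; a warning is issued and the boundary
    estimate (interval log-midpoint, 0.0) is returned.
    """
    obs = list(observations)
    if len(obs) < 2:
        raise ValueError("need at least two observations")
    if len({(o.lower, o.upper) for o in obs}) == 1:
        o = obs[0]
        warnings.warn(
            "all intervals identical: sigma is driven to the boundary 0",
            RuntimeWarning,
            stacklevel=2,
        )
        lo = math.log(o.lower) if o.lower > 0 else math.log(o.upper) - 1.0
        hi = math.log(o.upper) if math.isfinite(o.upper) else lo + 2.0
        return (0.5 * (lo + hi), 0.0)

    log_lo = np.array([math.log(o.lower) if o.lower > 0 else -np.inf for o in obs])
    log_hi = np.array([math.log(o.upper) if math.isfinite(o.upper) else np.inf for o in obs])

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        upper = stats.norm.cdf(log_hi, mu, sigma)
        lower = stats.norm.cdf(log_lo, mu, sigma)
        prob = np.clip(upper - lower, 1e-300, 1.0)
        return -float(np.log(prob).sum())

    # moment start from interval midpoints (finite parts only)
    mids = []
    for lo, hi in zip(log_lo, log_hi):
        if np.isfinite(lo) and np.isfinite(hi):
            mids.append(0.5 * (lo + hi))
        elif np.isfinite(hi):
            mids.append(hi - 0.5)
        else:
            mids.append(lo + 0.5)
    mids_arr = np.array(mids)
    mu0 = float(mids_arr.mean())
    sigma0 = float(max(mids_arr.std(), 0.2))
    res = optimize.minimize(nll, x0=[mu0, math.log(sigma0)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    if not res.success:
        warnings.warn(f"interval-censored MLE did not fully converge: {res.message}", RuntimeWarning)
    mu_hat, log_sigma_hat = res.x
    return float(mu_hat), float(math.exp(log_sigma_hat))


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------

def default_registry() -> FactorRegistry:
    """Registry of all exposure factors used by the simulator.

    Values originate from published exposure-factor literature, national
    survey statistics, and structured observation / household survey
    estimates for children under five in dense urban neighborhoods;
    entries with no published backing are marked ``synthetic`` in their
    provenance note.
    """
    reg = FactorRegistry()
    add = reg.add

    add(FactorSpec("hand_contact_area_cm2", "lognormal", {"mu": 2.75, "sigma": 0.75},
                   "exposure-factor handbooks: area of the hand touching a surface"))
    add(FactorSpec("hand_fraction_in_mouth", "beta", {"alpha": 3.7, "beta": 25.0},
                   "micro-activity studies: fraction of the hand surface mouthed"))
    add(FactorSpec("attachment_coefficient", "triangle", {"a": 0.01, "c": 0.02, "b": 0.03},
                   "surface-to-hand transfer efficiency"))
    add(FactorSpec("detachment_coefficient", "triangle", {"a": 0.5, "c": 0.75, "b": 0.95},
                   "hand-to-surface transfer efficiency; assumption"))
    add(FactorSpec("handwash_duration_s", "gamma_offset", {"shape": 2.5, "scale": 10.0, "offset": 10.0},
                   "assumption"))
    add(FactorSpec("bathing_duration_s", "gamma_offset", {"shape": 4.0, "scale": 60.0, "offset": 60.0},
                   "assumption"))
    add(FactorSpec("wash_log10_remaining_soap", "linlog", {"b0": 2.18, "b1": -1.18},
                   "handwashing efficacy literature (with soap)"))
    add(FactorSpec("wash_log10_remaining_nosoap", "linlog", {"b0": 0.68, "b1": -0.80},
                   "handwashing efficacy literature (without soap)"))
    add(FactorSpec("mouthing_removal_fraction", "triangle", {"a": 0.01, "c": 0.33, "b": 0.40},
                   "fraction of hand microbes removed per hand-mouth contact"))
    add(FactorSpec("prob_handwash_soap", "beta", {"alpha": 5.0, "beta": 17.0},
                   "structured observation"))
    add(FactorSpec("prob_bathing_soap", "beta", {"alpha": 45.0, "beta": 19.0},
                   "structured observation"))
    add(FactorSpec("soil_adherence_mg_cm2", "lognormal", {"mu": 0.11, "sigma": 2.0},
                   "soil-to-skin adherence"))
    add(FactorSpec("water_adherence_ul_cm2", "lognormal", {"mu": 5.4, "sigma": 0.5},
                   "water film adhering to skin"))
    add(FactorSpec("surface_contact_per_hour", "weibull", {"shape": 1.85, "scale": 145.0},
                   "hand-surface contact frequency for children"))
    add(FactorSpec("mouthing_per_hour_indoor", "weibull", {"shape": 0.91, "scale": 18.79},
                   "indoor hand-mouth frequency"))
    add(FactorSpec("mouthing_per_hour_outdoor", "weibull", {"shape": 0.98, "scale": 13.76},
                   "outdoor hand-mouth frequency"))
    add(FactorSpec("prob_touch_own_feces", "beta", {"alpha": 5.0, "beta": 41.0},
                   "structured observation; defecation, ages 2-5"))
    add(FactorSpec("prob_surface_contact_defecation", "beta", {"alpha": 24.0, "beta": 18.0},
                   "structured observation"))
    add(FactorSpec("surface_contacts_defecation_per_hour", "uniform", {"a": 1.0, "b": 10.0},
                   "assumption"))
    add(FactorSpec("prob_exclusive_breastfeeding", "constant_by_age",
                   {"values": {"0-1": 0.339, "1-2": 0.007, "2-5": 0.0}},
                   "national demographic survey"))
    for ag, (a, b) in {"0-1": (79, 46), "1-2": (85, 114), "2-5": (10, 90)}.items():
        add(FactorSpec("prob_breastfeeding", "beta", {"alpha": float(a), "beta": float(b)},
                       "structured observation; breastfeeding given not exclusively breastfed",
                       context={"age_group": ag}))
    for ag, (a, b) in {"0-1": (31, 16), "1-2": (72, 43), "2-5": (74, 17)}.items():
        add(FactorSpec("prob_raw_or_bought_food", "beta", {"alpha": float(a), "beta": float(b)},
                       "structured observation; raw produce or bought food given not breastfed",
                       context={"age_group": ag}))
    add(FactorSpec("prob_eat_with_hands", "beta", {"alpha": 254.0, "beta": 46.0},
                   "structured observation"))
    add(FactorSpec("raw_produce_serving_g", "gamma", {"shape": 2.5, "scale": 40.0},
                   "structured observation and assumption"))
    add(FactorSpec("prepared_food_serving_g", "normal", {"mu": 100.0, "sigma": 15.0},
                   "structured observation and assumption"))
    for nb, (a, b) in {"alajo": (154, 47), "bukom": (145, 57),
                       "old_fadama": (187, 14), "shiabu": (151, 49)}.items():
        add(FactorSpec("prob_sachet_water", "beta", {"alpha": float(a), "beta": float(b)},
                       "household survey; probability of drinking sachet rather than tap water",
                       context={"neighborhood": nb}))
    for ag, (mu, sg) in {"0-1": (0.371, 0.683), "1-2": (0.927, 0.642), "2-5": (1.080, 0.702)}.items():
        add(FactorSpec("tap_water_daily_cups", "lognormal", {"mu": mu, "sigma": sg},
                       "household survey, interval-censored lognormal fit",
                       context={"age_group": ag}))
    for ag, (mu, sg) in {"0-1": (0.040, 0.631), "1-2": (0.597, 0.677), "2-5": (1.060, 0.478)}.items():
        add(FactorSpec("sachet_water_daily_sachets", "lognormal", {"mu": mu, "sigma": sg},
                       "household survey, interval-censored lognormal fit",
                       context={"age_group": ag}))
    add(FactorSpec("behavior_duration_min", "weibull", {"shape": 4.48, "scale": 30.0},
                   "duration-of-behavior hazard; scale synthetic (study scales vary by "
                   "age group and neighborhood and are not published)"))
    return reg
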