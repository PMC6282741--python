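"""Microbe transfer kernel for hand--surface and hand--mouth contacts.

A single touching event moves microbes in both directions at once: each of
the ``N`` microbes on the contacted hand area detaches with probability
``p`` (hand -> surface), while each of the ``M`` microbes on the contacted
surface patch attaches with probability ``q`` (surface -> hand).  Both
counts are binomial, so the number remaining on the hand afterwards,
``k = N - n + m``, is the convolution of Binomial(N, 1-p) and
Binomial(M, q).  Repeated touching of the same closed surface drives the
expected loads to a steady state in which the hand holds the share
``q/(p+q)`` of the combined pool; because field-observed detachment far
exceeds attachment, hands stay close to the surface-dominated equilibrium
instead of accumulating contamination.  See :func:`expected_recursion`.

The kernel is exact and integer-conserving: every sampled touch moves whole
microbes and the two pools always sum to ``N + M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ContactParams",
    "ContactPool",
    "TouchResult",
    "touch_pmf",
    "sample_touch",
    "expected_recursion",
    "events_to_steady",
    "mouthing_transfer",
]

#: Above this pool size the exact convolution is refused unless the caller
#: opts into the normal approximation.
PMF_SIZE_CAP = 10_000


@dataclass(frozen=True)
class ContactParams:
    """Per-microbe transfer probabilities for one touching event.

    Parameters
    ----------
    p : float
        Detachment probability: chance that a microbe on the contacted hand
        area moves to the surface.
    q : float
        Attachment probability: chance that a microbe on the contacted
        surface patch moves to the hand.
    """

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError(f"transfer probabilities must lie in [0, 1]; got p={self.p}, q={self.q}")


@dataclass(frozen=True)
class ContactPool:
    """Microbes available to one touching event.

    ``N`` counts microbes on the contacted hand area (a portion of the total
    hand load), ``M`` counts microbes on the contacted surface patch.
    """

    N: int
    M: int

    def __post_init__(self) -> None:
        if self.N < 0 or self.M < 0:
            raise ValueError("pool counts must be non-negative integers")
        if self.N != int(self.N) or self.M != int(self.M):
            raise ValueError("pool counts must be integers")


class TouchResult(NamedTuple):
    """Outcome of one sampled touch. ``hand_after + surface_after == N + M``."""

    hand_after: int
    surface_after: int
    n_detached: int
    m_attached: int


def touch_pmf(pool: ContactPool, params: ContactParams, *, allow_normal_approx: bool = False) -> np.ndarray:
    """Exact distribution of the hand count after one touching event.

    Returns the probability vector over ``k = 0 .. N + M`` where ``k`` is the
    number of microbes on the contacted hand area after the simultaneous
    detachment/attachment event.  The result is the convolution of
    ``Binomial(N, 1-p)`` (microbes that stay on the hand) with
    ``Binomial(M, q)`` (microbes newly attached).

    For pools larger than :data:`PMF_SIZE_CAP` the exact convolution is
    replaced, on request, by a discretised normal with the exact mean
    ``N(1-p) + Mq`` and variance ``Np(1-p) + Mq(1-q)``.
    """
    N, M = pool.N, pool.M
    if N + M > PMF_SIZE_CAP:
        if not allow_normal_approx:
            raise ValueError(
                f"pool size N+M={N + M} exceeds the exact-pmf cap {PMF_SIZE_CAP}; "
                "pass allow_normal_approx=True to use the moment-matched normal"
            )
        k = np.arange(N + M + 1)
        mean = N * (1.0 - params.p) + M * params.q
        var = N * params.p * (1.0 - params.p) + M * params.q * (1.0 - params.q)
        sd = math.sqrt(max(var, 1e-300))
        upper = stats.norm.cdf(k + 0.5, mean, sd)
        lower = stats.norm.cdf(k - 0.5, mean, sd)
        pmf = upper - lower
        return pmf / pmf.sum()
    stay = stats.binom.pmf(np.arange(N + 1), N, 1.0 - params.p)
    gain = stats.binom.pmf(np.arange(M + 1), M, params.q)
    return np.convolve(stay, gain)


def sample_touch(pool: ContactPool, params: ContactParams, rng: np.random.Generator) -> TouchResult:
    """Sample one touching event; microbes are conserved exactly.

    ``n ~ Binomial(N, p)`` detach from the hand, ``m ~ Binomial(M, q)``
    attach from the surface, independently.  The hand keeps ``N - n + m``
    and the surface keeps ``M - m + n``.
    """
    n = int(rng.binomial(pool.N, params.p)) if pool.N else 0
    m = int(rng.binomial(pool.M, params.q)) if pool.M else 0
    return TouchResult(pool.N - n + m, pool.M - m + n, n, m)


def expected_recursion(
    s0: float, h0: float, params: ContactParams, steps: int
) -> tuple[float, float]:
    """Expected surface/hand loads after ``steps`` touches of the same surface.

    One touch moves the expected fraction ``p`` of the hand pool to the
    surface (detachment) and the fraction ``q`` of the surface pool to the
    hand (attachment)::

        S' = (1 - q) S + p H
        H' = q S + (1 - p) H

    so the one-step hand expectation equals the :func:`touch_pmf` mean
    ``H(1-p) + Sq``.  Totals are conserved; the fixed point satisfies
    ``H*/(S* + H*) = q/(p + q)`` and the deviation from it contracts by
    ``|1 - (p + q)|`` per step (the second eigenvalue of the update).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    s, h = float(s0), float(h0)
    for _ in range(steps):
        s, h = (1.0 - params.q) * s + params.p * h, params.q * s + (1.0 - params.p) * h
    return s, h


def events_to_steady(
    params: ContactParams,
    tol: float,
    *,
    s0: float = 1.0,
    h0: float = 0.0,
    max_events: int = 100_000,
) -> int:
    """Touching events needed for the expected hand load to settle.

    Starting from clean hands (``h0 = 0``) and a loaded surface, iterate the
    expectation recursion and return the smallest event count ``n`` with
    ``|H_n - H*| / H* <= tol`` where ``H* = q/(p+q) * (S0 + H0)``.  The
    deviation contracts geometrically by ``|1 - (p + q)|`` per event, so at
    ``p + q = 1`` a single event reaches the steady state exactly.
    """
    if not (0.0 < tol < 1.0):
        raise ValueError("tol must be in (0, 1)")
    if params.p + params.q <= 0.0:
        raise ValueError("p + q = 0: loads never change, steady state unreachable")
    if s0 + h0 <= 0:
        raise ValueError("need a positive total load")
    total = float(s0) + float(h0)
    h_star = params.q / (params.p + params.q) * total
    if h_star == 0.0:
        # q = 0: the hand equilibrium is empty; clean hands are already there.
        return 1
    s, h = float(s0), float(h0)
    for n in range(1, max_events + 1):
        s, h = (1.0 - params.q) * s + params.p * h, params.q * s + (1.0 - params.p) * h
        if abs(h - h_star) <= tol * h_star:
            return n
    raise RuntimeError(f"no convergence within {max_events} events (p+q={params.p + params.q})")


def mouthing_transfer(
    hand: Mapping[str, int],
    fraction_in_mouth: float,
    removal_fraction: float,
    rng: np.random.Generator,
) -> tuple[dict[str, int], dict[str, int]]:
    """One hand-to-mouth contact: only detachment from the hand occurs.

    For every origin source the microbes exposed to the mouth are a binomial
    thinning with the fraction of the hand surface mouthed, and of those a
    binomial fraction is removed and ingested.  Returns
    ``(ingested_by_source, hand_remaining_by_source)``; the remainder is
    assumed to redistribute uniformly over the hand surface, so no spatial
    bookkeeping is needed.
    """
    if not (0.0 <= fraction_in_mouth <= 1.0 and 0.0 <= removal_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    ingested: dict[str, int] = {}
    remaining: dict[str, int] = {}
    for source, count in hand.items():
        count = int(count)
        if count < 0:
            raise ValueError(f"negative hand load for source {source!r}")
        exposed = int(rng.binomial(count, fraction_in_mouth)) if count else 0
        eaten = int(rng.binomial(exposed, removal_fraction)) if exposed else 0
        if eaten:
            ingested[source] = eaten
        remaining[source] = count - eaten
    return ingested, remaining
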