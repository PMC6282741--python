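"""Poisson-gamma mixture model for overdispersed fecal-indicator counts.

Environmental samples (water, soil, surface swabs, food) are plated in
replicate after dilution; each replicate yields a colony count ``k_i`` for
an equivalent amount ``V_i`` of the original sample (mL, g or cm^2).  Counts
from one sample share a latent concentration ``c`` and are Poisson with
means ``c * V_i``; across samples the concentration varies as a gamma with
shape ``rho`` and scale ``lam`` (mean ``rho * lam``), giving the familiar
negative-binomial overdispersion of environmental counts.

The marginal likelihood of one sample has the closed form

    Gamma(rho + K) / (Gamma(rho) * lam**rho)
        * (1/lam + sum(V))**-(rho + K) * prod(V_i**k_i / k_i!)

with ``K = sum(k_i)``.  A quadrature evaluation of the same integral is
provided as an independent cross-check.

:func:`fit_hierarchical` fits the two-level model in which ``log rho``
varies by sample type and ``log lam`` by location, each with a normal
population distribution, using an affine-invariant ensemble MCMC sampler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special

import emcee

__all__ = [
    "ReplicateSample",
    "GammaConcentration",
    "HyperPriors",
    "HierarchicalPosterior",
    "replicate_loglik",
    "marginal_loglik",
    "fit_hierarchical",
    "draw_concentration",
    "read_counts_csv",
    "write_counts_csv",
]


@dataclass(frozen=True)
class ReplicateSample:
    """Replicate dilution counts from one environmental sample.

    ``equiv_amounts`` holds the equivalent volume (mL), mass (g) or surface
    area (cm^2) of original sample represented by each plated replicate;
    any buffer-suspension dilution factor is already folded in by the
    reader.
    """

    counts: tuple[int, ...]
    equiv_amounts: tuple[float, ...]
    sample_type: str
    location: str
    unit: str = "mL"
    sample_id: str = ""

    def __post_init__(self) -> None:
        counts = tuple(int(k) for k in self.counts)
        amounts = tuple(float(v) for v in self.equiv_amounts)
        if len(counts) != len(amounts) or len(counts) < 1:
            raise ValueError("counts and equiv_amounts must have equal, positive length")
        if any(k < 0 for k in counts):
            raise ValueError("counts must be non-negative integers")
        if any(np.asarray(self.counts, dtype=float) % 1 != 0):
            raise ValueError("counts must be integers")
        if any(v <= 0 for v in amounts):
            raise ValueError("equivalent amounts must be positive")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "equiv_amounts", amounts)


@dataclass(frozen=True)
class GammaConcentration:
    """Gamma concentration distribution: shape ``rho``, scale ``lam``, mean ``rho*lam``."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError("shape must be positive and finite")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError("scale must be positive and finite")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def replicate_loglik(sample: ReplicateSample, c: float) -> float:
    """Poisson log likelihood of one sample's replicate counts at concentration ``c``.

    ``sum_i [k_i log(c V_i) - c V_i - log(k_i!)]``; at ``c = 0`` the value is
    0 when every count is zero and ``-inf`` otherwise.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    k = np.asarray(sample.counts, dtype=float)
    v = np.asarray(sample.equiv_amounts, dtype=float)
    if c == 0.0:
        return 0.0 if k.sum() == 0 else -math.inf
    return float(np.sum(k * np.log(c * v) - c * v - special.gammaln(k + 1.0)))


def _sample_stats(sample: ReplicateSample) -> tuple[float, float, float]:
    """(K, sum V, sum[k_i log V_i - log k_i!]) for the closed-form marginal."""
    k = np.asarray(sample.counts, dtype=float)
    v = np.asarray(sample.equiv_amounts, dtype=float)
    return float(k.sum()), float(v.sum()), float(np.sum(k * np.log(v) - special.gammaln(k + 1.0)))


def marginal_loglik(sample: ReplicateSample, g: GammaConcentration, *, method: str = "analytic") -> float:
    """Log marginal likelihood of one sample under the gamma mixing distribution.

    ``method="analytic"`` uses the gamma-Poisson closed form;
    ``method="quadrature"`` integrates the Poisson likelihood against the
    gamma density numerically and exists as an independent cross-check of
    the algebra.  Across samples, log marginals add.
    """
    rho, lam = g.shape, g.scale
    if method == "analytic":
        K, sum_v, const = _sample_stats(sample)
        ll = (
            special.gammaln(rho + K)
            - special.gammaln(rho)
            - rho * math.log(lam)
            - (rho + K) * math.log(1.0 / lam + sum_v)
            + const
        )
        ll = float(ll)
    elif method == "quadrature":
        K, sum_v, _ = _sample_stats(sample)
        # the integrand is a gamma-shaped peak at mode with posterior rate
        # 1/lam + sum V; integrate a generous finite window around it so the
        # adaptive rule cannot miss a narrow peak on an infinite interval
        rate = 1.0 / lam + sum_v
        mode = max(rho + K - 1.0, 0.5) / rate
        sd = math.sqrt(rho + K) / rate
        lo, hi = max(0.0, mode - 60.0 * sd), mode + 60.0 * sd

        def log_integrand(c: float) -> float:
            if c <= 0:
                return -math.inf
            return (
                (rho - 1.0) * math.log(c)
                - c / lam
                - special.gammaln(rho)
                - rho * math.log(lam)
                + replicate_loglik(sample, c)
            )

        shift = log_integrand(mode)
        if not math.isfinite(shift):
            shift = 0.0
        val, _err = integrate.quad(
            lambda c: math.exp(log_integrand(c) - shift), lo, hi,
            limit=500, points=[mode],
        )
        ll = math.log(val) + shift
    else:
        raise ValueError("method must be 'analytic' or 'quadrature'")
    if not math.isfinite(ll):
        raise FloatingPointError(
            f"non-finite marginal log likelihood (sample {sample.sample_id!r}, rho={rho}, lam={lam})"
        )
    return ll


def draw_concentration(g: GammaConcentration, rng: np.random.Generator) -> float:
    """One gamma concentration variate (mean ``rho * lam``)."""
    return float(rng.gamma(g.shape, g.scale))


# ---------------------------------------------------------------------------
# hierarchical fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperPriors:
    """Weakly informative priors for the hierarchical model.

    ``log rho`` (per sample type) and ``log lam`` (per location) get normal
    population distributions whose means are given normal priors and whose
    SDs get half-normal priors.
    """

    mu_log_rho_loc: float = 0.0
    mu_log_rho_sd: float = 10.0
    sigma_log_rho_scale: float = 2.0
    mu_log_lam_loc: float = 0.0
    mu_log_lam_sd: float = 10.0
    sigma_log_lam_scale: float = 2.0


@dataclass
class HierarchicalPosterior:
    """Posterior draws from :func:`fit_hierarchical`.

    ``draws`` holds one row per retained draw with columns ``rho[<type>]``,
    ``lam[<location>]`` and the four hyperparameters; ``rhat`` is the
    split-chain potential-scale-reduction diagnostic per column.
    """

    draws: pd.DataFrame
    rhat: pd.Series
    sample_types: tuple[str, ...] = ()
    locations: tuple[str, ...] = ()
    converged: bool = True

    def median(self, column: str) -> float:
        return float(self.draws[column].median())

    def rho_median(self, sample_type: str) -> float:
        return self.median(f"rho[{sample_type}]")

    def lam_median(self, location: str) -> float:
        return self.median(f"lam[{location}]")

    def interval(self, column: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = self.draws[column].quantile([a, 1.0 - a])
        return float(lo), float(hi)

    def to_csv(self, path) -> None:
        long = self.draws.reset_index(names="draw").melt(
            id_vars="draw", var_name="parameter", value_name="value"
        )
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HierarchicalPosterior":
        long = pd.read_csv(path)
        wide = long.pivot(index="draw", columns="parameter", values="value")
        wide.columns.name = None
        types = tuple(c[4:-1] for c in wide.columns if c.startswith("rho["))
        locs = tuple(c[4:-1] for c in wide.columns if c.startswith("lam["))
        return cls(draws=wide, rhat=pd.Series(dtype=float), sample_types=types, locations=locs)


def _split_rhat(chains: np.ndarray) -> float:
    """Classic split-chain R-hat. ``chains``: (n_chains, n_draws)."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    split = chains[:, : 2 * half].reshape(n_chains * 2, half)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def fit_hierarchical(
    samples: Sequence[ReplicateSample],
    *,
    hyperpriors: HyperPriors | None = None,
    n_walkers: int = 24,
    n_steps: int = 2000,
    burn_frac: float = 0.5,
    thin: int = 4,
    seed: int | np.random.Generator = 0,
    rhat_threshold: float = 1.2,
) -> HierarchicalPosterior:
    """Fit the hierarchical gamma-Poisson model by ensemble MCMC.

    Parameters are ``log rho`` per sample type, ``log lam`` per location and
    the four population hyperparameters; the likelihood is the product of
    closed-form sample marginals.  An affine-invariant ensemble sampler is
    run with ``n_walkers`` walkers for ``n_steps`` moves; the first
    ``burn_frac`` of each walker's chain is discarded and the rest thinned.
    A warning (never a silent success) is raised when the split-chain R-hat
    of any retained parameter exceeds ``rhat_threshold``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    hp = hyperpriors or HyperPriors()

    types = sorted({s.sample_type for s in samples})
    locs = sorted({s.location for s in samples})
    type_idx = np.array([types.index(s.sample_type) for s in samples])
    loc_idx = np.array([locs.index(s.location) for s in samples])
    K = np.array([sum(s.counts) for s in samples], dtype=float)
    sum_v = np.array([sum(s.equiv_amounts) for s in samples], dtype=float)
    const = sum(_sample_stats(s)[2] for s in samples)

    n_t, n_l = len(types), len(locs)
    ndim = n_t + n_l + 4

    def log_post(theta: np.ndarray) -> float:
        log_rho = theta[:n_t]
        log_lam = theta[n_t : n_t + n_l]
        mu_r, log_sig_r, mu_l, log_sig_l = theta[n_t + n_l :]
        if abs(log_sig_r) > 20 or abs(log_sig_l) > 20:
            return -math.inf
        if np.any(np.abs(log_rho) > 40) or np.any(np.abs(log_lam) > 40):
            return -math.inf
        sig_r, sig_l = math.exp(log_sig_r), math.exp(log_sig_l)
        rho = np.exp(log_rho)[type_idx]
        lam_log = log_lam[loc_idx]
        lam = np.exp(lam_log)
        # closed-form marginal likelihood, summed over samples
        ll = np.sum(
            special.gammaln(rho + K)
            - special.gammaln(rho)
            - rho * lam_log
            - (rho + K) * np.log(1.0 / lam + sum_v)
        ) + const
        if not np.isfinite(ll):
            return -math.inf
        # population distributions
        lp = -0.5 * np.sum(((log_rho - mu_r) / sig_r) ** 2) - n_t * math.log(sig_r)
        lp += -0.5 * np.sum(((log_lam - mu_l) / sig_l) ** 2) - n_l * math.log(sig_l)
        # hyperpriors: normal means, half-normal SDs (+ log-Jacobian of log-SD)
        lp += -0.5 * ((mu_r - hp.mu_log_rho_loc) / hp.mu_log_rho_sd) ** 2
        lp += -0.5 * ((mu_l - hp.mu_log_lam_loc) / hp.mu_log_lam_sd) ** 2
        lp += -0.5 * (sig_r / hp.sigma_log_rho_scale) ** 2 + log_sig_r
        lp += -0.5 * (sig_l / hp.sigma_log_lam_scale) ** 2 + log_sig_l
        return float(ll + lp)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # crude method-of-moments start: per-type/per-location mean concentration
    conc = K / sum_v
    start = np.empty(ndim)
    overall = max(conc.mean(), 1e-3)
    start[:n_t] = 0.0  # log rho ~ 1
    for j in range(n_l):
        m = conc[loc_idx == j].mean()
        start[n_t + j] = math.log(max(m, 1e-3))  # lam ~ mean conc when rho ~ 1
    start[n_t + n_l :] = [0.0, 0.0, math.log(max(overall, 1e-3)), 0.0]

    n_walkers = max(n_walkers, 2 * ndim + 2)
    p0 = start + 0.3 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_post)
    sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)

    burn = int(n_steps * burn_frac)
    chain = sampler.get_chain(discard=burn, thin=thin)  # (draws, walkers, ndim)

    names = (
        [f"rho[{t}]" for t in types]
        + [f"lam[{l}]" for l in locs]
        + ["mu_log_rho", "sigma_log_rho", "mu_log_lam", "sigma_log_lam"]
    )
    rhat = {}
    for d, name in enumerate(names):
        rhat[name] = _split_rhat(chain[:, :, d].T)
    flat = chain.reshape(-1, ndim)
    data = {}
    for j, t in enumerate(types):
        data[f"rho[{t}]"] = np.exp(flat[:, j])
    for j, l in enumerate(locs):
        data[f"lam[{l}]"] = np.exp(flat[:, n_t + j])
    data["mu_log_rho"] = flat[:, n_t + n_l]
    data["sigma_log_rho"] = np.exp(flat[:, n_t + n_l + 1])
    data["mu_log_lam"] = flat[:, n_t + n_l + 2]
    data["sigma_log_lam"] = np.exp(flat[:, n_t + n_l + 3])

    rhat_s = pd.Series(rhat)
    converged = bool((rhat_s <= rhat_threshold).all())
    if not converged:
        worst = rhat_s.idxmax()
        warnings.warn(
            f"MCMC may not have converged: split R-hat {rhat_s.max():.3f} for {worst!r} "
            f"exceeds {rhat_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )
    return HierarchicalPosterior(
        draws=pd.DataFrame(data),
        rhat=rhat_s,
        sample_types=tuple(types),
        locations=tuple(locs),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["sample_id", "sample_type", "location", "replicate", "count", "equiv_amount", "unit"]


def read_counts_csv(path) -> list[ReplicateSample]:
    """Read a long-format replicate-count table into samples.

    Expected columns: ``sample_id, sample_type, location, replicate, count,
    equiv_amount, unit``.  Counts must be non-negative integers and
    equivalent amounts positive; violations raise ``ValueError``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table is missing columns {missing}")
    if (df["count"] < 0).any() or (df["count"] % 1 != 0).any():
        raise ValueError("counts must be non-negative integers")
    if (df["equiv_amount"] <= 0).any():
        raise ValueError("equivalent amounts must be positive")
    out: list[ReplicateSample] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        types = grp["sample_type"].unique()
        locs = grp["location"].unique()
        units = grp["unit"].unique()
        if len(types) > 1 or len(locs) > 1 or len(units) > 1:
            raise ValueError(f"sample {sid!r} mixes sample types, locations or units")
        out.append(
            ReplicateSample(
                counts=tuple(int(k) for k in grp["count"]),
                equiv_amounts=tuple(float(v) for v in grp["equiv_amount"]),
                sample_type=str(types[0]),
                location=str(locs[0]),
                unit=str(units[0]),
                sample_id=str(sid),
            )
        )
    return out


def write_counts_csv(samples: Sequence[ReplicateSample], path) -> None:
    rows = []
    for s in samples:
        for r, (k, v) in enumerate(zip(s.counts, s.equiv_amounts), start=1):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "sample_type": s.sample_type,
                    "location": s.location,
                    "replicate": r,
                    "count": k,
                    "equiv_amount": v,
                    "unit": s.unit,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
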