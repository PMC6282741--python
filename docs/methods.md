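# Methods

This note specifies the model implemented by `fecalflow`, the values of
all shipped parameters with their provenance class, the scope of the
synthetic data generators, the numerical choices, and known limitations.

## 1. Overview

The simulator composes four submodels into one child-day of length
14 hours (840 minutes): a behavior sequence, environmental contamination,
a microbe transfer kernel, and source-to-sink accounting.  The population
of interest is children under five in dense, highly contaminated urban
neighborhoods; results are reported per age group (0–1, 1–2, 2–5 years)
and neighborhood.

## 2. Behavior: competing hazards

A state is a (behavior, compartment) pair drawn from six behaviors
(playing/sitting, sleeping, handwashing, bathing, defecating, eating) and
five compartments (dirt floor, concrete floor, off-ground, stagnant-water
area, open drain), restricted to a feasibility mask of 13 states
(`fecalflow.behavior.FEASIBLE_STATES`).

From the current state, every feasible next state *j* draws an event time
`t_j ~ Weibull(k, λ_j)` (shape `k` shared, scale `λ_j` in minutes); the
smallest draw wins, fixing both the dwell time and the next state.
Consequences of the shared shape:

- win probability: `P(j wins) = λ_j^{-k} / Σ_i λ_i^{-k}`;
- winning time: `Weibull(k, (Σ_i λ_i^{-k})^{-1/k})`.

Scales may depend on the *previous* state as well: an exact
`(prev, curr)` rate entry overrides the wildcard `("*", curr)` entry.
This second-order dependence produces sequences such as defecation →
handwashing at realistic frequency.  The shape is `k = 4.48`
(duration-of-behavior hazard; with `hazard="exponential"` the model
collapses to a first-order Markov chain).  Days start asleep and
off-ground at `t = 0`.

## 3. Environment: Poisson-gamma concentrations

A sample's replicate dilution counts `k_i` with equivalent amounts `V_i`
(mL, g, or cm² of original sample) are Poisson: `k_i ~ Poisson(c·V_i)`
with a shared latent concentration `c`.  Across samples,
`c ~ Gamma(ρ, λ)` (shape ρ, **scale** λ, mean ρλ).  The marginal
likelihood has the closed form

```
L(k | ρ, λ) = Γ(ρ+K) / (Γ(ρ) λ^ρ) · (1/λ + ΣV)^-(ρ+K) · Π V_i^{k_i}/k_i!
```

with `K = Σk_i`.  The hierarchical model lets `log ρ` vary by sample type
and `log λ` by location, each with a normal population distribution;
hyper-means get Normal(0, 10) priors and hyper-SDs half-Normal(2).

The posterior is sampled with an affine-invariant ensemble MCMC sampler
(emcee) on the joint log posterior, using the vectorized closed form.
Convergence is monitored with the split-chain R-hat; values above 1.2
raise a `RuntimeWarning` (never a silent success).  With few groups the
hyper-parameters are only prior-identified (the usual funnel) and may
trip the diagnostic while the group-level ρ and λ are well mixed.

During simulation each child-day draws one concentration per stratum from
its gamma; nine strata are consumed (soil CFU/mg, concrete floor and
off-ground surfaces CFU/cm², drain water CFU/mL, feces CFU/mg, raw
produce CFU/g, prepared food CFU/g, tap and sachet water CFU/mL).

## 4. Transfer: exact binomial attach/detach

One touch between a hand patch holding `N` microbes and a surface patch
holding `M`:

- `n ~ Binomial(N, p)` detach (hand → surface),
- `m ~ Binomial(M, q)` attach (surface → hand),

independently, leaving `N - n + m` on the hand.  The hand-count pmf is
the convolution of `Binomial(N, 1-p)` and `Binomial(M, q)`; sampled
touches conserve `N + M` exactly.  Expected loads follow

```
S' = (1-q) S + p H
H' =  q  S + (1-p) H
```

whose fixed point puts the share `q/(p+q)` on the hand, with the
deviation contracting by `|1-(p+q)|` per touch
(`events_to_steady` reports the touch count to reach a tolerance).
Because observed detachment (p ≈ 0.75) far exceeds attachment
(q ≈ 0.02), hands equilibrate within a few touches and do not accumulate
contamination.  Hand-to-mouth contacts are detach-only: a binomial
thinning by the fraction of hand surface mouthed, then by a removal
fraction, applied per origin source.

The contacted hand patch is drawn from the total load by multivariate
hypergeometric sampling (microbes assumed uniformly distributed over the
hands after each event).

## 5. The day engine

Each state occupancy activates exposure modules
(`fecalflow.engine.dispatch`):

| state | modules |
| --- | --- |
| playing on a surface | fomite touches + hand mouthing, interleaved in time |
| playing at drain / stagnant water | attach-only water contact |
| sleeping | hand mouthing only |
| handwashing / bathing | binomial removal of hand microbes |
| defecating | rare own-feces contact; (ages 2–5) nearby fomite touches |
| eating | breastfeeding / raw produce / prepared food + drinking |

Contact and mouthing events are Poisson in time within a segment.  A
fomite touch samples a contact area, converts the surface concentration
to a per-area count (`Poisson(c·area)`, via soil adherence mg/cm² on dirt
floors), and applies the kernel of §4.  Drain contact attaches
`Poisson(c · film · area)` microbes through an adhering water film.
Washing and bathing remove a binomial fraction `1 - f(d, soap)` where
`log10 f = b0 + b1·ln(d)` with soap-specific coefficients (see §8).
Eating handles three food routes: breast milk (assumed clean), raw
produce (contaminated skin is handled and discarded; hand contact can
recontaminate the clean inner part), and prepared food (its intrinsic
load is ingested directly; eating by hand moves hand microbes onto the
food first).  The day's tap or sachet water volume is split evenly across
meals and ingested directly.

Modeling assumptions: the child starts the day asleep off-ground; no
microbial die-off within the day; microbes redistribute uniformly over
the hands; inner produce flesh and breast milk are clean; no mouthing
during defecation; only mouthing during sleep.

**Accounting.**  Every transferred microbe keeps its origin label.  Per
source, the ledger verifies exactly:

```
emitted = ingested_direct + ingested_indirect + washed + bathed
        + returned_surface + discarded_food + hand_end
```

"Direct" ingestion never resided on the hands (drinking water, the
intrinsic load of prepared food).  Transfers whose Poisson mean exceeds
`event_cap` (default 10⁹) are capped and the day flagged `overflow`;
attachments are additionally clamped so the hand load never exceeds 10⁸
(`HAND_POOL_CAP`), keeping the exact hypergeometric allocator inside
numpy's integer range.  Both caps preserve exact conservation.

**Seeding.**  Child *i* uses the stream
`default_rng(SeedSequence(root_seed, spawn_key=(i,)))`, so populations
are reproducible and order-invariant.

## 6. Survey estimators

- Binary behavior attributes (soap use, food choices): conjugate update
  of a uniform prior, `Beta(y+1, n-y+1)` from `y` successes in `n`
  trials.
- Daily water intake reported as whole cups/sachets: interval-censored
  lognormal maximum likelihood, maximizing
  `Σ log[Φ((ln U_i - μ)/σ) - Φ((ln L_i - μ)/σ)]` by Nelder–Mead in
  `(μ, log σ)`; the top category is open-ended.  All-identical intervals
  drive σ to the boundary 0 and are reported with a warning.

## 7. Outputs

`summarize` reports per-pathway daily ingestion (log10 quantiles over
exposed days, with the exposed fraction separate; zero days are NaN,
never −∞) and the dominant pathway per day.  `fraction_direct` gives the
share of ingestion that never touched the hands, per day or per
365-day child-year.  `hand_rinse_crosssection` reads the hand-load time
series at one uniform-random time per child, optionally censored at an
upper detection limit (default 10⁵ CFU), mimicking a membrane-filtration
field survey.  `export_network` writes the time-binned source-to-sink
edge list (CSV, optional GraphML).

## 8. Parameters and provenance

Factors live in `fecalflow.factors.default_registry()`; each entry
carries a provenance note.  Provenance classes:

- **published** — taken from exposure-factor literature, national survey
  statistics, or structured observation / household survey estimates:
  hand contact area LogN(2.75, 0.75) cm²; fraction of hand mouthed
  Beta(3.7, 25); attachment Tri(0.01, 0.02, 0.03); detachment
  Tri(0.5, 0.75, 0.95); wash removal coefficients (soap 2.18/−1.18,
  no soap 0.68/−0.80); mouthing removal Tri(0.01, 0.33, 0.40); soap-use
  probabilities Beta(5, 17) washing, Beta(45, 19) bathing; soil adherence
  LogN(0.11, 2.0) mg/cm²; water film LogN(5.4, 0.5) µL/cm²; surface
  contacts Weibull(1.85, 145)/h; mouthing Weibull(0.91, 18.79)/h indoor,
  Weibull(0.98, 13.76)/h outdoor; own-feces touch Beta(5, 41); defecation
  surface-contact Beta(24, 18) with Uniform(1, 10)/h frequency;
  breastfeeding, food-choice, eat-with-hands and sachet-choice Betas by
  age group / neighborhood; daily water intake lognormals by age group
  (fitted from interval-censored reports); exclusive-breastfeeding
  constants 0.339 / 0.007 / 0; cup 237 mL, sachet 500 mL.
- **assumption** — wash duration Gamma(2.5, 10)+10 s, bath duration
  Gamma(4, 60)+60 s, serving sizes (raw Gamma(2.5, 40) g; prepared
  Normal(100, 15) g, redrawn positive).
- **synthetic** — never published for the emulated study and invented
  here: all behavioral transition scales
  (`fecalflow.synthetic.default_transition_rates`), all default
  concentration strata (`default_concentrations`), and the total
  two-hand area (420 cm²).

The wash-removal model `fraction = 10^(b0 + b1·log d)` uses a *natural*
inner log: with base-10 the with-soap fraction would exceed 1 for any
wash shorter than ~70 s, which is unusable as a remaining fraction.
`log_base="10"` is available for sensitivity analysis.

## 9. Synthetic data generators

`fecalflow.synthetic` stands in for undistributable field microdata:

- `gen_count_table` — replicate dilution counts from known gamma strata,
  in the reader's CSV layout (used to validate the hierarchical fit
  against ground truth);
- `gen_survey` — Bernoulli behavior responses and interval-censored
  cup-count intake reports from a known lognormal;
- `default_transition_rates` — behavior scales chosen to yield a
  plausible day (≈9 h play — only a few percent of it at the drain or
  stagnant water — a nap, ≈3–4 meals, ≈1–2 defecations, hygiene events
  strongly boosted right after defecation);
- `default_concentrations` — gamma strata respecting the reported
  ordering (drains, feces and street food heavily contaminated; piped
  and sachet water relatively clean).

The generators fix *study conditions*; they are not tuned to any output.

## 10. Numerical choices

- Exact touch pmf by convolution up to pool size 10⁴; beyond that an
  opt-in moment-matched discretized normal.
- The quadrature cross-check of the closed-form marginal integrates a
  finite window (mode ± 60 approximate posterior SDs, with the mode as a
  quadrature breakpoint) so narrow high-count peaks cannot be missed.
- MCMC: ≥ 2·dim+2 walkers, default 2000 steps, first half discarded,
  thinned by 4; split-chain R-hat per retained parameter.
- Integer microbe arithmetic throughout the engine; allocations across
  origin sources use multivariate hypergeometric draws, so conservation
  is exact, not approximate.
- A simulated child-day costs ≈50 ms; 1,000 days ≈1 minute.

## 11. Limitations

- Transition rates and concentration magnitudes are synthetic; absolute
  exposure levels from the default configuration are illustrative, not
  field estimates.  Pathway *structure* (frequent-low soil/food versus
  rare-high drain/feces) is the meaningful output.
- No within-day die-off, growth, or re-suspension; surfaces are infinite
  reservoirs except through the day's drawn concentration.
- Hands are one pool (no left/right or finger-level structure); the
  contacted-patch assumption is uniform redistribution.
- The hierarchical model shares the gamma scale across sample types
  within a location; strata violating that structure are mis-specified
  by construction.
- Caps (`event_cap`, `HAND_POOL_CAP`) saturate astronomically large
  transfers; affected days are flagged `overflow` and should be excluded
  from dose summaries.
- One day is simulated at a time; multi-day carry-over reduces to the
  end-of-day hand load, which is reported but not fed into the next day.
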