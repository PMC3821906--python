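# Methods

## The kinetic model

`rtkinetics` describes a tumor as an exponentially growing cell population
split into cycling (`Np`) and quiescent (`Nq`) compartments, with optional
radioresistant counterparts (`Nrp`, `Nrq`) and a three-stage pipeline
(`Nd1`–`Nd3`) holding cells committed to death by irradiation.  Measured
volume is proportional to the total over all seven compartments
(10⁹ cells ≙ 1 cm³; the constant only sets the scale and cancels from every
fitted quantity except V0).

Growth is parameterized by four observables:

| parameter | meaning | units | typical NSCLC value |
|---|---|---|---|
| Td | volume doubling time | days | ~100 (15–1000 fitted range) |
| GF | growth fraction (share of cycling cells) | – | ~0.2 |
| Tc | cell-cycle duration (equivalently T_pot) | days | 2–3 (T_pot ~8) |
| γ | quiescent → cycling re-entry rate | /day | 0–0.01 |

Dependent rates follow from the age-structured theory of exponentially
growing populations: with E = e^(ln2·Tc/Td) and λ = ln2/Td,

- cycle-exit rate u = ln2 / (Td·(E − 1)),
- potential doubling time T_pot = Td·(E − 1)/GF,
- quiescent loss rate μ_q = ln2·(1/T_pot − 1/Td)/(1 − GF) (0 when GF = 1),
- newborn re-cycling fraction θ = E/2 + γ·(E/2 − 1)/(λ + μ_q).

The θ expression is the unique value solving the exponential-balance
equations; it is algebraically identical to θ = E/2 − γ(1 − GF)/(2·u·GF).
As a consequence two invariants hold *exactly* in the discrete scheme
below: N(t) = N(0)·2^(t/Td) for untreated growth, and Np/(Np+Nq) = GF at
every step when compartments start at their stationary proportions.

### Discrete stepping

State advances in Δt = 1-day steps (configurable).  The effective step
length Δt′ = (e^(λΔt) − 1)/λ links the discrete update to the continuous
model, which is what makes untreated growth exact rather than first-order
accurate.  The explicit step has a stability domain: parameter
combinations with (γ + μ_q)·Δt′ > 1 would drain more than the whole
quiescent pool in one step and are rejected as invalid (the fitted domain,
GF ≤ 0.6 and T_pot ≥ 3 d, lies well inside).

Killed cells advance through the three dying stages with daily probability
D, so time-to-loss is a sum of three geometric waits with mean 3/D days
(4 d at D = 0.75, 6 d at D = 0.5, 15 d at D = 0.2).  Dynamics are
deterministic expected values; counts are continuous and nonnegative.

## Treatment-efficacy variants

At each fraction (applied instantaneously between the pre- and post-
fraction states of its day; sampled volumes are pre-fraction, like CTs
taken before treatment):

- **M (minimal)**: K% of all live sensitive cells are killed.  Uniform
  kill makes the cycling/quiescent split irrelevant to the volume path, so
  the M family runs on a single-population kernel (GF = 1, Tc = Td).
- **St (standard)**: separate kill of cycling (Kp%) and quiescent (Kq%)
  cells.
- **Rec (recruitment)**: inside a window after treatment start the
  re-entry rate γ is replaced by γ_rec > 0.01/day (accelerated
  repopulation).  Windows follow the patterns seen per patient (days 1–3,
  days 1–13, from the 3rd or 4th week); during a fit the window is scanned
  over that grid because no selection rule was ever published.  θ and μ_q
  keep their pretreatment values — recruitment changes the transfer flux,
  not the population's intrinsic kinetics.  The window is anchored at the
  first fraction day.
- **Res (resistance)**: either a fraction Rini of cells is resistant from
  the start, or a fraction Rind of surviving sensitive cells converts at
  each fraction.  Resistant cells grow like sensitive ones and are never
  killed; the two variants are expected to be nearly indistinguishable
  from volume data alone, so both are reported when relevant.
  Combined Rec+Res variants are constructible but not part of the default
  ladder.

## Likelihood and fitting

Errors are Gaussian on log volumes.  The noise scale σ is profiled out in
closed form (σ̂ = RMS log-residual), leaving the objective
n/2·(log 2πσ̂² + 1).  Censored points (at or below the CT detection limit)
enter as exact observations at the limit — the conservative convention —
by default; a normal-CDF censored likelihood (σ then a free parameter) is
available but off by default.

Fits are constrained within literature ranges (Td 15–1000 d, GF ≤ 0.6,
T_pot 3–30 d, kill 0–99.9%, D 0.05–1) and run on a unit box with log₁₀
axes for scale parameters, using L-BFGS-B from a heuristic start, the box
midpoint, and a seeded Latin-hypercube multistart (default 20 starts).  γ
is fixed at 0 by default (freeing it is a config choice).  Without a
pretreatment scan Td is not estimable: the fit is repeated at Td = 25 and
150 days and both results are returned.

95% intervals per parameter are profile-likelihood based: the parameter is
pushed outward with all others re-optimized (warm-started) until the
profile log-likelihood drops by χ²₍₀.₀₅,₁₎/2 ≈ 1.921, with the crossing
bisected to 5·10⁻⁴ of the parameter's unit range.  Endpoints at bounds are
truncated and flagged; a flat likelihood yields the whole allowed range,
flagged on both sides.

### Model selection

A parsimony ladder, all tests at α = 0.05 (the interval construction uses
the same χ² quantile): fit M, then St, adopting St only if the
likelihood-ratio test (df = difference in free-parameter counts; σ is
profiled in both models and never counted) is significant; then offer
recruitment (StRec over the window grid — the M family has no quiescent
pool to recruit) and both resistance variants of the adopted family,
adopting the best significant extension.  Candidates within χ²₍₀.₀₅,₁₎/2
log-likelihood units of the winner are reported as alternates ("not
significantly worse").

A calibration note: on minimal-model data the St extension's growth
parameters (GF, T_pot) are unidentified as long as Kp = Kq, so the
2·ΔlogL statistic is stochastically smaller than its nominal χ²₃
reference and the ladder's first rung is conservative — it over-adopts
St at well below the nominal 5% rate.  The acceptance test asserts control
(rate ≤ nominal + 3 binomial SE), not equality.

### Goodness of fit

Δ% = mean over observations of 100·|V_obs − V_fit|/V_obs (the denominator
convention is a package choice; with 5% lognormal noise and a correct
model its expectation is ≈ 100·cv·√(2/π) ≈ 4%).

## Response typing

Fitted patients land on a 2×2 grid: kill (K or Kp, interchangeably) is
"high" at ≥ 5% per fraction under conventional fractionation (group L) or
≥ 35% under hypofractionation (group S, courses finishing in under 14
days); dying is "fast" at D ≥ 0.5/day.  A = high/slow, B = high/fast,
C = low/slow (including a non-detectable dying rate), D = low/fast.
Comparisons are inclusive.  When alternates exist, the higher-likelihood
fit drives classification.

## Synthetic data: what it emulates, what it does not

The generator produces: exponential pretreatment growth; weekday
1.8–2.5 Gy calendars over 6–10 weeks (L) or five 10 Gy fractions inside
two weeks (S); a planning scan (default 14 days before treatment);
pre-fraction daily volumes; follow-ups about one and two months after the
course (short courses add an early ~2-week post-treatment diagnostic: with
only five treatment-day CTs the richer models would otherwise have as many
free parameters as observations); median-one multiplicative lognormal noise (default CV 0.07, the
middle of the 5–10% measurement-error range — median-one so log errors
are exactly the Gaussian the likelihood assumes, with the empirical CV
equal to the nominal one); and a CT detection limit (default 0.1 cc — no
published value exists; configurable) below which values are recorded at
the limit and flagged censored.

It does **not** emulate atelectasis, fibrosis or inflammation artifacts,
contouring variability, chemotherapy effects, or growth retardation at
large volumes — so passing recovery tests demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
those real-data failure modes.

The archetype battery holds seven scenarios (types A–C for group L, A–D
for group S) parameterized from the reference cohort's best fits.  Two
practical notes from validation:

- With ~8–9 observations per hypofractionated course at 7% noise, the
  St-vs-M test is underpowered (df = 3 at n ≈ 9), so a single replicate of
  a group-S type-A scenario is often classified from an M fit with
  moderate kill — i.e. mistyped as C.  End-to-end type recovery is
  therefore asserted in the small-noise regime, where ladder consistency
  is the provable property; the noisy regime is covered by distributional
  tests (coverage, calibration) instead of per-replicate claims.
- A trajectory that crosses the detection limit yields censored,
  deliberately biased points; recovery oracles use scenarios whose
  trajectories stay above the limit.

## Numerical choices and problem sizes

Unit tests run with 3-start fits; statistical acceptance checks use 200
replicates for interval coverage and 150 for LRT calibration on
single-patient series of 20–35 observations.  The acceptance script
reports the same quantities at 60/50 replicates.  Bisection tolerance for
profile endpoints is 5·10⁻⁴ of the unit range; optimizer ftol 10⁻¹²;
infeasible parameter regions (T_pot > Td, unstable steps, negative
compartments) return a large penalty to the optimizer rather than an
exception.

## Known limitations

- Expected-value dynamics: no stochastic birth–death variability, no
  spatial or vascular structure, no phase-specific radiosensitivity, no
  dose-dependence of the kill fraction (each fraction's kill is a free
  per-patient constant).
- Single-patient fits only; no mixed-effects pooling across patients.
- Profile re-optimizations are single-start warm-started local searches;
  on multimodal likelihoods an interval endpoint can land on a local
  branch.
- The ladder's significance level and the recruitment-window grid are
  configuration, not estimates; results for recruitment models depend on
  the grid supplied.
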