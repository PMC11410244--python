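# Methods

## Model

A spatially structured population is a strongly connected directed graph
of D well-mixed demes. Two types compete: wild-types with exponential
growth rate 1 and mutants with rate 1 + s. One bottleneck-to-bottleneck
step has two phases.

**Growth.** Every deme grows deterministically for a fixed time t:
W′ᵢ = Wᵢ·eᵗ, M′ᵢ = Mᵢ·e^{(1+s)t}. The within-deme mutant fraction
follows x′ = x·e^{st}/(1 + x(e^{st} − 1)), so the fraction dynamics
depend on s and t only through the *effective fitness advantage* st.
Sizes, however, depend on t separately (they set binomial trial counts
and per-cycle division numbers), which is why the API accepts s and t
individually; the default growth time is t = ln 100, the value implied
by a daily 100-fold regrowth.

**Dilution and migration.** Serial passage is modelled as independent
binomial samplings: the number of mutants sent from deme i to deme j is
Binomial(round(N′ᵢ), m_ij·x′ᵢ·B/N′ᵢ), and analogously for wild-types
with 1 − x′ᵢ. Deme j's new bottleneck is the sum over sources. This is
*soft selection*: since the success probability divides by N′ᵢ, a deme's
contribution is independent of how large it grew. The expected size of
deme j after passage is B·Σᵢ m_ij (its migration-matrix column sum).
Success probabilities above 1 (m_ij·B/N′ᵢ > 1, a post-growth deme too
small for its outgoing weight) raise an error rather than being clamped:
they signal parameter misuse. Empty demes send nothing.

Fixation (no wild-types anywhere) and extinction (no mutants) are
evaluated at bottlenecks; a step cap (default 10⁶) yields an explicit
`unresolved` outcome, which downstream statistics exclude with a warning
rather than silently censor.

**Bottleneck conventions.** Migration matrices are normalised in one of
two declared ways: `receive_B` (every column sums to 1; each deme
receives B on average) or `contribute_B` (every row sums to 1; each deme
contributes B on average). The clique is doubly stochastic and satisfies
both. The star satisfies only one at a time; its diagonal is stored
explicitly as the residual of the declared convention, and validation
errors name the offending deme. A matrix read from TSV must come with a
declared convention (sidecar file or argument), which is verified, never
inferred. Connectivity is checked on the off-diagonal support; a
zero-migration multi-deme graph is rejected because absorption would
then be per-deme.

A graph is a *circulation* when every row and column sum equals 1; there
migration conserves the expected overall mutant fraction, and the
fixation probability matches the well-mixed population of size DB
(clique for any feasible m; star exactly when α = 1).

## Key parameters

| parameter | meaning | typical values here |
|---|---|---|
| D | number of demes | 4 (growth scenarios), 5 (suppression scenarios) |
| B | mean deme bottleneck size (individuals) | 100 (proposed experiments), 10⁵–10⁷ (past experiments) |
| s, t, st | relative advantage, growth time, effective advantage | st = 0.01 (suppression regime), st = 0.2·ln 100 ≈ 0.921 (resistance-mutant regime) |
| m, m_I, m_O, α | clique migration; star leaf→center, center→leaf, asymmetry m_I/m_O | m_I = 0.05, α = 1/10 ⇒ m_O = 0.5; matched clique m = (m_I+m_O)/D |
| max_steps | bottleneck cap per trajectory | 10⁶ |

## Deterministic recurrence

Neglecting fluctuations, per-deme fractions evolve as
x_{i,n+1} = Σⱼ m_ji·x′_{j,n} / Σⱼ m_ji, with x′ the growth map. The
denominator uses the stored matrix's column sums, so one expression
serves both conventions. The *overall* fraction series weights demes by
their expected bottleneck sizes (column sums; plain mean at step 0 and
under `receive_B`). The equal-weight mean was measurably wrong where the
conventions matter: under `contribute_B` with α = 3 and m_O = 0.3 the
star's expected deme sizes are (2.8, 0.4, 0.4, 0.4)·B, and size
weighting reduces the gap to the 100-replicate stochastic average from
0.018 to 0.0009.

The recurrence is valid when per-deme fraction fluctuations are
negligible: large B, large initial mutant counts, and expected migrant
numbers m·x·B well above 1. At B = 10⁵ the averaged stochastic dynamics
track it within 0.02 per step for m ∈ {0.3, 0.01}; at m = 10⁻⁵ (where
m·B = 1) seeding-time jitter produces deviations of order 0.25 — that
regime belongs to the plateau analysis below, not to the deterministic
limit.

**Plateaus.** Under rare migrations demes are invaded sequentially and
the overall fraction climbs a staircase: 0.25 for one fixed deme of
four, then (leaf start in a star) 0.5 when the center has fixed, then 1;
averaging over the four possible start demes yields an intermediate
level 0.5·3/4 + 1/4 = 0.625. `find_plateaus` reports maximal runs with
per-step changes below `flat_tol` whose level is inside
(edge_tol, 1 − edge_tol), excluding the slow approach to the absorbing
values. The defaults (flat_tol = 0.015, min_len = 3, edge_tol = 0.01)
are set by the geometry of the m = 10⁻⁵, st ≈ 0.92 regime: successive
invasions are separated by the seeding lag −ln(m)/st ≈ 12.5 steps while
one sigmoid transition is itself ≈ 12 steps wide, so intermediate levels
are flat only to ~0.01 per step. A much tighter tolerance (10⁻³) detects
only the first plateau, where the not-yet-seeded demes are still exactly
mutant-free. Measured levels at these defaults: 0.2532 (clique first
plateau) and 0.6232 (star start-average), against the idealised 0.25 and
0.625 — the small excesses are the run means including the beginning of
the next rise.

## Hard selection

The variant couples growth to a carrying capacity and dilutes by a fixed
factor d instead of targeting B: mutants sent i→j are
Binomial(round(N′ᵢ), m_ij·x′ᵢ/d). Contributions now scale with
post-growth size — fuller demes seed more offspring — which is the
operational meaning of hard selection.

Growth is logistic with a shared brake on both types,
dW/dτ = W(1 − N/K), dM/dτ = (1+s)·M(1 − N/K), with a
composition-dependent capacity K(x) = K_wt·(1 − x + x·r); r is the
post-growth density of a fully mutant deme relative to a fully wild-type
one (default 1.4, i.e. a 40% density difference, direction flippable via
`mutant_denser`). This is the simplest competitive-saturation model with
a composition-dependent final density; because the brake multiplies both
rates, the type ratio obeys d ln M / d ln W = 1 + s exactly, so the
mutant *enrichment* equals the soft-selection growth map evaluated at
the realised wild-type log-growth. Single-type demes use the logistic
closed form; mixed demes are integrated with fixed-step RK4 (t/1000 per
step; halving the step changes results by < 10⁻⁹ relative).

Consequences worth knowing:

- with K → ∞ and s = 0 and d = eᵗ, the hard and soft sampling laws
  coincide exactly; with s > 0 they must differ (that difference *is*
  hard selection);
- saturation requires t > ln d when K_wt = d·B; at t = ln d a wild-type
  deme only reaches K/2 and the "densities differ by 40%" premise is
  void — the saturated scenarios here use t = 8 (reduced scale) or
  t = 2·ln 100 (full scale);
- with r ≠ 1 the plateau levels shift because denser demes weigh more in
  the overall fraction: r/(r+3) ≈ 0.318 and 2r/(2r+2) ≈ 0.583 at
  r = 1.4, against 0.25 and 0.5 at r = 1. The *sequence* of sequential
  invasion is the same in both selection modes.

## Closed forms and experimental design

- Fixation probability of n mutants in a well-mixed bottleneck-B
  population: ρ = (1 − e^{−2n·st})/(1 − e^{−2B·st}), the diffusion
  approximation (B ≫ 1, |st| ≪ 1), with the continuous extension n/B at
  st = 0. At B = 20 its own error is ~1% (bottleneck-size fluctuations
  inflate the sampling variance by ≈ E[B/T] ≈ 1 + 1/B, T the realised
  bottleneck size), which is visible against Monte-Carlo bands tighter
  than that; at B = 500 the formula and simulation agree within three
  binomial standard errors at 10⁵ replicates.
- Competitive advantage from head-to-head growth:
  log(M₁/M₀)/log(W₁/W₀) = 1 + s.
- Wilson score interval for a fixation proportion (z the two-sided
  normal quantile), preferred over Wald for proportions near 0 or 1;
  bounds are clipped to [0, 1] against float round-off at the endpoints.
- Mean-time interval τ̂ ± t₍ₙ₋₁₎·σ̂/√n with σ̂ the sample standard
  deviation of per-replicate absorption times.
- Minimal replicate numbers: the smallest n at which the two arms'
  intervals are disjoint *and remain disjoint for the next 20 values of
  n* (guarding non-monotone edge cases); the search is capped at 10⁶ and
  raises beyond it. Equal proportions or equal means are rejected — no
  finite n separates them.

## Randomness and reproducibility

Ensembles are simulated in vectorised lockstep: all still-active
replicates advance one bottleneck per iteration, drawing their binomials
jointly from a single generator seeded by the caller. Results are
bit-reproducible for a fixed (seed, reps) pair; `run_trajectory` takes
its own generator for per-trajectory control. Scenario runs write the
resolved parameter set, seed and package version to a manifest, and
identical seeds give byte-identical output files.

## Problem sizes used in the checks

The simulation-backed checks use 10,000 replicates per arm for fixation
probabilities (binomial SE ≈ 0.005 at ρ = 0.38), which also yields
≥ 5,000 fixation trajectories per arm for conditional time means (SEM
≈ 2–3 steps); 2×10⁵ replicates per initial count for the single-deme
diffusion comparison; 100 replicates for deterministic-limit tracking at
B = 10⁵; and 60–100 replicates for the reduced-scale (B = 10⁴)
plateau-sequence comparisons. Reference proportions printed to two
decimals are compared with an extra half-ulp (0.005) allowance on top of
the three-standard-error band, since the reference itself is rounded.

## What the simulations do and do not emulate

All inputs are parameter sets; the scenarios emulate batch-culture
serial-passage experiments with controlled migrations — fluctuating
bottleneck sizes and compositions, absorbing fixation/extinction, and
either soft or hard selection. They do not model de-novo mutation during
growth, cell death or antibiotic pharmacodynamics, stationary-phase
growth slowdown (t is the *equivalent* exponential growth time),
per-deme heterogeneous bottleneck targets, time-varying migration, or
deme extinctions. Passing checks therefore speak to the fidelity of the
serial-passage sampling model, not to biological effects outside it —
e.g. real experiments show faster mutant-fraction increases and stronger
fluctuations than the model, consistent with antibiotic-induced death
and imperfect dilution control.

## Known limitations

- A deme may in principle send more individuals than it contains, since
  the per-destination binomials are independent; at realistic parameters
  the probability is astronomically small, and accepting it keeps the
  sampling law exactly as specified.
- Binomial trial counts are rounded post-growth sizes; the bias is
  O(1/N′) and invisible at N′ ≥ 10³.
- The diffusion formula is used as a reference, not a ground truth: its
  small-B error exceeds tight Monte-Carlo bands (see above).
- The plateau detector is tuned for the sequential-invasion geometry; a
  series with genuine plateaus closer than ~3 steps apart, or flatter
  than 0.015 per step at levels within 0.01 of the absorbing values,
  needs non-default settings.
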