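# Methods

## The model

A population of `N` entities is fixed, well mixed and spatially
unstructured. Each entity is an abstracted autocatalytic-set holder: its
internal chemistry is deliberately not modelled; all that matters is the
*set* of discrete products (innovations) it currently holds, plus — in SIR
mode — the set of products it has recovered from. Products are
presence/absence only: they model topology changes of the underlying
reaction network, not concentrations, so there is no copy-number dynamics.

Five elementary processes, each a Poisson clock, drive the dynamics:

| process      | rate                                        | effect |
|--------------|---------------------------------------------|--------|
| stimulus     | `lambda_stim` per population                 | a uniformly chosen entity creates a new product |
| transmission | `beta` per ordered (holder, eligible non-holder) pair per product | the recipient gains the product |
| recovery     | `gamma` per (entity, held product) pair      | product lost, permanently immune (SIR) |
| degradation  | `delta` per (entity, held product) pair      | product lost, re-acquirable |
| birth–death  | `mu` per entity                              | Moran replacement (below) |

Setting `gamma = delta = mu = 0` and `p_beneficial = 1` recovers baseline
SOR exactly: an SI contact process in which every innovation percolates to
fixation and nothing is ever lost. Each nonzero rate restores one of the
processes that baseline SOR ignores.

New products draw an effect class from
`(p_beneficial, p_neutral, p_deleterious)` with fixed additive effect
sizes `+s_beneficial`, `0`, `−s_deleterious`. Fixed magnitudes (rather
than continuous effect-size distributions) keep every oracle computation
exact; continuous distributions are a deliberate extension point, not a
current feature. Entity fitness is additive with baseline 1 and floored
at zero:

    w = max(0, 1 + Σ effect sizes over held products).

The model itself never defines what fitness "is" chemically; additivity
makes cumulative change literal, and the floor prevents negative
reproduction rates. In cumulative mode each new product requires its
parent — the most recently created product — so innovations form lineages
(p → p′ → p″) and a stimulus arriving when no entity holds the lineage tip
is a logged no-op rather than a silent drop, keeping
innovation-opportunity counts auditable.

### Birth–death (Darwinian) mode

One birth–death event picks a parent with probability proportional to
fitness and a victim uniformly over all `N` entities, the parent included
(the standard Moran convention, which makes the neutral fixation
probability exactly `1/N`). The victim becomes a copy of the parent in
which each product is independently retained with probability
`1 − epsilon`. Imperfect inheritance is loss-at-birth only — there is no
spontaneous gain at copy time; gains come only from stimuli. `N` is
constant in every mode. If all entities reach fitness 0, nothing can
reproduce: the run terminates with a collapse flag rather than excluding
lethal product sets by fiat.

### Simulation algorithm

The engine is the exact Gillespie direct method: the waiting time to the
next event is exponential in the aggregate rate, the event kind is chosen
proportionally to its rate component, and one event is applied per step.
Populations here are desk-scale (N up to a few thousand), so exactness is
cheap and tau-leaping is not needed. All stochastic choices flow through
one `numpy` PCG64 generator seeded from the config, so identical config
and seed give byte-identical event logs — this is tested at the byte
level. Within an event kind, the realized instance is uniform over enabled
instances; entities are iterated in id order. The state keeps incremental
indices (per-product holder sets, recovered counts, per-entity effect
sums, the transmission pair-sum) so each event costs roughly O(1)–O(N);
a from-scratch rate recount is kept as a reference implementation and the
two are asserted equal along trajectories in the test suite.

## Oracles

Three closed forms validate the machinery end to end:

* **SI fixation time.** With one seeded product, the holder count is a
  pure-birth chain with rate `beta·k·(N−k)` at `k` holders, so
  `E[T_fix] = Σ_{k=1}^{N−1} 1/(beta·k·(N−k)) = 2·H_{N−1}/(beta·N)`.
* **Moran fixation probability.** `(1 − r⁻¹)/(1 − r⁻ᴺ)` with
  `r = 1 + s`; `1/N` when neutral. The tests additionally cross-check
  this against an independent absorbing-Markov-chain linear solve for
  N ≤ 50 to 1e-10, so the formula and the simulator are validated by two
  separate routes.
* **SIR final size.** The largest root of `z = 1 − exp(−R₀·z)`, solved by
  bracketed Brent iteration to |Δz| < 1e-10; 0 for R₀ ≤ 1. Simulated
  attack fractions are compared conditional on a major outbreak, where a
  replicate is "major" when its final size reaches at least 10% of the
  deterministic prediction — small-fizzle runs (probability ≈ 1/R₀) are
  excluded by this documented rule, since the deterministic root only
  describes the major-outbreak branch. `R₀ = beta·N/gamma` under the
  pairwise (density-dependent) contact convention used throughout.

## Regime classification

The polymorphism index of a population is the probability that two
distinct entities drawn without replacement hold *unequal product sets*
(set equality, not fitness equality — identical fitness with different
repertoires still counts as polymorphic). A sample is monomorphic when
the index is 0. The regime ratio `T_fix(N, beta) · lambda_stim` compares
fixation speed with innovation pressure; runs are classified
community-based below `ratio_low` (default 0.1), individual-based above
`ratio_high` (default 10), marginal between. The thresholds are this
package's convention — the underlying claim is only "faster on average" —
and both are config-exposed. With `lambda_stim = 0` the ratio is 0
(community-based by convention); with `beta = 0` products can never fix
and the ratio is infinite. The observed monomorphic time-fraction is
estimated from the equally spaced sample grid of the trajectory.

## Presets: what the demonstrations emulate

The presets are the package's study conditions; the values below were
chosen once, on the following reasoning, and are not tuned per run.

* `sor_baseline` — N = 50, β = 1, λ = 0.005: regime ratio ≈ 9·10⁻⁴, so
  each innovation fixes long before the next arrives; over t = 1000 about
  five innovations accrue. Demonstrates monotone mean fitness and a
  monomorphic end state.
* `regime_map` — N = 20, β = 1, ratios 0.01 and 100, horizon spanning 28
  expected innovations per replicate, 100 samples per run.
* `triple_lottery_relaxed` — (p_b, p_n, p_d) = (0.25, 0.25, 0.5) with
  equal magnitudes s = 0.1: random effects mostly non-beneficial, so the
  expected effect per innovation is −0.025; with ≈ 20 innovations over the
  horizon the expected final mean fitness is ≈ 0.5.
* `degradation_collapse` — δ = 0.2 with β = 0.02 at N = 10, i.e.
  β(N−1)/δ < 1 (subcritical). Extinction of all products is certain in
  either case (the empty state is the only absorbing state when
  λ = 0), but in the supercritical regime the expected absorption time
  grows exponentially with N and the demonstration would be invisible at
  desk scale; the preset sits where it is visible.
* `darwinian_takeover` — N = 30, β = 0.02, μ = 1, ε = 0, λ = 0.5,
  t = 60, mixed effects as above. β is set low enough that horizontal
  percolation does not swamp selection: from a single holder,
  transmission pushes at β(N−1) ≈ 0.6 per unit time while Moran turnover
  removes at ≈ 1, so deleterious products are usually purged before they
  spread, while beneficial ones are amplified. Both arms of a pair consume
  an identical pre-drawn innovation stream (times, target entities, effect
  draws); only the engine's own event randomness differs.
* `multi_sir` — N = 500, γ = 1, β = R₀γ/N with R₀ = 2, recurrent
  introductions at λ = 0.05.

Replicate seeds derive as `base_seed + replicate_index`; the paired
experiment uses disjoint offsets for the stream generator and the two
arms.

## What the generator does and does not emulate

Runs are their own data: there is no external input. The simulator
emulates well-mixed contact, memoryless event timing and additive,
independent product effects. It does **not** emulate spatial or network
structure, within-entity reaction kinetics, product copy numbers,
epistasis between products, continuous effect-size distributions, or
free-growing populations (birth and death are always simultaneous).
Passing tests therefore show that the *idealized* processes behave as
their theory predicts — they do not show that real protocell or cultural
populations sit in any particular parameter regime.

## Numerical choices and degenerate inputs

* Effect-class probabilities must sum to 1 within 1e-12; all rates must be
  non-negative; unknown config keys are rejected, each violation producing
  one named error.
* A zero total rate is an absorbing state: the run ends at the last event
  time, and an all-rates-zero configuration yields a trajectory with only
  its initial sample row.
* Trajectory samples are the right-continuous state at `0, dt, 2dt, …`
  plus a final row at the time actually reached.
* Transmission recipients are drawn by rejection sampling with a full-scan
  fallback, which is exact and fast except in the last few steps before
  fixation.
* `moran_fixation_probability` treats any `s` below float resolution
  (`1 + s == 1.0`) as neutral.
* The final-size root is bracketed on (1e-12, 1], avoiding the trivial
  root z = 0.
* Mean-fitness monotonicity checks use a 1e-12 float tolerance for
  accumulated additive sums.

## Known limitations

* The per-event cost of transmission grows with the number of concurrently
  spreading products; at regime ratios ≫ 100 or N ≫ 10³ the pure-Python
  engine becomes the bottleneck.
* Frequency-dependent (per-contact) transmission is not implemented; the
  pairwise density-dependent convention is the only contact model.
* Imperfect inheritance is product loss at birth; per-product copy *error*
  (mutated effect sizes) is out of scope.
* The collapse flag ends a run at the first all-zero-fitness event; there
  is no rescue or re-seeding mechanism afterwards.
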