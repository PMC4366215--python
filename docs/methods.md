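# Methods

## Model overview and assumptions

`warblersim` simulates one breeding season of a songbird community whose
members differ only in how they choose a breeding site, on a homogeneous
200 × 200-cell torus (1 cell ≡ 10 m, no obstacles or edges, so every
spatial process is translation-invariant).  A run has two stages: birds
settle and sprout nests; then predators forage for 6400 ticks and nests
that survive count as successes.  Predation risk is constant within a run:
predator numbers never change, nests are not re-laid, and depredation is
absorbing.  Birds and predators never interact directly — predators eat
nests, not adults — and predators do not interact with each other.

Time is scaled to red fox travel: foxes cover ~2 km per foraging day, one
cell is 10 m, so one day is 200 ticks of 1 cell each and the 32-day Wood
Warbler nest cycle is 6400 ticks.  Boars cover about half that distance
daily and are therefore active only 100 ticks per day (the first 100 of
each day; the phase is arbitrary because birds do not move in stage 2, and
it is configurable).

All movement uses one correlated-random-walk kernel: heading ← heading +
N(0°, SD²), advance one cell, wrap.  Headings are compass-style (0° = +y,
clockwise); turn draws are added unreduced so an SD of 360° really does
wind the heading through multiple turns and produces a tight convoluted
path.  The convention itself is unobservable (every process is isotropic)
but is fixed so tests are deterministic.

## Settlement

* **Cue-providers** (8): placed by rejection sampling, uniformly with
  pairwise distance ≥ 10 cells (the empirical mean nearest-neighbour
  spacing of ~100 m motivates the floor).  Settled from the start — they
  model site-faithful birds using personal information.
* **Cue-users** (36): start uniform, ≥ 10 cells from every provider, then
  prospect by CRW until a settled bird (of either social type) lies within
  10 cells; they settle on the spot and immediately become cues for later
  birds, including birds later in the same tick (agents act sequentially
  in freshly shuffled order each tick).  This cascade is what aggregates
  territories.
* **Random-settlers** (36): rejection-sampled uniformly, pairwise ≥ 10
  cells and ≥ 20 cells from every settled social bird.  The exclusion zone
  keeps the uninformed baseline from sitting inside social clusters;
  "nearest cluster" is operationalised as nearest settled social bird.
* **Nests**: one per bird, uniform on the 3-cell disc around the territory
  centre (mean nest–centre distance 2 cells, matching the ~32 m empirical
  mean).

**Bayesian updating.**  With a threshold *k* set, settled social birds that
count more than *k* other social birds within 15 cells wander (CRW,
SD 360°) until the count drops to ≤ *k*, stopping immediately; updating
re-triggers as neighbours arrive or move, and wandering birds may displace
already-settled neighbours' counts.  Two couplings are provided:

* `bayesian_adjust` (default) runs after prospecting has finished and
  counts settled birds only; it terminates when a full shuffled pass moves
  nobody.
* `prospect_with_updating` interleaves prospecting and updating within one
  tick loop and counts all social birds, settled or prospecting
  (`updating="concurrent"` in the experiment layer).

Both satisfy the same equilibrium (every bird ends with ≤ *k* neighbours
within 15 cells); the concurrent variant spreads clusters more because
transient prospectors inflate counts during formation.  Tick caps (10⁶)
and rejection caps (10⁵ draws) convert pathological configurations into
explicit errors rather than hangs; simultaneous-wander livelock is
theoretically possible but has never been observed at the default
community sizes.

## Predation

Predators destroy **every** live nest sharing their floored grid cell —
no satiation, consistent with a boar or fox being far from full after six
small eggs.  The cell is checked after each move, and each predator's
initial cell is checked once before movement begins.

* **Boar** (incidental): plain CRW, turn SD 10°, active 100 ticks/day.
* **Fox** (responsive): CRW with turn SD 10°; destroying a nest arms a
  100-tick area-restricted-search timer during which the turn SD is 55°,
  concentrating search near the find.  Every new find re-arms (not
  extends) the timer; with no finds the timer decays and the fox resumes
  straight foraging.  "Encountering a nest" means destroying a live one —
  consumed nests leave no trace to react to.

The default movement parameters (turning 10°, ARS strength 55°, duration
100) are the "efficient predator" setup: in the staged sensitivity sweeps
(`sweep_efficient_predator`, 50 replicates per point) survival rises
steeply as turning grows above 10°, is lowest for ARS strength around
40–70°, and responds to ARS duration in opposite directions for random
nests (longer ARS wastes fox time, survival rises) and clustered nests
(longer ARS exploits neighbours, survival falls).  Six predators produce
mean nest failure within the empirically observed 20–60% band
(`sweep_predator_density`).

### Execution paths

The per-agent functions (`boar_step`, `fox_step`, `run_predation_stage`)
are the readable reference semantics: predators step in freshly shuffled
order each tick.  The experiment layer uses `run_predation_batch`, which
vectorises the identical process across replicates: because a strike
removes all nests in a cell at once, a boolean per-cell occupancy grid is
an exact sufficient state, and the only semantic difference is that
within-tick kills are simultaneous rather than ordered — observable only
when two predators hit the same live-nest cell in the same tick, which is
negligible and tested for distributional agreement against the scalar
path.  A 100-replicate fox-only experiment runs in well under a minute on
one CPU.

## Statistical layer

Replicate tables hold one binomial row per (replicate, strategy).  Because
the binomial likelihood factorises, rows are aggregated by design cell
before sampling — posterior-identical and much faster.  Three logit-link
models (means, ANCOVA against fox count, effects coding with strategy and
threshold factors, first levels fixed at zero) are sampled with a
component-wise random-walk Metropolis sampler: 3 chains × 10 000
iterations, burn-in 4 000, thinning 10 (600 stored draws per chain, 1800
total), vague N(0, 100²) priors on all logit-scale parameters.  Proposal
scales adapt toward ~44% acceptance in 50-iteration batches **during
burn-in only**, so the post-burn-in kernel is a fixed, valid Metropolis
kernel.  Chains are initialised at moment-based logits plus jitter;
split-chain Gelman–Rubin R̂ is computed for every quantity and a warning
is raised above 1.1.  The prior SD is configurable; at these sample sizes
(hundreds of binomial trials per cell) the posterior is
likelihood-dominated and the test suite cross-checks posterior means
against maximum-likelihood logistic fits.

Probability-scale summaries apply the inverse logit to each draw and then
summarise (not the other way around), so credible intervals are genuine
intervals on p.  Contrasts are posterior distributions of draw-wise
differences; "significant" means the central 95% interval excludes zero.

## Experiment presets and problem sizes

Presets mirror the published suite: `boar-only` and `fox-only`
(6 predators, 100 replicates, means model), `mixed` (foxes 0–6 with total
predators fixed at 6, 100 replicates each, ANCOVA plus a pooled
social-vs-random refit), and `k-sweep-fox` / `k-sweep-boar` (k = 2–6, 100
replicates per k, naive baseline run as a separate experiment — or reused
from the matching pure-community experiment, since the naive baseline *is*
that experiment's configuration).  Sensitivity sweeps default to 50
replicates per grid point.  Replicate seeds are spawned deterministically
from the master seed, so a (configuration, seed) pair reproduces its table
bit for bit; MCMC summaries are deterministic given the sampler seed.  The
test suite runs the four headline experiments at full scale and the
sensitivity checks at 30–80 replicates per point, keeping the whole suite
in a few minutes of CPU time.

## What the generator does and does not emulate

The simulation *is* the study system — there is no external data — but it
abstracts real landscapes heavily: habitat quality is homogeneous (so
random settlement carries no information penalty), fecundity is fixed at
one nest with no re-nesting, adult predation and nest defence are absent,
and predator densities are constant within a season.  Passing tests
therefore demonstrate the internal logic of the predation-related costs
and benefits of clustering, not their magnitude in any real forest.

## Known limitations

* Prospecting turn SD is not pinned by any published value; the default
  (30°) gives directed-but-wandering search.  Naive-community results are
  insensitive to it (checked over 5–180°); it mainly sets how long
  stage 1 lasts.
* The payoff of Bayesian updating is small in this implementation.
  Per-nest fox risk is nearly flat in the local neighbour count (clusters
  are exploited as wholes once discovered), so trimming neighbourhoods
  above *k* buys little: the k-sweep contrasts γ_k hover within a few
  hundredths of zero (logit scale) for both couplings of updating to
  prospecting, rather than showing a pronounced advantage at low *k*.
  Experiment-to-experiment Monte-Carlo wobble in the shared naive baseline
  (~±0.05 logit at 100 replicates) is of the same order as the effects
  themselves, so single k-sweep runs can show apparently credible gains
  or losses at individual thresholds.
* Within-cluster spatial position (edge vs centre) is not tracked, and
  predator memory beyond the ARS timer, satiation, and Lévy-type step
  lengths are deliberately out of scope.
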