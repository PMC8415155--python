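# Methods

`culturesim` implements a stochastic, spatially explicit agent-based model of
the coevolution of a socially learned trait (a "cultural type": a song
syllable variant, a pronunciation, ...) and a vertically inherited learning
preference (conformity bias vs novelty bias).  Selection acts on the cultural
phenotype, and therefore only *indirectly* on the heritable learning
preference that produced it.  This note documents the model, its parameters,
the numerical choices, and the places where the design was genuinely open.

## The model

Individuals occupy every site of a square lattice (side `grid_side`).  Each
carries exactly one cultural type (an integer id) and one learning
preference.  Each timestep applies three events, in order:

1. **Mortality.**  Every living individual dies independently with
   probability `death_prob` (default 0.20 per timestep, in the range used
   for annual mortality in songbird models).  Its site becomes empty.

2. **Replacement.**  Empty sites are visited in uniformly randomized order.
   For each vacancy, the living, cultured neighbors (Moore 8-neighborhood by
   default) are surveyed once; a candidate whose cultural type has local
   frequency `f` among those neighbors receives fitness weight

       w(f) = 1 − max(0, f − INP)          ("ceiling" form, default)

   where `INP` (`ideal_neighbor_proportion`, in [0, 1]) is the local type
   frequency above which carrying the type becomes disadvantageous.  One
   candidate is sampled with probability proportional to its weight
   (uniformly if every weight is zero, which happens only at `INP = 0` in a
   locally homogeneous neighborhood).  The juvenile inherits the parent's
   learning preference; with probability `preference_mutation_prob`
   (default 1e-4) it instead receives a uniformly random preference, so the
   effective flip rate is half the mutation probability.  Juveniles placed
   earlier in the same phase carry the empty-culture sentinel and are never
   candidate parents.  A vacancy with no living cultured neighbor stays
   empty and may be recolonized from the frontier in later timesteps.

3. **Learning.**  Synchronous over the lattice as it stood at the start of
   the phase, so same-timestep juveniles are never tutors.  Each juvenile
   invents a brand-new cultural type with probability `invention_prob`
   (default 0.005) — and always, if it has no living cultured tutor —
   otherwise it surveys its neighbors' types and adopts one according to its
   preference.  In the default `strict` mode a conformity-biased juvenile
   adopts a most-common type and a novelty-biased juvenile a rarest type,
   ties broken uniformly at random.  A soft `weighted` mode is provided
   (conformity: probability ∝ f²; novelty: ∝ 1 − f; both reduce to uniform
   when all types are equally frequent).

A run starts from a fully occupied lattice with `n_initial_cultures`
(default 16) types assigned uniformly at random and the novelty preference
assigned by independent Bernoulli draws at rate `initial_novelty_fraction`
(default 0.25; at 16,384 individuals the binomial variance of the realized
fraction is negligible, so no exact-count shuffle is used).

## Why the parent weight is one-sided

The natural first reading of "types near an ideal local frequency are
favored" is a symmetric penalty `w = 1 − |f − INP|`.  That form is retained
as `selection_mode="distance"`, but it cannot produce the regime structure
this model is built to study, for a reason worth recording.  Early in a run
the cultural landscape is fine-grained: almost every local frequency is
~1/8.  Under a symmetric penalty with a *high* ideal (say INP = 0.9) every
candidate's weight is then small (0.1–0.35), so the small absolute frequency
differences between conformist phenotypes (locally commoner types) and
novelty phenotypes (locally rarer types) become large *relative* fitness
ratios — roughly 1.5 per birth event — and novelty-biased learners are
purged within a couple hundred timesteps, long before the landscape can
homogenize and shut the differential off.  The high-ideal regime then shows
strong selection against novelty, which is exactly what the model should
not do there: with a high ideal, a conformity-dominated population
homogenizes, novelty-biased learners end up surrounded by a single type,
learn it like everyone else, and become phenotypically cryptic — there is
nothing left to select against.

The one-sided ceiling form restores this behavior exactly rather than
approximately.  With at most 8 neighbors, a local frequency can exceed 0.9
only by equalling 1, and `f = 1` forces a single-type candidate set in
which every weight ties.  Parent choice at INP ≥ 0.9 is therefore uniform
in every vacancy: the high-ideal regime is exactly neutral for the learning
preference, which drifts around its initial value.  At low ideals the
ceiling penalizes every locally common type, so carriers of rare types are
favored and novelty-biased learning sweeps.  In between, the penalty binds
only where some type locally exceeds the ideal, giving a graded transition
(at Moore-8 granularity the onset lies between INP ≈ 0.5 and ≈ 0.875).
The cost of this choice is that a high ideal no longer *actively* rewards
common types — homogenization at high INP is driven by the conformist
learning majority rather than by parent selection.  Both forms are exposed
so the sensitivity of any conclusion to this choice can be checked directly.

## Cultural patchiness ("spatial derivative")

For each cultural type present among living individuals, form the binary
indicator image (1 where a living individual carries the type, else 0; dead
sites are 0).  Convolve with the standard 3×3 Sobel kernels
`[[−1,0,1],[−2,0,2],[−1,0,1]]` and its transpose using reflect-edge
padding, take the per-cell Euclidean norm of the two responses, and sum
over all cells and all types.  Properties that motivated these choices:

- reflect padding makes a constant image score exactly 0, so a fully alive
  single-type lattice has zero patchiness and no spurious lattice-edge
  boundaries are counted;
- per-type indicator images make the statistic invariant under relabeling
  of culture ids (applying Sobel directly to the integer-labeled culture
  matrix would not be; that alternative was considered and rejected);
- dead sites interrupt homogeneous regions and are counted as boundaries —
  relevant when interpreting early-run transients after mortality bursts;
- the statistic is invariant under lattice rotation and reflection.

## Per-timestep summaries

`summarize` records population size, the novelty-preference fraction among
living individuals (undefined — NaN, written as an empty CSV field — for an
empty population, never coerced to 0), the cultural richness (count of
distinct types among living individuals; richness only, no Shannon/Simpson
index), and the Sobel patchiness sum.

## Randomness and reproducibility

All stochastic draws flow through one `numpy.random.Generator` per
replicate, seeded from the config; replicate `k` of a replicate set uses
`base_seed + k`, and sweep cell `i` (row-major over the factorial grid)
starts at `base_seed + i·n_replicates`.  The exact order and kind of draws
per phase is frozen and documented in `culturesim.dynamics`; a brute-force
straight-line reference implementation in the test suite follows the same
protocol, so the optimized step function is checked for *bit-identical*
agreement across seeds, parameter regimes, neighborhoods and boundaries.
Identical config + seed yields bit-identical trajectories, and every CSV
artifact round-trips exactly.

Tie-breaking draws (strict learning) are consumed only when an actual tie
exists; a juvenile with no tutor invents without consuming an invention
draw.  These conventions are part of the determinism contract.

## Problem sizes and what the scaled runs show

Two presets are provided.  The full-scale preset (128 per side = 16,384
individuals, 4,000 timesteps) reproduces the original study conditions and
takes a few CPU-hours per sweep; it is the documented long-run mode.  The
desk preset (64 per side = 4,096 individuals, 1,000 timesteps, summaries
every 10 steps) preserves all rates and the qualitative regime structure
and runs in ~15 s per replicate; the test suite and the acceptance script
use it.  Because the high-ideal regime is neutral, the final novelty
fraction there is a drift outcome whose replicate-to-replicate scatter
grows with timesteps over population size; at desk scale single replicates
scatter substantially around the initial 0.25, which is why the high-INP
check is stated on the mean of five replicates rather than on any single
run.  Low-ideal selection is strong and desk-scale outcomes
(novelty fixation) are essentially deterministic.

The model generates all of its own data; no external inputs exist.  What
the tests do *not* establish about real populations: the model has one
cultural trait per individual (no repertoires), no age structure, mate
choice, or migration, discrete non-overlapping learning (one vertical
transmission event per juvenile), and selection only via the vacancy-fill
rule.  Dialect-boundary geometry beyond the scalar patchiness statistic is
out of scope.

## Degenerate inputs and edge cases

- `death_prob = 0`: a timestep is a no-op apart from the clock.
- `death_prob = 1`: the lattice empties; with no cultured neighbors
  anywhere, vacancies persist; an isolated juvenile (none possible here)
  would invent.
- Empty population: novelty fraction is missing (NaN), richness 0,
  patchiness 0.
- `grid_side < 3` is rejected (the patchiness stencil needs 3×3).
- `n_initial_cultures` may not exceed the population size.

## Known limitations

- The functional form of parent fitness is underdetermined by the verbal
  model description; the ceiling default is justified above, but
  conclusions sensitive to the high-ideal neutrality should be re-checked
  under `selection_mode="distance"` and the `weighted` learning mode.
- At desk scale the neutral high-INP regime has wide drift scatter; checks
  on single replicates there are not meaningful, only replicate means.
- Truncated boundaries introduce mild edge effects (edge sites have 3–5
  neighbors); the toroidal option exists for sensitivity analysis.
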