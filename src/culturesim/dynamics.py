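"""Per-timestep events (mortality, replacement, learning) and the run loop.

Each timestep applies three events in order:

1. **Mortality** — every living individual dies independently with
   probability ``death_prob``; its site becomes empty.
2. **Replacement** — empty sites are visited in uniformly randomized order.
   For each vacancy the living, cultured neighbors are surveyed once; a
   candidate whose cultural type has local frequency ``f`` receives weight
   ``1 - max(0, f - INP)`` (INP = ideal neighbor proportion; the symmetric
   alternative ``1 - |f - INP|`` is available as
   ``selection_mode="distance"``), and one neighbor is sampled with
   probability proportional to weight (uniformly if all weights are zero).  The juvenile inherits the parent's learning preference, which
   with probability ``preference_mutation_prob`` is replaced by a uniformly
   random preference.  Juveniles placed earlier in the same phase carry the
   empty-culture sentinel and are therefore never candidate parents.  A
   vacancy with no living cultured neighbor stays empty this timestep.
3. **Learning** — synchronous over the lattice as it stood at the start of
   the phase, so same-timestep juveniles are never tutors.  Each juvenile
   invents a brand-new cultural type with probability ``invention_prob``
   (and always, if it has no living cultured neighbor); otherwise it adopts
   a type from its neighborhood according to its learning preference
   (strict mode: conformists take a most-common type, novelty-seekers a
   rarest type, ties broken uniformly; weighted mode: probability
   proportional to ``f**2`` resp. ``1 - f``).

RNG draw protocol
-----------------
The exact sequence of draws from the per-run generator is part of the
reproducibility contract (tests compare against an independent straight-line
reference implementation bit for bit):

* mortality: one ``rng.random(grid_side**2)`` vector, row-major; a living
  site dies iff its entry is ``< death_prob``.
* replacement: ``rng.permutation(n_vacancies)`` applied to the ascending
  flat-index list of vacancies; then per filled vacancy, in order —
  one ``rng.random()`` scaled by the total weight (cumulative-sum selection
  over candidates in neighbor-table order) when the total is positive, else
  one ``rng.integers(n_candidates)``; one ``rng.random()`` mutation check;
  if it fires, one ``rng.integers(2)`` for the random preference.
* learning: juveniles in creation order; if tutors exist, one
  ``rng.random()`` invention check; on learning, strict mode draws one
  ``rng.integers(n_tied)`` only when several types tie (tied type ids in
  ascending order), weighted mode draws one ``rng.random()`` scaled by the
  total weight (types in ascending id order), falling back to one
  ``rng.integers(n_types)`` if the total is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .state import (
    CONFORMITY,
    EMPTY_CULTURE,
    NOVELTY,
    Juvenile,
    PopulationState,
    initialize_population,
    neighbor_table,
)

__all__ = [
    "StepReport",
    "mortality_step",
    "local_type_frequencies",
    "parent_weight",
    "choose_parent",
    "mutate_preference",
    "replacement_step",
    "choose_culture_to_learn",
    "learning_step",
    "step",
    "run_simulation",
]


@dataclass(frozen=True)
class StepReport:
    """Bookkeeping counts for one full timestep."""

    n_deaths: int
    n_births: int
    n_inventions: int
    n_preference_mutations: int
    n_unfilled_vacancies: int


# -- mortality -------------------------------------------------------------

def mortality_step(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[PopulationState, int]:
    """Kill each living individual independently with probability ``death_prob``."""
    state = state.copy()
    n_deaths = _mortality_inplace(state, config, rng)
    return state, n_deaths


def _mortality_inplace(state, config, rng) -> int:
    u = rng.random(state.grid_side**2).reshape(state.alive.shape)
    dies = state.alive & (u < config.death_prob)
    state.alive[dies] = False
    state.culture[dies] = EMPTY_CULTURE
    return int(dies.sum())


# -- replacement -----------------------------------------------------------

def parent_weight(freq: float, inp: float, selection_mode: str = "ceiling") -> float:
    """Fitness weight of a candidate parent whose type has local frequency
    ``freq``.

    ``"ceiling"`` (default): ``1 - max(0, freq - inp)`` — the ideal neighbor
    proportion acts as a frequency ceiling; candidates whose type exceeds it
    locally are penalized in proportion to the excess, while selection is
    neutral among candidates at or below it.  ``"distance"``:
    ``1 - |freq - inp|`` — symmetric penalty on either side of the ideal.
    See the methods note for why the one-sided form is the default.
    """
    if not 0.0 < freq <= 1.0:
        raise ValueError(f"freq must lie in (0, 1], got {freq!r}")
    if not 0.0 <= inp <= 1.0:
        raise ValueError(f"inp must lie in [0, 1], got {inp!r}")
    if selection_mode == "ceiling":
        return 1.0 - max(0.0, freq - inp)
    if selection_mode == "distance":
        return 1.0 - abs(freq - inp)
    raise ValueError(f"unknown selection_mode {selection_mode!r}")


def local_type_frequencies(
    state: PopulationState, site: tuple[int, int], config: SimulationConfig
) -> dict[int, float]:
    """Cultural-type frequencies among the living, cultured neighbors of
    ``site``.  An empty dict signals an empty neighborhood (the caller
    decides the fallback)."""
    s = state.grid_side
    alive = state.alive.ravel()
    culture = state.culture.ravel()
    counts: dict[int, int] = {}
    n = 0
    for idx in neighbor_table(s, config.neighborhood, config.boundary)[site[0] * s + site[1]]:
        if alive[idx]:
            t = int(culture[idx])
            if t != EMPTY_CULTURE:
                counts[t] = counts.get(t, 0) + 1
                n += 1
    return {t: k / n for t, k in counts.items()}


def choose_parent(
    state: PopulationState,
    empty_site: tuple[int, int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Sample the parent of the juvenile to be born at ``empty_site``.

    Candidates are the living cultured neighbors; each is weighted by
    :func:`parent_weight` of its type's local frequency.  Returns ``None``
    when there is no candidate (the site stays empty this timestep).
    """
    s = state.grid_side
    if state.alive[empty_site]:
        raise ValueError(f"site {empty_site} is not empty")
    idx = _choose_parent_flat(
        state.alive.ravel(),
        state.culture.ravel(),
        neighbor_table(s, config.neighborhood, config.boundary)[empty_site[0] * s + empty_site[1]],
        config.ideal_neighbor_proportion,
        rng,
        distance_mode=config.selection_mode == "distance",
    )
    return None if idx is None else (idx // s, idx % s)


def _choose_parent_flat(alive, culture, neighbors, inp, rng, distance_mode=False):
    """Weighted parent draw over flat indices; one shared survey per vacancy."""
    cand = []
    counts: dict[int, int] = {}
    for idx in neighbors:
        if alive[idx]:
            t = int(culture[idx])
            if t != EMPTY_CULTURE:
                cand.append(idx)
                counts[t] = counts.get(t, 0) + 1
    if not cand:
        return None
    n = len(cand)
    if distance_mode:
        weights = [1.0 - abs(counts[int(culture[i])] / n - inp) for i in cand]
    else:
        weights = [1.0 - max(0.0, counts[int(culture[i])] / n - inp) for i in cand]
    total = sum(weights)
    if total > 0.0:
        r = rng.random() * total
        acc = 0.0
        for i, w in zip(cand, weights):
            acc += w
            if r < acc:
                return i
        return cand[-1]  # numerical guard
    return cand[int(rng.integers(n))]


def mutate_preference(pref: int, config: SimulationConfig, rng: np.random.Generator) -> int:
    """With probability ``preference_mutation_prob`` return a uniformly
    random preference (so the effective flip rate is half that), else
    ``pref`` unchanged."""
    if rng.random() < config.preference_mutation_prob:
        return int(rng.integers(2))
    return pref


def replacement_step(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[PopulationState, list[Juvenile]]:
    """Fill vacancies with juveniles in uniformly randomized order."""
    state = state.copy()
    juveniles, _, _ = _replacement_inplace(state, config, rng)
    return state, juveniles


def _replacement_inplace(state, config, rng):
    s = state.grid_side
    alive = state.alive.ravel()
    culture = state.culture.ravel()
    preference = state.preference.ravel()
    table = neighbor_table(s, config.neighborhood, config.boundary)
    vacancies = np.flatnonzero(~alive)
    order = vacancies[rng.permutation(len(vacancies))]
    inp = config.ideal_neighbor_proportion
    distance_mode = config.selection_mode == "distance"
    mut_p = config.preference_mutation_prob
    juveniles: list[Juvenile] = []
    n_mut = 0
    n_unfilled = 0
    for site in order:
        site = int(site)
        parent = _choose_parent_flat(alive, culture, table[site], inp, rng, distance_mode)
        if parent is None:
            n_unfilled += 1
            continue
        pref = int(preference[parent])
        if rng.random() < mut_p:
            pref = int(rng.integers(2))
            n_mut += 1
        alive[site] = True
        culture[site] = EMPTY_CULTURE  # unlearned until the learning phase
        preference[site] = pref
        juveniles.append(Juvenile((site // s, site % s), pref))
    return juveniles, n_mut, n_unfilled


# -- learning --------------------------------------------------------------

def choose_culture_to_learn(
    freqs: dict[int, float], pref: int, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Pick the cultural type a juvenile adopts from local frequencies.

    Strict mode: conformity takes a most-common type, novelty a rarest type,
    ties uniform.  Weighted mode: conformity samples type ``t`` with
    probability proportional to ``freqs[t]**2``, novelty proportional to
    ``1 - freqs[t]`` (uniform fallback when all weights vanish).
    """
    if not freqs:
        raise ValueError("freqs must be nonempty")
    types = sorted(freqs)
    if config.bias_mode == "strict":
        target = max(freqs.values()) if pref == CONFORMITY else min(freqs.values())
        tied = [t for t in types if freqs[t] == target]
        if len(tied) == 1:
            return tied[0]
        return tied[int(rng.integers(len(tied)))]
    # weighted
    if pref == CONFORMITY:
        weights = [freqs[t] ** 2 for t in types]
    else:
        weights = [1.0 - freqs[t] for t in types]
    total = sum(weights)
    if total <= 0.0:
        return types[int(rng.integers(len(types)))]
    r = rng.random() * total
    acc = 0.0
    for t, w in zip(types, weights):
        acc += w
        if r < acc:
            return t
    return types[-1]


def learning_step(
    state: PopulationState,
    juveniles: list[Juvenile],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PopulationState, int]:
    """Assign a cultural type to every juvenile (synchronous survey)."""
    state = state.copy()
    n_inv = _learning_inplace(state, juveniles, config, rng)
    return state, n_inv


def _learning_inplace(state, juveniles, config, rng):
    s = state.grid_side
    alive = state.alive.ravel()
    culture = state.culture.ravel()
    culture_before = culture.copy()  # start-of-phase lattice: juveniles are sentinel here
    table = neighbor_table(s, config.neighborhood, config.boundary)
    strict = config.bias_mode == "strict"
    inv_p = config.invention_prob
    n_inv = 0
    for (r, c), pref in juveniles:
        site = r * s + c
        counts: dict[int, int] = {}
        n = 0
        for idx in table[site]:
            if alive[idx]:
                t = int(culture_before[idx])
                if t != EMPTY_CULTURE:
                    counts[t] = counts.get(t, 0) + 1
                    n += 1
        if n == 0 or rng.random() < inv_p:
            culture[site] = state.next_culture_id
            state.next_culture_id += 1
            n_inv += 1
            continue
        if strict:
            target = max(counts.values()) if pref == CONFORMITY else min(counts.values())
            tied = sorted(t for t, k in counts.items() if k == target)
            chosen = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
        else:
            chosen = choose_culture_to_learn(
                {t: k / n for t, k in counts.items()}, pref, config, rng
            )
        culture[site] = chosen
    return n_inv


# -- full step and run loop ------------------------------------------------

def step(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[PopulationState, StepReport]:
    """One full timestep: mortality, replacement, learning; timestep += 1."""
    state = state.copy()
    n_deaths = _mortality_inplace(state, config, rng)
    juveniles, n_mut, n_unfilled = _replacement_inplace(state, config, rng)
    n_inv = _learning_inplace(state, juveniles, config, rng)
    state.timestep += 1
    return state, StepReport(
        n_deaths=n_deaths,
        n_births=len(juveniles),
        n_inventions=n_inv,
        n_preference_mutations=n_mut,
        n_unfilled_vacancies=n_unfilled,
    )


def run_simulation(config: SimulationConfig, keep_final_state: bool = True):
    """Run one replicate; returns a :class:`culturesim.metrics.Trajectory`.

    Summaries are recorded at t=0, every ``record_every`` steps, and always
    at the final timestep.
    """
    from .metrics import Trajectory, summarize  # metrics does not import dynamics

    rng = np.random.default_rng(config.seed)
    state = initialize_population(config, rng)
    records = [summarize(state)]
    for t in range(1, config.n_timesteps + 1):
        state, _ = step(state, config, rng)
        if t % config.record_every == 0 or t == config.n_timesteps:
            records.append(summarize(state))
    return Trajectory(
        config=config,
        records=records,
        final_state=state if keep_final_state else None,
    )
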