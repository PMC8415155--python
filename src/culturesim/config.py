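"""Simulation configuration and presets.

A :class:`SimulationConfig` holds every model parameter and run control in a
single immutable record.  Two presets are provided: :func:`paper_preset`
(128 individuals per side, 4,000 timesteps — the full-scale published
conditions) and :func:`desk_preset` (64 per side, 1,000 timesteps — a
scaled-down configuration that preserves the qualitative regimes and runs in
minutes on a laptop).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

NEIGHBORHOODS = ("moore8", "vonneumann4")
BOUNDARIES = ("truncated", "toroidal")
BIAS_MODES = ("strict", "weighted")
SELECTION_MODES = ("ceiling", "distance")


class ConfigurationError(ValueError):
    """A configuration field is outside its legal range; names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """All model parameters and run controls.

    Parameters
    ----------
    grid_side
        Individuals per side of the square lattice (default 128).
    n_initial_cultures
        Number of distinct cultural types present at t=0 (default 16).
    initial_novelty_fraction
        Probability that a founder carries the novelty learning preference
        (default 0.25); the rest prefer conformity.
    death_prob
        Per-individual, per-timestep mortality probability (default 0.20).
    ideal_neighbor_proportion
        Local cultural-type frequency at which a candidate parent's fitness
        weight is maximal (INP, in [0, 1]).  Low values reward carriers of
        rare types; high values reward carriers of common types.
    invention_prob
        Per-juvenile probability of inventing a brand-new cultural type
        instead of learning one from a tutor (default 0.005).
    preference_mutation_prob
        Per-juvenile probability of receiving a uniformly random learning
        preference instead of the parent's (default 0.0001); the effective
        flip rate is half of this.
    n_timesteps
        Number of mortality/replacement/learning cycles to run (default 4000).
    seed
        RNG seed; identical config + seed gives bit-identical runs.
    neighborhood
        ``"moore8"`` (the 8 surrounding cells, default) or ``"vonneumann4"``.
    boundary
        ``"truncated"`` (bounded lattice, default) or ``"toroidal"``.
    bias_mode
        ``"strict"`` (conformists copy an argmax type, novelty-seekers an
        argmin type, ties uniform — default) or ``"weighted"`` (soft
        frequency-dependent sampling).
    selection_mode
        Parent fitness-weight form: ``"ceiling"`` (default,
        ``1 - max(0, f - INP)``: only local type frequencies above the ideal
        are penalized) or ``"distance"`` (``1 - |f - INP|``, symmetric).
    record_every
        Summary-recording interval in timesteps (default 1).
    """

    grid_side: int = 128
    n_initial_cultures: int = 16
    initial_novelty_fraction: float = 0.25
    death_prob: float = 0.20
    ideal_neighbor_proportion: float = 0.5
    invention_prob: float = 0.005
    preference_mutation_prob: float = 0.0001
    n_timesteps: int = 4000
    seed: int = 0
    neighborhood: str = "moore8"
    boundary: str = "truncated"
    bias_mode: str = "strict"
    selection_mode: str = "ceiling"
    record_every: int = 1

    def __post_init__(self) -> None:
        def bad(field: str, why: str):
            raise ConfigurationError(f"{field}: {why}")

        if not isinstance(self.grid_side, int) or self.grid_side < 3:
            bad("grid_side", "must be an integer >= 3 (the Sobel metric needs a 3x3 stencil)")
        if not isinstance(self.n_initial_cultures, int) or self.n_initial_cultures < 1:
            bad("n_initial_cultures", "must be a positive integer")
        if self.n_initial_cultures > self.grid_side**2:
            bad("n_initial_cultures", "cannot exceed grid_side**2")
        for field in (
            "initial_novelty_fraction",
            "death_prob",
            "ideal_neighbor_proportion",
            "invention_prob",
            "preference_mutation_prob",
        ):
            v = getattr(self, field)
            if not 0.0 <= float(v) <= 1.0:
                bad(field, f"must lie in [0, 1], got {v!r}")
        if not isinstance(self.n_timesteps, int) or self.n_timesteps < 0:
            bad("n_timesteps", "must be a nonnegative integer")
        if not isinstance(self.seed, int):
            bad("seed", "must be an integer")
        if self.neighborhood not in NEIGHBORHOODS:
            bad("neighborhood", f"must be one of {NEIGHBORHOODS}")
        if self.boundary not in BOUNDARIES:
            bad("boundary", f"must be one of {BOUNDARIES}")
        if self.bias_mode not in BIAS_MODES:
            bad("bias_mode", f"must be one of {BIAS_MODES}")
        if self.selection_mode not in SELECTION_MODES:
            bad("selection_mode", f"must be one of {SELECTION_MODES}")
        if not isinstance(self.record_every, int) or self.record_every < 1:
            bad("record_every", "must be a positive integer")

    # -- convenience -------------------------------------------------------

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown field(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def paper_preset(**overrides) -> SimulationConfig:
    """Full-scale conditions: 128 per side, 4,000 timesteps."""
    return SimulationConfig(**overrides)


def desk_preset(**overrides) -> SimulationConfig:
    """Scaled-down conditions: 64 per side, 1,000 timesteps, summaries every 10."""
    defaults = dict(grid_side=64, n_timesteps=1000, record_every=10)
    defaults.update(overrides)
    return SimulationConfig(**defaults)
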