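"""Population state: the lattice, initialization, neighborhoods and snapshots.

The population lives on a ``grid_side x grid_side`` lattice.  Each site
carries an alive flag, a cultural type id (``EMPTY_CULTURE`` = -1 marks empty
sites and newly placed juveniles that have not yet learned), and a learning
preference (``CONFORMITY`` = 0 or ``NOVELTY`` = 1).  ``next_culture_id`` is a
monotone counter used to mint new cultural types on invention.

Snapshots serialize to three integer CSV matrices (culture, preference,
alive) plus a JSON sidecar with the counter, the timestep and, optionally,
the generating configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np

from .config import ConfigurationError, SimulationConfig

CONFORMITY = 0
NOVELTY = 1
EMPTY_CULTURE = -1

#: Fixed neighbor visit order (row-major over offsets); part of the RNG
#: draw-sequence contract in :mod:`culturesim.dynamics`.
MOORE_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
VONNEUMANN_OFFSETS = ((-1, 0), (0, -1), (0, 1), (1, 0))


class Juvenile(NamedTuple):
    """A pending newborn between the replacement and learning phases."""

    site: tuple[int, int]
    preference: int


@dataclass
class PopulationState:
    """Lattice state at one timestep.

    ``culture`` is ``EMPTY_CULTURE`` wherever ``alive`` is false and at
    juvenile sites awaiting learning; ``preference`` values at empty sites
    are ignored.
    """

    alive: np.ndarray  # (s, s) bool
    culture: np.ndarray  # (s, s) int64, EMPTY_CULTURE at empty/unlearned sites
    preference: np.ndarray  # (s, s) int8, CONFORMITY/NOVELTY
    next_culture_id: int
    timestep: int

    @property
    def grid_side(self) -> int:
        return self.alive.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            alive=self.alive.copy(),
            culture=self.culture.copy(),
            preference=self.preference.copy(),
            next_culture_id=self.next_culture_id,
            timestep=self.timestep,
        )

    def equals(self, other: "PopulationState") -> bool:
        """Bit-identical comparison (preferences at dead sites included)."""
        return (
            np.array_equal(self.alive, other.alive)
            and np.array_equal(self.culture, other.culture)
            and np.array_equal(self.preference, other.preference)
            and self.next_culture_id == other.next_culture_id
            and self.timestep == other.timestep
        )

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        if not ((self.culture[~self.alive] == EMPTY_CULTURE).all()):
            raise ValueError("culture must be the empty sentinel wherever alive is false")
        cultured = self.culture[self.culture != EMPTY_CULTURE]
        if cultured.size and (cultured.min() < 0 or cultured.max() >= self.next_culture_id):
            raise ValueError("culture ids must lie in [0, next_culture_id)")


def initialize_population(config: SimulationConfig, rng: np.random.Generator) -> PopulationState:
    """Create the founding population: all sites alive, cultures uniform over
    ``{0, ..., n_initial_cultures-1}``, preference novelty with independent
    probability ``initial_novelty_fraction``."""
    if not isinstance(config, SimulationConfig):
        raise ConfigurationError("config: expected a SimulationConfig")
    s = config.grid_side
    culture = rng.integers(0, config.n_initial_cultures, size=(s, s), dtype=np.int64)
    preference = (rng.random((s, s)) < config.initial_novelty_fraction).astype(np.int8)
    return PopulationState(
        alive=np.ones((s, s), dtype=bool),
        culture=culture,
        preference=preference,
        next_culture_id=config.n_initial_cultures,
        timestep=0,
    )


@lru_cache(maxsize=32)
def neighbor_table(grid_side: int, neighborhood: str, boundary: str) -> tuple:
    """Per-site tuple of flat neighbor indices, in fixed offset order.

    Cached per geometry; with ``truncated`` boundaries edge sites simply have
    fewer entries, with ``toroidal`` boundaries indices wrap.
    """
    offsets = MOORE_OFFSETS if neighborhood == "moore8" else VONNEUMANN_OFFSETS
    s = grid_side
    table = []
    for r in range(s):
        for c in range(s):
            nbs = []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if boundary == "toroidal":
                    nbs.append((rr % s) * s + (cc % s))
                elif 0 <= rr < s and 0 <= cc < s:
                    nbs.append(rr * s + cc)
            table.append(tuple(nbs))
    return tuple(table)


def living_neighbor_sites(
    state: PopulationState, site: tuple[int, int], config: SimulationConfig
) -> list[tuple[int, int]]:
    """Sites of living, cultured neighbors of ``site``.

    Living neighbors whose culture is still the empty sentinel (same-phase
    juveniles awaiting learning) are excluded: they can be neither tutors nor
    parents.
    """
    s = state.grid_side
    r, c = site
    if not (0 <= r < s and 0 <= c < s):
        raise IndexError(f"site {site} out of bounds for grid_side {s}")
    alive = state.alive.ravel()
    culture = state.culture.ravel()
    out = []
    for idx in neighbor_table(s, config.neighborhood, config.boundary)[r * s + c]:
        if alive[idx] and culture[idx] != EMPTY_CULTURE:
            out.append((idx // s, idx % s))
    return out


# -- snapshot I/O ----------------------------------------------------------

def save_snapshot(state: PopulationState, directory, config: Optional[SimulationConfig] = None) -> None:
    """Write ``culture.csv``, ``preference.csv``, ``alive.csv`` and ``state.json``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "culture.csv", state.culture, fmt="%d", delimiter=",")
    np.savetxt(d / "preference.csv", state.preference, fmt="%d", delimiter=",")
    np.savetxt(d / "alive.csv", state.alive.astype(np.int8), fmt="%d", delimiter=",")
    sidecar = {
        "next_culture_id": int(state.next_culture_id),
        "timestep": int(state.timestep),
        "config": config.to_dict() if config is not None else None,
    }
    with open(d / "state.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def load_snapshot(directory) -> tuple[PopulationState, Optional[SimulationConfig]]:
    """Read a snapshot written by :func:`save_snapshot`."""
    d = Path(directory)
    culture = np.loadtxt(d / "culture.csv", dtype=np.int64, delimiter=",", ndmin=2)
    preference = np.loadtxt(d / "preference.csv", dtype=np.int8, delimiter=",", ndmin=2)
    alive = np.loadtxt(d / "alive.csv", dtype=np.int8, delimiter=",", ndmin=2).astype(bool)
    with open(d / "state.json") as fh:
        sidecar = json.load(fh)
    config = None
    if sidecar.get("config") is not None:
        config = SimulationConfig.from_dict(sidecar["config"])
    state = PopulationState(
        alive=alive,
        culture=culture,
        preference=preference,
        next_culture_id=int(sidecar["next_culture_id"]),
        timestep=int(sidecar["timestep"]),
    )
    return state, config
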