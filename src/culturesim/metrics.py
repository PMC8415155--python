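"""Per-timestep population summaries and the cultural-patchiness statistic.

The patchiness ("spatial derivative") statistic treats each cultural type as
a binary indicator image on the lattice and sums the Sobel gradient
magnitude over all cells and all types.  Homogeneous cultural regions
contribute nothing; boundaries between types — and holes left by dead
sites — contribute positively, so high values mean a heterogeneous cultural
landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SimulationConfig
from .state import EMPTY_CULTURE, NOVELTY, PopulationState

#: Horizontal Sobel kernel; the vertical kernel is its transpose.
SOBEL_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_KY = SOBEL_KX.T


@dataclass(frozen=True)
class SummaryRecord:
    """One timestep's population summaries.

    ``novelty_fraction`` is NaN for an empty population (missing, not 0).
    """

    timestep: int
    n_alive: int
    novelty_fraction: float
    culture_richness: int
    sobel_sum: float


@dataclass
class Trajectory:
    """Ordered summaries for one replicate, plus an optional final snapshot."""

    config: SimulationConfig
    records: list[SummaryRecord]
    final_state: Optional[PopulationState] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestep": [r.timestep for r in self.records],
                "n_alive": [r.n_alive for r in self.records],
                "novelty_fraction": [r.novelty_fraction for r in self.records],
                "culture_richness": [r.culture_richness for r in self.records],
                "sobel_sum": [r.sobel_sum for r in self.records],
            }
        )

    @property
    def final_record(self) -> SummaryRecord:
        return self.records[-1]


def novelty_fraction(state: PopulationState) -> float:
    """Fraction of living individuals carrying the novelty preference;
    NaN for an empty population."""
    n = state.n_alive
    if n == 0:
        return math.nan
    return float((state.preference[state.alive] == NOVELTY).sum()) / n


def culture_richness(state: PopulationState) -> int:
    """Number of distinct cultural types among living individuals."""
    cultured = state.culture[state.alive]
    cultured = cultured[cultured != EMPTY_CULTURE]
    return int(np.unique(cultured).size)


def sobel_patchiness(state: PopulationState) -> float:
    """Sum of Sobel gradient magnitudes over all per-type indicator images.

    For each cultural type present, the indicator image is 1 where a living
    individual carries that type and 0 elsewhere (dead sites are 0, so
    occupancy holes register as boundaries).  Both 3x3 Sobel kernels are
    applied with reflect-edge padding; the per-cell magnitude is the
    Euclidean norm of the two responses.  A fully alive single-type lattice
    scores exactly 0.
    """
    if state.grid_side < 3:
        raise ValueError("sobel_patchiness needs grid_side >= 3")
    cultured = state.culture[state.alive]
    types = np.unique(cultured[cultured != EMPTY_CULTURE])
    total = 0.0
    for t in types:
        ind = ((state.culture == t) & state.alive).astype(np.float64)
        gx = ndimage.convolve(ind, SOBEL_KX, mode="reflect")
        gy = ndimage.convolve(ind, SOBEL_KY, mode="reflect")
        total += float(np.sqrt(gx * gx + gy * gy).sum())
    return total


def summarize(state: PopulationState) -> SummaryRecord:
    """Assemble all four statistics for the state's current timestep."""
    return SummaryRecord(
        timestep=state.timestep,
        n_alive=state.n_alive,
        novelty_fraction=novelty_fraction(state),
        culture_richness=culture_richness(state),
        sobel_sum=sobel_patchiness(state),
    )


# -- trajectory I/O --------------------------------------------------------

def write_trajectories_csv(trajectories: list[Trajectory], path) -> None:
    """Tidy CSV: replicate, timestep, n_alive, novelty_fraction,
    culture_richness, sobel_sum (missing novelty fractions are empty)."""
    frames = []
    for k, traj in enumerate(trajectories):
        df = traj.to_dataframe()
        df.insert(0, "replicate", k)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path) -> pd.DataFrame:
    # round_trip parsing: the fast default parser can be off by one ulp,
    # which would break the exact-reproducibility contract
    return pd.read_csv(path, float_precision="round_trip")


def trajectory_from_dataframe(config: SimulationConfig, df: pd.DataFrame) -> Trajectory:
    """Rebuild a (snapshot-free) Trajectory from its tidy table."""
    records = [
        SummaryRecord(
            timestep=int(row.timestep),
            n_alive=int(row.n_alive),
            novelty_fraction=float(row.novelty_fraction),
            culture_richness=int(row.culture_richness),
            sobel_sum=float(row.sobel_sum),
        )
        for row in df.itertuples(index=False)
    ]
    return Trajectory(config=config, records=records, final_state=None)
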