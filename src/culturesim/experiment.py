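"""Replicate runs, factorial parameter sweeps and output rendering.

A sweep executes the full factorial of ideal-neighbor-proportion values x
initial-novelty-fraction values x replicates, recording each replicate's
final novelty fraction, cultural richness, patchiness and population size,
plus per-cell mean and population standard deviation.  Seeds are assigned
deterministically: cell ``i`` (row-major over the factorial grid),
replicate ``k`` uses ``base_seed + i * n_replicates + k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dynamics import run_simulation
from .metrics import Trajectory, write_trajectories_csv
from .state import save_snapshot

log = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    """Factorial sweep specification."""

    base_config: SimulationConfig
    inp_values: list[float]
    initial_novelty_values: list[float]
    n_replicates: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.inp_values or not self.initial_novelty_values:
            raise ValueError("inp_values and initial_novelty_values must be nonempty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SweepResult:
    """Long-format per-replicate table plus per-cell mean/sd summary."""

    spec: SweepSpec
    table: pd.DataFrame  # one row per (inp, initial_novelty, replicate)
    summary: pd.DataFrame  # one row per (inp, initial_novelty)


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    base_seed: int,
    keep_final_state: bool = True,
) -> list[Trajectory]:
    """Run independent replicates; replicate ``k`` uses seed ``base_seed + k``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for k in range(n_replicates):
        out.append(
            run_simulation(config.replace(seed=base_seed + k), keep_final_state=keep_final_state)
        )
        log.info("replicate %d/%d done", k + 1, n_replicates)
    return out


def run_sweep(spec: SweepSpec, keep_final_states: bool = False) -> SweepResult:
    """Execute the full factorial sweep and summarize final states."""
    rows = []
    cell = 0
    for inp in spec.inp_values:
        for nov in spec.initial_novelty_values:
            cfg = spec.base_config.replace(
                ideal_neighbor_proportion=float(inp), initial_novelty_fraction=float(nov)
            )
            base = spec.base_seed + cell * spec.n_replicates
            for k, traj in enumerate(
                run_replicates(cfg, spec.n_replicates, base, keep_final_state=keep_final_states)
            ):
                rec = traj.final_record
                rows.append(
                    {
                        "inp": float(inp),
                        "initial_novelty": float(nov),
                        "replicate": k,
                        "seed": base + k,
                        "final_novelty_fraction": rec.novelty_fraction,
                        "final_richness": rec.culture_richness,
                        "final_sobel_sum": rec.sobel_sum,
                        "n_alive": rec.n_alive,
                    }
                )
            cell += 1
            log.info("sweep cell %d (inp=%s, novelty=%s) done", cell, inp, nov)
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["inp", "initial_novelty"], as_index=False)
        .agg(
            mean_final_novelty=("final_novelty_fraction", "mean"),
            sd_final_novelty=("final_novelty_fraction", lambda x: float(np.std(x, ddof=0))),
            mean_final_sobel=("final_sobel_sum", "mean"),
            mean_final_richness=("final_richness", "mean"),
            n_replicates=("replicate", "size"),
        )
        .sort_values(["inp", "initial_novelty"], ignore_index=True)
    )
    return SweepResult(spec=spec, table=table, summary=summary)


def render_outputs(
    result: SweepResult,
    trajectories: list[Trajectory],
    out_dir,
    make_plots: bool = False,
) -> list[Path]:
    """Write sweep CSVs, trajectory CSV, final-state snapshots and optional plots.

    Returns the list of files/directories written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sweep_csv = out / "sweep.csv"
    result.table.to_csv(sweep_csv, index=False)
    written.append(sweep_csv)
    summary_csv = out / "sweep_summary.csv"
    result.summary.to_csv(summary_csv, index=False)
    written.append(summary_csv)
    cfg_json = out / "config.json"
    result.spec.base_config.to_json(cfg_json)
    written.append(cfg_json)

    if not trajectories:
        log.info("no trajectories supplied; skipping trajectory and snapshot outputs")
        return written

    traj_csv = out / "trajectories.csv"
    write_trajectories_csv(trajectories, traj_csv)
    written.append(traj_csv)

    for k, traj in enumerate(trajectories):
        if traj.final_state is not None:
            snap_dir = out / f"final_state_rep{k}"
            save_snapshot(traj.final_state, snap_dir, config=traj.config)
            written.append(snap_dir)

    if make_plots:
        written.extend(_render_plots(result, trajectories, out))
    return written


def _render_plots(result: SweepResult, trajectories: list[Trajectory], out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.table["inp"], result.table["final_novelty_fraction"], s=12, c="k")
    ax.errorbar(
        result.summary["inp"],
        result.summary["mean_final_novelty"],
        yerr=result.summary["sd_final_novelty"],
        fmt="none",
        ecolor="red",
    )
    ax.set_xlabel("ideal neighbor proportion")
    ax.set_ylabel("final novelty fraction")
    fig.tight_layout()
    p = out / "final_novelty_vs_inp.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for traj in trajectories:
        df = traj.to_dataframe()
        label = f"INP={traj.config.ideal_neighbor_proportion:g}"
        axes[0].plot(df["timestep"], df["novelty_fraction"], lw=0.8, label=label)
        axes[1].plot(df["timestep"], df["sobel_sum"], lw=0.8, label=label)
    axes[0].set_xlabel("timestep")
    axes[0].set_ylabel("novelty fraction")
    axes[1].set_xlabel("timestep")
    axes[1].set_ylabel("spatial derivative (Sobel sum)")
    fig.tight_layout()
    p = out / "trajectories.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    snaps = [t for t in trajectories if t.final_state is not None]
    if snaps:
        fig, axes = plt.subplots(1, len(snaps), figsize=(3 * len(snaps), 3), squeeze=False)
        for ax, traj in zip(axes[0], snaps):
            m = np.ma.masked_where(~traj.final_state.alive, traj.final_state.culture)
            ax.imshow(m, interpolation="nearest", cmap="viridis")
            ax.set_title(f"INP={traj.config.ideal_neighbor_proportion:g}", fontsize=9)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.tight_layout()
        p = out / "final_culture_matrices.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
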