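"""Optional matplotlib views of simulation outputs.

Imported lazily so the core library has no plotting dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .experiments import PhaseTrajectory, PopulationSeries
from .gridworld import PREDATOR, PREY, GridState


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_population_series(series: PopulationSeries,
                           path: Union[str, Path]) -> None:
    """Predator and prey counts against time."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(series.t, series.n_predator, color="crimson", label="predator")
    ax.plot(series.t, series.n_prey, color="seagreen", label="prey")
    if series.switch_t is not None:
        ax.axvline(series.switch_t, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("step")
    ax.set_ylabel("population")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_trajectory(phase: PhaseTrajectory,
                          path: Union[str, Path]) -> None:
    """Predator-prey phase plane, colored by segment."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    colors = {"random-phase": "steelblue", "trained-phase": "crimson"}
    for name in dict.fromkeys(phase.labels):
        seg = phase.points[phase.labels == name]
        ax.plot(seg[:, 0], seg[:, 1], lw=0.7, alpha=0.8,
                color=colors.get(name, "black"), label=name)
        cx, cy = phase.centroids[name]
        ax.plot(cx, cy, "o", color=colors.get(name, "black"))
    ax.set_xlabel("predators")
    ax.set_ylabel("prey")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_agent_scatter(state: GridState, path: Union[str, Path]) -> None:
    """Agent locations on the grid (predators red, prey green)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    ids = state.living_ids()
    for sp, color, label in ((PREDATOR, "crimson", "predator"),
                             (PREY, "seagreen", "prey")):
        sel = ids[state.species[ids] == sp]
        ax.scatter(state.pos_c[sel], state.pos_r[sel], s=8, c=color,
                   label=label)
    ax.set_xlim(-0.5, state.cfg.N - 0.5)
    ax.set_ylim(state.cfg.N - 0.5, -0.5)
    ax.set_aspect("equal")
    ax.set_title(f"t = {state.t}")
    ax.legend(frameon=False, fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
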