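"""Episode rollouts and the population-dynamics analyses built on them.

This module turns simulated trajectories into the quantities the ecosystem
study is judged by: population time series and their post-burn-in summary
statistics (means, coefficients of variation, prey-over-predator dominance
gap, dominant oscillation period), predator-prey phase-plane trajectories,
a Clark-Evans nearest-neighbor index quantifying swarming on the torus, and
a robustness sweep that re-runs frozen trained policies under perturbed
initial conditions, grid sizes, and predator life spans.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import EnvConfig
from .errors import PredPreyError, UndefinedStatisticError
from .gridworld import (PREDATOR, PREY, GridState, StepEvents, env_step,
                        init_env, is_terminal)
from .policies import PolicyParams, RandomPolicy, load_checkpoint
from .rng import seed_streams

__all__ = [
    "PopulationSeries", "PhaseTrajectory", "SwarmStat",
    "run_episode", "phase_trajectory", "swarming_index", "robustness_suite",
    "summarize", "standard_variants", "snapshot_dict",
    "series_to_csv", "series_from_csv", "shoelace_area",
]

_CSV_COLUMNS = ["t", "n_predator", "n_prey", "captures_pred_action",
                "captures_prey_action", "births_pred", "births_prey",
                "deaths_starvation", "deaths_age", "deaths_age_predator"]


@dataclass
class PopulationSeries:
    """Per-step population counts and demographic events of one episode.

    Row 0 is the initial state (no events); row ``i >= 1`` describes the
    world after step ``i`` together with the events of that step.
    """

    t: np.ndarray
    n_predator: np.ndarray
    n_prey: np.ndarray
    events: List[Optional[StepEvents]]
    termination: Optional[str] = None
    switch_t: Optional[int] = None

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.t)):
            ev = self.events[i] or StepEvents()
            rows.append([int(self.t[i]), int(self.n_predator[i]),
                         int(self.n_prey[i]),
                         ev.captures_by_predator_action,
                         ev.captures_by_prey_action, ev.predator_births,
                         ev.prey_births, ev.starvation_deaths, ev.age_deaths,
                         ev.predator_age_deaths])
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def series_to_csv(series: PopulationSeries, path: Union[str, Path]) -> None:
    series.to_dataframe().to_csv(path, index=False)


def series_from_csv(path: Union[str, Path]) -> PopulationSeries:
    df = pd.read_csv(path)
    events: List[Optional[StepEvents]] = []
    for i, row in df.iterrows():
        if i == 0:
            events.append(None)
            continue
        events.append(StepEvents(
            captures_by_predator_action=int(row["captures_pred_action"]),
            captures_by_prey_action=int(row["captures_prey_action"]),
            predator_births=int(row["births_pred"]),
            prey_births=int(row["births_prey"]),
            starvation_deaths=int(row["deaths_starvation"]),
            age_deaths=int(row["deaths_age"]),
            predator_age_deaths=int(row["deaths_age_predator"])))
    return PopulationSeries(df["t"].to_numpy(), df["n_predator"].to_numpy(),
                            df["n_prey"].to_numpy(), events)


@dataclass
class PhaseTrajectory:
    """The (n_predator, n_prey) phase-plane view of a population series."""

    points: np.ndarray                      # (T, 2) ordered pairs
    labels: np.ndarray                      # segment label per point
    centroids: Dict[str, np.ndarray]
    radii: Dict[str, float]                 # max distance from own centroid
    trained_dominates_random: Optional[bool] = None


@dataclass
class SwarmStat:
    """Clark-Evans aggregation ratio of one species at one time.

    ``R = (mean nearest-neighbor distance) / (0.5 / sqrt(density))`` with
    toroidal distances; R is about 1 under complete spatial randomness and
    drops below 1 when individuals cluster (swarm).
    """

    species: str
    t: int
    n_agents: int
    mean_nn_distance: float
    expected_nn_distance: float

    @property
    def R(self) -> float:
        return self.mean_nn_distance / self.expected_nn_distance


# ---------------------------------------------------------------------------
# Rollouts
# ---------------------------------------------------------------------------

def _resolve_policy(source, species: str):
    """A policy source is a policy object, ``"random"``, or a checkpoint path."""
    if source == "random":
        return RandomPolicy(species)
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise PredPreyError(f"missing checkpoint: {path}")
        return load_checkpoint(path)
    return source


def _schedule_lookup(schedule, t: int):
    active = schedule[0]
    for entry in schedule:
        if entry[0] <= t:
            active = entry
        else:
            break
    return active[1], active[2]


def run_episode(policies, env_cfg: EnvConfig, seed: int,
                policy_schedule: Optional[Sequence[Tuple[int, object, object]]] = None,
                snapshot_steps: Sequence[int] = (),
                ) -> Tuple[PopulationSeries, Dict[int, GridState]]:
    """Roll out one episode and log populations and events per step.

    ``policies`` is a ``(predator, prey)`` pair used for the whole episode
    unless ``policy_schedule`` is given: a list of
    ``(start_step, predator_source, prey_source)`` entries, each source being
    a policy object, the string ``"random"``, or a checkpoint path — this
    enables the random-to-trained switch experiment.  Snapshots of the full
    grid state are taken at the requested step indices (0 = initial state).
    The rollout is a deterministic function of ``(env_cfg, policies, seed)``.
    """
    streams = seed_streams(seed)
    if policy_schedule is None:
        policy_schedule = [(0, policies[0], policies[1])]
    schedule = sorted(
        [(int(s), _resolve_policy(p, "predator"), _resolve_policy(q, "prey"))
         for s, p, q in policy_schedule], key=lambda e: e[0])
    switch_t = schedule[1][0] if len(schedule) > 1 else None

    state = init_env(env_cfg, streams["placement"])
    ts, n_pred, n_prey = [0], [state.counts()[0]], [state.counts()[1]]
    events: List[Optional[StepEvents]] = [None]
    snapshots: Dict[int, GridState] = {}
    if 0 in snapshot_steps:
        snapshots[0] = state.copy()
    termination = None
    while True:
        terminal, reason = is_terminal(state)
        if terminal:
            termination = reason
            break
        pol_pred, pol_prey = _schedule_lookup(schedule, state.t)
        state, _, ev = env_step(state, pol_pred, pol_prey,
                                streams["rollout"], collect=False)
        ts.append(state.t)
        n_pred.append(state.counts()[0])
        n_prey.append(state.counts()[1])
        events.append(ev)
        if state.t in snapshot_steps:
            snapshots[state.t] = state.copy()
    return (PopulationSeries(np.array(ts), np.array(n_pred), np.array(n_prey),
                             events, termination, switch_t), snapshots)


def snapshot_dict(state: GridState) -> Dict:
    """JSON-ready snapshot: config echo, time, and per-agent records."""
    return {
        "config": dataclasses.asdict(state.cfg),
        "t": int(state.t),
        "agents": [
            {"id": a.id, "species": a.species, "row": a.position[0],
             "col": a.position[1], "starvation": a.starvation, "age": a.age}
            for a in state.agents()
        ],
    }


# ---------------------------------------------------------------------------
# Phase-plane analysis
# ---------------------------------------------------------------------------

def shoelace_area(points: np.ndarray) -> float:
    """Absolute enclosed area of the closed polygon through ``points``."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def phase_trajectory(series: PopulationSeries,
                     switch_t: Optional[int] = None) -> PhaseTrajectory:
    """Re-index a population series as an ordered phase-plane trajectory.

    Points before ``switch_t`` are labeled ``random-phase``, the rest
    ``trained-phase`` (a single ``trained-phase`` segment when no switch is
    given).  Reports per-segment centroids, excursion radii (max distance
    from the segment centroid), and whether the trained-segment centroid
    dominates the random-segment centroid in both coordinates.
    """
    if len(series) == 0:
        raise PredPreyError("empty series")
    if switch_t is None:
        switch_t = series.switch_t
    pts = np.column_stack([series.n_predator, series.n_prey]).astype(float)
    if switch_t is not None and not (0 <= switch_t <= series.t[-1]):
        raise IndexError(f"switch_t={switch_t} outside series time range")
    if switch_t is None:
        labels = np.array(["trained-phase"] * len(pts))
    else:
        labels = np.where(series.t < switch_t, "random-phase", "trained-phase")
    centroids, radii = {}, {}
    for name in np.unique(labels):
        seg = pts[labels == name]
        centroids[name] = seg.mean(axis=0)
        radii[name] = float(np.max(np.linalg.norm(seg - seg.mean(axis=0), axis=1)))
    dominates = None
    if "random-phase" in centroids and "trained-phase" in centroids:
        dominates = bool(np.all(centroids["trained-phase"]
                                > centroids["random-phase"]))
    return PhaseTrajectory(pts, labels, centroids, radii, dominates)


# ---------------------------------------------------------------------------
# Swarming statistic
# ---------------------------------------------------------------------------

def _toroidal_nn_distances(positions: np.ndarray, N: int) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    d = np.abs(pos[:, None, :] - pos[None, :, :])
    d = np.minimum(d, N - d)
    dist = np.sqrt(np.sum(d * d, axis=-1))
    np.fill_diagonal(dist, np.inf)
    return dist.min(axis=1)


def swarming_index(snapshot: Union[GridState, Tuple[np.ndarray, int]],
                   species: Union[str, int]) -> SwarmStat:
    """Clark-Evans ratio of one species' positions on the torus.

    ``snapshot`` is a grid state, or a ``(positions, N)`` pair with an
    ``(n, 2)`` integer position array.  Requires at least two individuals.
    """
    sp_idx = species if isinstance(species, int) else \
        ("predator", "prey").index(species)
    sp_name = ("predator", "prey")[sp_idx]
    if isinstance(snapshot, GridState):
        ids = [int(a) for a in snapshot.living_ids()
               if snapshot.species[a] == sp_idx]
        positions = np.column_stack([snapshot.pos_r[ids], snapshot.pos_c[ids]]) \
            if ids else np.zeros((0, 2))
        N, t = snapshot.cfg.N, snapshot.t
    else:
        positions, N = snapshot
        positions = np.asarray(positions)
        t = 0
    n = len(positions)
    if n < 2:
        raise UndefinedStatisticError(
            f"Clark-Evans index needs >= 2 {sp_name} agents, got {n}")
    mean_nn = float(np.mean(_toroidal_nn_distances(positions, N)))
    density = n / float(N * N)
    expected = 0.5 / np.sqrt(density)
    return SwarmStat(sp_name, int(t), n, mean_nn, expected)


# ---------------------------------------------------------------------------
# Summaries and robustness sweeps
# ---------------------------------------------------------------------------

def _autocorr_period(x: np.ndarray, threshold: float = 0.2) -> Optional[int]:
    """Lag of the first local autocorrelation peak above ``threshold``."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0 or len(x) < 3:
        return None
    ac = np.correlate(x, x, mode="full")[len(x) - 1:] / denom
    for k in range(1, len(ac) - 1):
        if ac[k] > threshold and ac[k] >= ac[k - 1] and ac[k] >= ac[k + 1]:
            return k
    return None


def summarize(series: PopulationSeries, burn_in: int = 500) -> Dict:
    """Post-burn-in summary statistics of a population series.

    Reports per-species means, standard deviations and coefficients of
    variation, the prey-over-predator dominance gap, an extinction flag, and
    the dominant oscillation period (first autocorrelation peak above 0.2).
    """
    if burn_in >= len(series):
        raise PredPreyError(f"burn_in={burn_in} >= series length {len(series)}")
    pred = np.asarray(series.n_predator[burn_in:], dtype=float)
    prey = np.asarray(series.n_prey[burn_in:], dtype=float)

    def stats(x: np.ndarray) -> Dict[str, float]:
        mean, sd = float(x.mean()), float(x.std())
        return {"mean": mean, "sd": sd,
                "cv": sd / mean if mean > 0 else float("inf")}

    return {
        "burn_in": burn_in,
        "n_steps": len(series) - 1,
        "predator": stats(pred),
        "prey": stats(prey),
        "dominance_gap": float(np.mean(prey - pred)),
        "extinct": series.termination == "extinction",
        "termination": series.termination,
        "oscillation_period_prey": _autocorr_period(prey),
        "oscillation_period_predator": _autocorr_period(pred),
    }


def standard_variants(base: EnvConfig) -> List[Tuple[str, EnvConfig]]:
    """The robustness study's perturbed environments around ``base``.

    Initial counts scaled by +/-20%, grid sides 40 and 60, and predator
    maximum ages 40, 30 and 20 steps.
    """
    rep = dataclasses.replace
    return [
        ("counts-20pct", rep(base, nX=int(round(base.nX * 0.8)),
                             nY=int(round(base.nY * 0.8)))),
        ("counts+20pct", rep(base, nX=int(round(base.nX * 1.2)),
                             nY=int(round(base.nY * 1.2)))),
        ("N40", rep(base, N=40)),
        ("N60", rep(base, N=60)),
        ("TXage40", rep(base, TX_age=40)),
        ("TXage30", rep(base, TX_age=30)),
        ("TXage20", rep(base, TX_age=20)),
    ]


def robustness_suite(trained_policies: Tuple[PolicyParams, PolicyParams],
                     base_cfg: EnvConfig,
                     variants: Sequence[Tuple[str, EnvConfig]],
                     seeds: Sequence[int],
                     burn_in: Optional[int] = None) -> pd.DataFrame:
    """Run the unchanged trained policies across environment variants.

    For every variant x seed pair, rolls out one episode and reports whether
    both species survived to the step cap, the post-burn-in mean populations,
    and their coefficients of variation.  ``burn_in`` defaults to a quarter
    of the variant's step cap.
    """
    rows = []
    for name, cfg in variants:
        for seed in seeds:
            series, _ = run_episode(trained_policies, cfg, seed)
            bi = burn_in if burn_in is not None else cfg.max_steps // 4
            bi = min(bi, max(len(series) - 1, 0))
            summ = summarize(series, burn_in=bi)
            rows.append({
                "variant": name, "seed": seed,
                "survived": series.termination == "max_steps",
                "steps": int(series.t[-1]),
                "mean_n_predator": summ["predator"]["mean"],
                "mean_n_prey": summ["prey"]["mean"],
                "cv_predator": summ["predator"]["cv"],
                "cv_prey": summ["prey"]["cv"],
                "termination": series.termination,
            })
    return pd.DataFrame(rows, columns=["variant", "seed", "survived", "steps",
                                       "mean_n_predator", "mean_n_prey",
                                       "cv_predator", "cv_prey", "termination"])
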