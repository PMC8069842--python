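"""The toroidal lattice predator-prey ecosystem.

An ``N x N`` periodic grid holds at most one agent per cell.  Within each
environment step every living agent, in one freshly drawn random order,
observes its ``r x r`` neighborhood, samples one of nine moves (the eight
compass directions plus "remain"), and has the move applied immediately:

* a predator moving onto a prey eats it (reward ``+1``), resets its
  starvation clock, and with probability ``bX`` leaves an offspring in the
  vacated cell; moving onto another predator blocks the move;
* a prey moving onto an empty cell succeeds and with probability ``bY``
  leaves an offspring behind; moving onto a predator gets it eaten
  (reward ``-1``, and the predator's starvation clock resets); moving onto
  another prey blocks the move.

After all agents have acted, clocks advance: predators that did not eat gain
one starvation level and are removed on reaching ``TX``; prey age by one step
and are removed on reaching ``TY`` (optionally predators age out at
``TX_age``).  Captures are the only sources of non-zero reward, which makes
the two species' learning problems strictly antagonistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Optional, Set, Tuple

import numpy as np

from .config import EnvConfig
from .errors import InvalidActionError, InvalidConfigError, StaleAgentError

__all__ = [
    "PREDATOR", "PREY", "SPECIES_NAMES", "N_ACTIONS", "ACTION_NAMES",
    "AgentState", "GridState", "StepEvents", "Observation", "TransitionRecord",
    "init_env", "neighbor_cell", "apply_predator_action", "apply_prey_action",
    "advance_clocks", "observe", "flatten_observation", "env_step", "is_terminal",
]

PREDATOR = 0
PREY = 1
SPECIES_NAMES = ("predator", "prey")

# Action encoding: 0 up-left, 1 up, 2 up-right, 3 left, 4 remain, 5 right,
# 6 down-left, 7 down, 8 down-right ("up" decreases the row index).
N_ACTIONS = 9
ACTION_NAMES = (
    "up-left", "up", "up-right", "left", "remain", "right",
    "down-left", "down", "down-right",
)
_DR = np.array([-1, -1, -1, 0, 0, 0, 1, 1, 1], dtype=np.int64)
_DC = np.array([-1, 0, 1, -1, 0, 1, -1, 0, 1], dtype=np.int64)


@dataclass
class StepEvents:
    """Audit counts of the demographic events of one environment step."""

    captures_by_predator_action: int = 0
    captures_by_prey_action: int = 0
    predator_births: int = 0
    prey_births: int = 0
    starvation_deaths: int = 0
    age_deaths: int = 0              # prey removed at age TY
    predator_age_deaths: int = 0     # predators removed at age TX_age (if enabled)

    def as_dict(self) -> Dict[str, int]:
        return asdict(self)

    def __iadd__(self, other: "StepEvents") -> "StepEvents":
        for k, v in other.as_dict().items():
            setattr(self, k, getattr(self, k) + v)
        return self


@dataclass(frozen=True)
class AgentState:
    """Read-only snapshot of one living agent."""

    id: int
    species: str
    position: Tuple[int, int]
    starvation: int
    age: int


@dataclass(frozen=True)
class Observation:
    """The ``r x r x C`` egocentric window a policy conditions on."""

    window: np.ndarray
    species_of_observer: str


@dataclass
class TransitionRecord:
    """One agent-step experience tuple ``(s, a, r, s', done)``."""

    species: int
    obs: np.ndarray
    action: int
    reward: float
    next_obs: Optional[np.ndarray]
    done: bool


def flatten_observation(window: np.ndarray) -> np.ndarray:
    """Flatten an ``(r, r, C)`` window channel-blocked (predator plane first)."""
    return np.ascontiguousarray(np.moveaxis(window, -1, 0)).ravel()


class GridState:
    """Mutable world state: agent arrays plus consistent occupancy maps.

    Agents are stored in flat arrays indexed by a unique, never-reused id.
    ``occupancy[row, col]`` holds the id of the resident agent or ``-1``;
    ``channels`` is the ``C x N x N`` one-hot species view from which
    observations are gathered.
    """

    __slots__ = ("cfg", "t", "pos_r", "pos_c", "species", "starv", "age",
                 "alive", "occupancy", "channels", "_n", "_n_alive",
                 "pending", "_half", "_offsets")

    def __init__(self, cfg: EnvConfig) -> None:
        self.cfg = cfg
        self.t = 0
        cap = max(16, 2 * (cfg.nX + cfg.nY))
        self.pos_r = np.zeros(cap, dtype=np.int64)
        self.pos_c = np.zeros(cap, dtype=np.int64)
        self.species = np.zeros(cap, dtype=np.int8)
        self.starv = np.zeros(cap, dtype=np.int64)
        self.age = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.occupancy = np.full((cfg.N, cfg.N), -1, dtype=np.int64)
        self.channels = np.zeros((2, cfg.N, cfg.N), dtype=np.float64)
        self._n = 0                      # next fresh id
        self._n_alive = [0, 0]           # per-species living counts
        self.pending: Dict[int, list] = {}
        self._half = cfg.r // 2
        self._offsets = np.arange(-self._half, self._half + 1, dtype=np.int64)

    # -- bookkeeping -----------------------------------------------------
    def _grow(self) -> None:
        cap = len(self.pos_r)
        for name in ("pos_r", "pos_c", "species", "starv", "age", "alive"):
            arr = getattr(self, name)
            new = np.zeros(2 * cap, dtype=arr.dtype)
            new[:cap] = arr
            setattr(self, name, new)

    def spawn(self, species: int, row: int, col: int) -> int:
        """Create a newborn (all clocks zero) on an empty cell; returns its id."""
        if self._n >= len(self.pos_r):
            self._grow()
        aid = self._n
        self._n += 1
        self.pos_r[aid] = row
        self.pos_c[aid] = col
        self.species[aid] = species
        self.starv[aid] = 0
        self.age[aid] = 0
        self.alive[aid] = True
        self.occupancy[row, col] = aid
        self.channels[species, row, col] = 1.0
        self._n_alive[species] += 1
        return aid

    def remove(self, aid: int) -> None:
        sp = int(self.species[aid])
        self.alive[aid] = False
        r, c = self.pos_r[aid], self.pos_c[aid]
        self.occupancy[r, c] = -1
        self.channels[sp, r, c] = 0.0
        self._n_alive[sp] -= 1

    def move(self, aid: int, row: int, col: int) -> None:
        sp = int(self.species[aid])
        r0, c0 = self.pos_r[aid], self.pos_c[aid]
        self.occupancy[r0, c0] = -1
        self.channels[sp, r0, c0] = 0.0
        self.pos_r[aid] = row
        self.pos_c[aid] = col
        self.occupancy[row, col] = aid
        self.channels[sp, row, col] = 1.0

    # -- queries ---------------------------------------------------------
    def counts(self) -> Tuple[int, int]:
        """(n_predator, n_prey) currently alive."""
        return self._n_alive[PREDATOR], self._n_alive[PREY]

    def living_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self._n])

    def is_alive(self, aid: int) -> bool:
        return 0 <= aid < self._n and bool(self.alive[aid])

    def agent(self, aid: int) -> AgentState:
        if not self.is_alive(aid):
            raise StaleAgentError(f"agent {aid} is dead or unknown")
        return AgentState(
            id=int(aid),
            species=SPECIES_NAMES[int(self.species[aid])],
            position=(int(self.pos_r[aid]), int(self.pos_c[aid])),
            starvation=int(self.starv[aid]),
            age=int(self.age[aid]),
        )

    def agents(self) -> Iterator[AgentState]:
        for aid in self.living_ids():
            yield self.agent(int(aid))

    def tensor_view(self) -> np.ndarray:
        """The full-grid ``H x W x C`` occupancy tensor (predator channel 0)."""
        return np.moveaxis(self.channels, 0, -1).copy()

    def copy(self) -> "GridState":
        clone = object.__new__(GridState)
        clone.cfg = self.cfg
        clone.t = self.t
        for name in ("pos_r", "pos_c", "species", "starv", "age", "alive",
                     "occupancy", "channels"):
            setattr(clone, name, getattr(self, name).copy())
        clone._n = self._n
        clone._n_alive = list(self._n_alive)
        clone.pending = {k: list(v) for k, v in self.pending.items()}
        clone._half = self._half
        clone._offsets = self._offsets
        return clone


def init_env(cfg: EnvConfig, seed) -> GridState:
    """Place ``nX`` predators and ``nY`` prey uniformly on distinct cells.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  All clocks
    start at zero and the step counter at ``t = 0``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.nX + cfg.nY
    if n > cfg.N * cfg.N:
        raise InvalidConfigError("more agents than cells")
    state = GridState(cfg)
    cells = rng.choice(cfg.N * cfg.N, size=n, replace=False)
    for i, cell in enumerate(cells):
        species = PREDATOR if i < cfg.nX else PREY
        state.spawn(species, int(cell) // cfg.N, int(cell) % cfg.N)
    return state


def neighbor_cell(pos: Tuple[int, int], action: int, N: int) -> Tuple[int, int]:
    """Destination cell of ``action`` from ``pos`` under torus arithmetic."""
    if not 0 <= int(action) <= 8:
        raise InvalidActionError(f"action {action} outside 0..8")
    return (int(pos[0] + _DR[action]) % N, int(pos[1] + _DC[action]) % N)


# ---------------------------------------------------------------------------
# Single-agent dynamics.  The internal _apply_* fast paths skip validation and
# are shared by the public wrappers and env_step.
# ---------------------------------------------------------------------------

def _apply_predator(state: GridState, aid: int, action: int,
                    rng: np.random.Generator, ate: Set[int],
                    ev: StepEvents) -> Tuple[float, int]:
    """Returns (reward, captured_prey_id or -1)."""
    N = state.cfg.N
    r1 = (state.pos_r[aid] + _DR[action]) % N
    c1 = (state.pos_c[aid] + _DC[action]) % N
    if r1 == state.pos_r[aid] and c1 == state.pos_c[aid]:
        return 0.0, -1
    target = state.occupancy[r1, c1]
    if target == -1:
        state.move(aid, r1, c1)
        return 0.0, -1
    if state.species[target] == PREY:
        r0, c0 = int(state.pos_r[aid]), int(state.pos_c[aid])
        state.remove(target)
        state.move(aid, r1, c1)
        state.starv[aid] = 0
        ate.add(aid)
        ev.captures_by_predator_action += 1
        if rng.random() < state.cfg.bX:
            state.spawn(PREDATOR, r0, c0)
            ev.predator_births += 1
        return 1.0, int(target)
    return 0.0, -1  # blocked by another predator


def _apply_prey(state: GridState, aid: int, action: int,
                rng: np.random.Generator, ate: Set[int],
                ev: StepEvents) -> Tuple[float, bool]:
    """Returns (reward, captured_self)."""
    N = state.cfg.N
    r1 = (state.pos_r[aid] + _DR[action]) % N
    c1 = (state.pos_c[aid] + _DC[action]) % N
    if r1 == state.pos_r[aid] and c1 == state.pos_c[aid]:
        return 0.0, False
    target = state.occupancy[r1, c1]
    if target == -1:
        r0, c0 = int(state.pos_r[aid]), int(state.pos_c[aid])
        state.move(aid, r1, c1)
        if rng.random() < state.cfg.bY:
            state.spawn(PREY, r0, c0)
            ev.prey_births += 1
        return 0.0, False
    if state.species[target] == PREDATOR:
        # walked into a predator's jaws: the prey is eaten by its own action
        state.remove(aid)
        state.starv[target] = 0
        ate.add(int(target))
        ev.captures_by_prey_action += 1
        return -1.0, True
    return 0.0, False  # blocked by another prey


def _check_living(state: GridState, aid: int, species: int) -> None:
    if not state.is_alive(aid):
        raise StaleAgentError(f"agent {aid} is dead or unknown")
    if state.species[aid] != species:
        raise StaleAgentError(
            f"agent {aid} is a {SPECIES_NAMES[int(state.species[aid])]}, "
            f"not a {SPECIES_NAMES[species]}"
        )


def apply_predator_action(state: GridState, agent_id: int, action: int,
                          rng: np.random.Generator
                          ) -> Tuple[GridState, float, StepEvents]:
    """Apply one predator move (mutates and returns ``state``)."""
    _check_living(state, agent_id, PREDATOR)
    if not 0 <= int(action) <= 8:
        raise InvalidActionError(f"action {action} outside 0..8")
    ev = StepEvents()
    reward, _ = _apply_predator(state, agent_id, int(action), rng, set(), ev)
    return state, reward, ev


def apply_prey_action(state: GridState, agent_id: int, action: int,
                      rng: np.random.Generator
                      ) -> Tuple[GridState, float, StepEvents]:
    """Apply one prey move (mutates and returns ``state``)."""
    _check_living(state, agent_id, PREY)
    if not 0 <= int(action) <= 8:
        raise InvalidActionError(f"action {action} outside 0..8")
    ev = StepEvents()
    reward, _ = _apply_prey(state, agent_id, int(action), rng, set(), ev)
    return state, reward, ev


def advance_clocks(state: GridState, ate_this_step: Set[int]
                   ) -> Tuple[GridState, StepEvents, List[int]]:
    """Advance starvation/age clocks and remove agents that hit their limits.

    Predators in ``ate_this_step`` keep their (already reset) starvation
    level.  Returns the events delta and the list of removed agent ids.
    """
    cfg = state.cfg
    ev = StepEvents()
    removed: List[int] = []
    ids = state.living_ids()
    for aid in ids:
        aid = int(aid)
        if state.species[aid] == PREDATOR:
            if aid not in ate_this_step:
                state.starv[aid] += 1
                if state.starv[aid] >= cfg.TX:
                    state.remove(aid)
                    ev.starvation_deaths += 1
                    removed.append(aid)
                    continue
            state.age[aid] += 1
            if cfg.TX_age is not None and state.age[aid] >= cfg.TX_age:
                state.remove(aid)
                ev.predator_age_deaths += 1
                removed.append(aid)
        else:
            state.age[aid] += 1
            if state.age[aid] >= cfg.TY:
                state.remove(aid)
                ev.age_deaths += 1
                removed.append(aid)
    return state, ev, removed


def observe(state: GridState, agent_id: int) -> Observation:
    """The ``r x r x C`` window centered on the agent (toroidal wrap).

    With ``obs_padding`` enabled, out-of-grid cells read as empty instead of
    wrapping.  The observer itself appears at the window center in its own
    species channel.
    """
    if not state.is_alive(agent_id):
        raise StaleAgentError(f"agent {agent_id} is dead or unknown")
    cfg = state.cfg
    rows = (state.pos_r[agent_id] + state._offsets) % cfg.N
    cols = (state.pos_c[agent_id] + state._offsets) % cfg.N
    win = state.channels[:, rows[:, None], cols[None, :]].copy()
    if cfg.obs_padding:
        row_raw = state.pos_r[agent_id] + state._offsets
        col_raw = state.pos_c[agent_id] + state._offsets
        win[:, (row_raw < 0) | (row_raw >= cfg.N), :] = 0.0
        win[:, :, (col_raw < 0) | (col_raw >= cfg.N)] = 0.0
    return Observation(window=np.moveaxis(win, 0, -1),
                       species_of_observer=SPECIES_NAMES[int(state.species[agent_id])])


def _gather_flat(state: GridState, aid: int) -> np.ndarray:
    """Fast flattened observation (channel-blocked, predator plane first)."""
    cfg = state.cfg
    rows = (state.pos_r[aid] + state._offsets) % cfg.N
    cols = (state.pos_c[aid] + state._offsets) % cfg.N
    win = state.channels[:, rows[:, None], cols[None, :]]
    if cfg.obs_padding:
        win = win.copy()
        row_raw = state.pos_r[aid] + state._offsets
        col_raw = state.pos_c[aid] + state._offsets
        win[:, (row_raw < 0) | (row_raw >= cfg.N), :] = 0.0
        win[:, :, (col_raw < 0) | (col_raw >= cfg.N)] = 0.0
    return win.reshape(-1).astype(np.float32)


def env_step(state: GridState, policy_pred, policy_prey,
             rng: np.random.Generator, collect: bool = True
             ) -> Tuple[GridState, List[TransitionRecord], StepEvents]:
    """Advance the world by one step under the two species policies.

    One uniformly random permutation over all living agents is drawn; each
    agent in turn observes, samples its action from its species policy, and
    the action is applied immediately (so later movers see earlier moves).
    Afterwards the clocks advance and ``t`` increments.

    With ``collect=True`` the step returns the experience tuples *completed*
    during it: an agent's record opened at its previous turn is closed by its
    current observation, and agents removed mid-step (captured, starved or
    aged out) close their record with ``done=True`` and no successor
    observation.  Policies must expose ``act(flat_obs, rng) -> int``.
    """
    ev = StepEvents()
    ate: Set[int] = set()
    records: List[TransitionRecord] = []
    pending = state.pending
    order = rng.permutation(state.living_ids())

    for aid in order:
        aid = int(aid)
        if not state.alive[aid]:
            continue  # captured earlier in this step; record closed below
        sp = int(state.species[aid])
        obs = _gather_flat(state, aid)
        if collect and aid in pending:
            prev = pending.pop(aid)
            records.append(TransitionRecord(sp, prev[0], prev[1], prev[2], obs, False))
        if sp == PREDATOR:
            action = policy_pred.act(obs, rng)
            reward, captured = _apply_predator(state, aid, action, rng, ate, ev)
            if collect:
                pending[aid] = [obs, action, reward]
                if captured >= 0 and captured in pending:
                    # the captured prey's open record closes with the -1
                    # capture penalty folded into its last action
                    prev = pending.pop(captured)
                    records.append(TransitionRecord(PREY, prev[0], prev[1],
                                                    prev[2] - 1.0, None, True))
        else:
            action = policy_prey.act(obs, rng)
            reward, captured_self = _apply_prey(state, aid, action, rng, ate, ev)
            if collect:
                if captured_self:
                    records.append(TransitionRecord(PREY, obs, action, reward,
                                                    None, True))
                else:
                    pending[aid] = [obs, action, reward]

    state, clock_ev, removed = advance_clocks(state, ate)
    ev += clock_ev
    if collect:
        for aid in removed:
            if aid in pending:
                prev = pending.pop(aid)
                records.append(TransitionRecord(int(state.species[aid]), prev[0],
                                                prev[1], prev[2], None, True))
    state.t += 1
    return state, records, ev


def is_terminal(state: GridState) -> Tuple[bool, Optional[str]]:
    """Episode end test: extinction of either species, or the step cap."""
    n_pred, n_prey = state.counts()
    if n_pred == 0 or n_prey == 0:
        return True, "extinction"
    if state.t >= state.cfg.max_steps:
        return True, "max_steps"
    return False, None
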