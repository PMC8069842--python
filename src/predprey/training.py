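"""Co-evolution of the two species by iterated approximate best responses.

Each species is trained off-policy against the other's frozen policy.  The
critic minimizes the regularized primal objective

    L(Q) = (1 - gamma) * E_{s0, a0~pi}[Q(s0, a0)]
         + E_{(s,a,r,s') ~ D}[ f*( r + gamma * E_{a'~pi}[Q(s',a')] - Q(s,a) ) ]

with the convex conjugate f*(y) = y^2/2 of the half-square regularizer
f(x) = x^2/2; minimizing L over Q estimates the (divergence-regularized)
discounted return of the policy from arbitrary replay data.  The actor then
ascends the same objective by policy gradient (the expectation over the nine
discrete actions is computed exactly rather than sampled), plus a weighted
Shannon-entropy bonus that keeps exploration alive.  The outer loop iterates:
best-response stage for each species, a sampling horizon of fresh environment
steps appended to the replay buffer, and a policy-strengthening gradient
update, until the stopping criterion (an iteration cap) is met.

A tabular epsilon-greedy Q-learning baseline over the same observation
encoding is provided for comparison runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import EnvConfig, TrainConfig
from .errors import NoDataError, PredPreyError
from .gridworld import (N_ACTIONS, PREDATOR, PREY, SPECIES_NAMES, GridState,
                        TransitionRecord, _gather_flat, env_step, init_env,
                        is_terminal)
from .nn import MLP, AdamW, softmax
from .policies import PolicyParams
from .rng import seed_streams

__all__ = [
    "CriticParams", "ReplayBuffer", "SpeciesLearner",
    "f_conjugate", "bellman_residual", "algaedice_objective",
    "critic_update", "actor_update", "best_response_update", "coevolve",
    "TabularQ", "dqn_baseline_update", "EpsilonGreedyPolicy", "train_dqn",
]


def f_conjugate(y: np.ndarray) -> np.ndarray:
    """Convex conjugate f*(y) = y^2/2 of the regularizer f(x) = x^2/2."""
    y = np.asarray(y, dtype=float)
    return 0.5 * y * y


class CriticParams:
    """State-action value network Q(s, .) of one species (nine outputs)."""

    def __init__(self, species: str, input_dim: int,
                 hidden: Tuple[int, int] = (64, 64),
                 rng: Optional[np.random.Generator] = None) -> None:
        if species not in SPECIES_NAMES:
            raise PredPreyError(f"unknown species {species!r}")
        self.species = species
        self.input_dim = int(input_dim)
        self.hidden = tuple(int(h) for h in hidden)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.net = MLP([self.input_dim, *self.hidden, N_ACTIONS], rng)

    @property
    def weights(self) -> np.ndarray:
        return self.net.get_flat()

    @weights.setter
    def weights(self, flat: np.ndarray) -> None:
        self.net.set_flat(np.asarray(flat, dtype=float))


class ReplayBuffer:
    """Capacity-bounded FIFO store of per-agent transitions, split by species.

    Also keeps a sample of episode-start observations per species, used for
    the ``(1 - gamma) * E[Q(s0, a0)]`` term of the objective.
    """

    def __init__(self, capacity: int, obs_dim: int,
                 init_capacity: int = 8192) -> None:
        self.capacity = int(capacity)
        self.obs_dim = int(obs_dim)
        self._store = {}
        for sp in (PREDATOR, PREY):
            self._store[sp] = {
                "obs": np.zeros((self.capacity, self.obs_dim), dtype=np.float32),
                "action": np.zeros(self.capacity, dtype=np.int64),
                "reward": np.zeros(self.capacity, dtype=np.float64),
                "next_obs": np.zeros((self.capacity, self.obs_dim), dtype=np.float32),
                "done": np.zeros(self.capacity, dtype=bool),
                "head": 0, "size": 0,
            }
        self._init = {sp: {"obs": np.zeros((init_capacity, self.obs_dim),
                                           dtype=np.float32),
                           "head": 0, "size": 0} for sp in (PREDATOR, PREY)}

    def __len__(self) -> int:
        return sum(self._store[sp]["size"] for sp in (PREDATOR, PREY))

    def size(self, species: int) -> int:
        return self._store[species]["size"]

    def add(self, records: Sequence[TransitionRecord]) -> None:
        for rec in records:
            st = self._store[rec.species]
            i = st["head"]
            st["obs"][i] = rec.obs
            st["action"][i] = rec.action
            st["reward"][i] = rec.reward
            if rec.next_obs is None:
                st["next_obs"][i] = 0.0
            else:
                st["next_obs"][i] = rec.next_obs
            st["done"][i] = rec.done
            st["head"] = (i + 1) % self.capacity
            st["size"] = min(st["size"] + 1, self.capacity)

    def add_initial_obs(self, species: int, obs_batch: np.ndarray) -> None:
        ini = self._init[species]
        for row in np.atleast_2d(obs_batch):
            i = ini["head"]
            ini["obs"][i] = row
            ini["head"] = (i + 1) % len(ini["obs"])
            ini["size"] = min(ini["size"] + 1, len(ini["obs"]))

    def sample(self, species: int, batch_size: int,
               rng: np.random.Generator) -> Dict[str, np.ndarray]:
        st = self._store[species]
        if st["size"] == 0:
            raise NoDataError(f"no {SPECIES_NAMES[species]} records in buffer")
        idx = rng.integers(st["size"], size=batch_size)
        return {k: st[k][idx] for k in ("obs", "action", "reward", "next_obs", "done")}

    def sample_initial(self, species: int, batch_size: int,
                       rng: np.random.Generator) -> np.ndarray:
        ini = self._init[species]
        if ini["size"] == 0:
            raise NoDataError(f"no initial {SPECIES_NAMES[species]} observations")
        idx = rng.integers(ini["size"], size=batch_size)
        return ini["obs"][idx]


# ---------------------------------------------------------------------------
# Objective and gradients
# ---------------------------------------------------------------------------

def _policy_probs(policy: PolicyParams, X: np.ndarray) -> np.ndarray:
    logits, _ = policy.net.forward_batch(X)
    return softmax(logits)


def bellman_residual(critic: CriticParams, policy: PolicyParams,
                     rec: TransitionRecord, gamma: float) -> float:
    """One-sample residual r + gamma * E_{a'~pi}[Q(s',a')] - Q(s,a).

    The expectation over the successor action is an exact nine-way sum;
    terminal records use zero continuation value.
    """
    sp = SPECIES_NAMES[rec.species] if isinstance(rec.species, (int, np.integer)) \
        else rec.species
    if critic.species != sp or policy.species != sp:
        raise PredPreyError("record species does not match the networks")
    q = critic.net.forward(np.asarray(rec.obs, dtype=float))
    cont = 0.0
    if not rec.done and rec.next_obs is not None:
        qn = critic.net.forward(np.asarray(rec.next_obs, dtype=float))
        pn = softmax(policy.net.forward(np.asarray(rec.next_obs, dtype=float)))
        cont = float(pn @ qn)
    return float(rec.reward + gamma * cont - q[rec.action])


def _batch_residual(critic: CriticParams, policy: PolicyParams,
                    batch: Dict[str, np.ndarray], gamma: float):
    """Vectorized residuals plus the forward caches needed for backprop."""
    Q, cache_s = critic.net.forward_batch(batch["obs"].astype(np.float64))
    Qn, cache_sn = critic.net.forward_batch(batch["next_obs"].astype(np.float64))
    Pn = _policy_probs(policy, batch["next_obs"].astype(np.float64))
    live = ~batch["done"]
    cont = np.where(live, np.sum(Pn * Qn, axis=1), 0.0)
    qa = Q[np.arange(len(Q)), batch["action"]]
    delta = batch["reward"] + gamma * cont - qa
    return delta, Q, Qn, Pn, cache_s, cache_sn, live


def algaedice_objective(critic: CriticParams, policy: PolicyParams,
                        batch: Dict[str, np.ndarray], init_obs: np.ndarray,
                        gamma: float) -> float:
    """The regularized primal objective L(Q) on a replay batch.

    ``batch`` is a dict of arrays (keys ``obs, action, reward, next_obs,
    done``); ``init_obs`` is a sample of episode-start observations.
    """
    if len(batch["obs"]) == 0 or len(init_obs) == 0:
        raise NoDataError("objective needs a nonempty batch and initial sample")
    delta, *_ = _batch_residual(critic, policy, batch, gamma)
    Q0, _ = critic.net.forward_batch(np.asarray(init_obs, dtype=np.float64))
    P0 = _policy_probs(policy, np.asarray(init_obs, dtype=np.float64))
    init_term = (1.0 - gamma) * float(np.mean(np.sum(P0 * Q0, axis=1)))
    return init_term + float(np.mean(f_conjugate(delta)))


def critic_update(critic: CriticParams, policy: PolicyParams,
                  batch: Dict[str, np.ndarray], init_obs: np.ndarray,
                  gamma: float, opt: AdamW) -> float:
    """One descent step of the critic on L(Q); returns the loss value."""
    B = len(batch["obs"])
    delta, Q, Qn, Pn, cache_s, cache_sn, live = _batch_residual(
        critic, policy, batch, gamma)
    X0 = np.asarray(init_obs, dtype=np.float64)
    Q0, cache_s0 = critic.net.forward_batch(X0)
    P0 = _policy_probs(policy, X0)
    B0 = len(X0)

    G_s = np.zeros_like(Q)
    G_s[np.arange(B), batch["action"]] = -delta / B
    G_sn = (gamma * delta * live)[:, None] * Pn / B
    G_s0 = (1.0 - gamma) * P0 / B0

    grads = critic.net.backward(cache_s, G_s)
    for g, g2 in zip(grads, critic.net.backward(cache_sn, G_sn)):
        g += g2
    for g, g2 in zip(grads, critic.net.backward(cache_s0, G_s0)):
        g += g2
    opt.step(critic.net.params, grads)
    init_term = (1.0 - gamma) * float(np.mean(np.sum(P0 * Q0, axis=1)))
    return init_term + float(np.mean(f_conjugate(delta)))


def _softmax_backprop_coeff(P: np.ndarray, V: np.ndarray) -> np.ndarray:
    """d/dlogits of sum_a pi(a) * V(a) for each row: pi_k (V_k - E_pi V)."""
    return P * (V - np.sum(P * V, axis=1, keepdims=True))


def actor_update(policy: PolicyParams, critic: CriticParams,
                 batch: Dict[str, np.ndarray], init_obs: np.ndarray,
                 gamma: float, entropy_coef: float, opt: AdamW) -> float:
    """One ascent step of the policy on L + entropy bonus; returns the value.

    The gradient treats the critic as fixed (detached); the residual enters
    only through its exact dependence on the successor-action distribution.
    """
    X = batch["obs"].astype(np.float64)
    Xn = batch["next_obs"].astype(np.float64)
    X0 = np.asarray(init_obs, dtype=np.float64)
    B, B0 = len(X), len(X0)

    Q, _ = critic.net.forward_batch(X)
    Qn, _ = critic.net.forward_batch(Xn)
    Q0, _ = critic.net.forward_batch(X0)

    logits_n, cache_n = policy.net.forward_batch(Xn)
    Pn = softmax(logits_n)
    logits_0, cache_0 = policy.net.forward_batch(X0)
    P0 = softmax(logits_0)
    logits_s, cache_s = policy.net.forward_batch(X)
    Ps = softmax(logits_s)

    live = ~batch["done"]
    cont = np.where(live, np.sum(Pn * Qn, axis=1), 0.0)
    qa = Q[np.arange(B), batch["action"]]
    delta = batch["reward"] + gamma * cont - qa

    # d/dlogits of the objective, row by row
    G0 = (1.0 - gamma) / B0 * _softmax_backprop_coeff(P0, Q0)
    Gn = (gamma * delta * live / B)[:, None] * _softmax_backprop_coeff(Pn, Qn)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(Ps > 0, np.log(Ps), 0.0)
    H = -np.sum(Ps * logP, axis=1)
    Gh = entropy_coef / B * (-Ps * (logP + H[:, None]))

    grads = policy.net.backward(cache_0, G0)
    for g, g2 in zip(grads, policy.net.backward(cache_n, Gn)):
        g += g2
    for g, g2 in zip(grads, policy.net.backward(cache_s, Gh)):
        g += g2
    # ascend: optimizer minimizes, so flip the sign
    opt.step(policy.net.params, [-g for g in grads])
    value = (1.0 - gamma) * float(np.mean(np.sum(P0 * Q0, axis=1))) \
        + float(np.mean(f_conjugate(delta))) + entropy_coef * float(np.mean(H))
    return value


# ---------------------------------------------------------------------------
# Best-response stage and outer loop
# ---------------------------------------------------------------------------

@dataclass
class SpeciesLearner:
    """Policy + critic of one species with their optimizer state."""

    policy: PolicyParams
    critic: CriticParams
    actor_opt: AdamW
    critic_opt: AdamW
    last_losses: Tuple[float, float] = (float("nan"), float("nan"))

    @classmethod
    def fresh(cls, species: str, input_dim: int, cfg: TrainConfig,
              rng: np.random.Generator) -> "SpeciesLearner":
        policy = PolicyParams(species, input_dim, cfg.hidden, rng)
        critic = CriticParams(species, input_dim, cfg.hidden, rng)
        return cls(policy, critic,
                   AdamW(policy.net.params, lr=cfg.actor_lr_for(species),
                         weight_decay=1e-4),
                   AdamW(critic.net.params, lr=cfg.critic_lr, weight_decay=1e-4))


def best_response_update(learner, opponent: PolicyParams,
                         buffer: ReplayBuffer, cfg: TrainConfig,
                         rng: np.random.Generator,
                         n_steps: Optional[int] = None):
    """Train one species toward a best response, opponent frozen.

    ``learner`` is a :class:`SpeciesLearner` or a ``(PolicyParams,
    CriticParams)`` pair (fresh optimizers are created for a bare pair).
    Performs ``n_steps`` (default ``cfg.n_inner_steps``) interleaved critic
    descent / actor ascent steps on replay batches of the learner's species.
    The opponent's parameters are never touched.
    """
    if isinstance(learner, tuple):
        policy, critic = learner
        learner = SpeciesLearner(
            policy, critic,
            AdamW(policy.net.params, lr=cfg.actor_lr_for(policy.species),
                  weight_decay=1e-4),
            AdamW(critic.net.params, lr=cfg.critic_lr, weight_decay=1e-4))
    species = SPECIES_NAMES.index(learner.policy.species)
    if buffer.size(species) == 0:
        raise NoDataError(f"no {learner.policy.species} data in buffer")
    n_steps = cfg.n_inner_steps if n_steps is None else n_steps
    critic_loss = actor_value = float("nan")
    for _ in range(n_steps):
        batch = buffer.sample(species, cfg.batch_size, rng)
        init_obs = buffer.sample_initial(species, min(cfg.batch_size, 64), rng)
        critic_loss = critic_update(learner.critic, learner.policy, batch,
                                    init_obs, cfg.gamma, learner.critic_opt)
        actor_value = actor_update(learner.policy, learner.critic, batch,
                                   init_obs, cfg.gamma, cfg.entropy_coef,
                                   learner.actor_opt)
    learner.last_losses = (critic_loss, actor_value)
    return learner


def _record_initial_obs(state: GridState, buffer: ReplayBuffer) -> None:
    for aid in state.living_ids():
        buffer.add_initial_obs(int(state.species[aid]),
                               _gather_flat(state, int(aid)))


def _collect(state: GridState, pred_policy, prey_policy, buffer: ReplayBuffer,
             env_cfg: EnvConfig, h: int, rng_rollout: np.random.Generator,
             rng_place: np.random.Generator) -> Tuple[GridState, Dict]:
    """Run ``h`` environment steps, restarting episodes on termination."""
    n_pred_sum = n_prey_sum = terminations = 0
    for _ in range(h):
        state, records, _ = env_step(state, pred_policy, prey_policy,
                                     rng_rollout, collect=True)
        buffer.add(records)
        n_pred, n_prey = state.counts()
        n_pred_sum += n_pred
        n_prey_sum += n_prey
        terminal, _reason = is_terminal(state)
        if terminal:
            terminations += 1
            state = init_env(env_cfg, rng_place)
            _record_initial_obs(state, buffer)
    stats = {"mean_n_predator": n_pred_sum / h, "mean_n_prey": n_prey_sum / h,
             "terminations": terminations}
    return state, stats


def coevolve(env_cfg: EnvConfig, cfg: TrainConfig,
             progress: bool = False
             ) -> Tuple[PolicyParams, PolicyParams, List[Dict]]:
    """Run the full co-evolution procedure.

    Initializes both species' networks, resets the replay buffer and the
    episode, then iterates: a best-response stage for prey and for predators
    (each against the other's frozen policy), collection of ``cfg.h`` fresh
    environment steps into the buffer (episodes restart on extinction or the
    step cap), and one strengthening policy-gradient update per species.
    Stops after ``cfg.n_iterations`` outer iterations.

    Returns the trained predator policy, prey policy, and a history list with
    one record per outer iteration (losses, mean populations, terminations).
    """
    streams = seed_streams(cfg.seed)
    obs_dim = env_cfg.obs_dim
    pred = SpeciesLearner.fresh("predator", obs_dim, cfg, streams["policy_init"])
    prey = SpeciesLearner.fresh("prey", obs_dim, cfg, streams["policy_init"])
    history: List[Dict] = []
    if cfg.n_iterations == 0:
        return pred.policy, prey.policy, history

    buffer = ReplayBuffer(cfg.buffer_capacity, obs_dim)
    state = init_env(env_cfg, streams["placement"])
    _record_initial_obs(state, buffer)
    # seed the buffer so the first best-response stage has data to learn from
    state, _ = _collect(state, pred.policy, prey.policy, buffer, env_cfg,
                        cfg.h, streams["rollout"], streams["placement"])

    iterator = range(cfg.n_iterations)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="coevolve")
    for it in iterator:
        t0 = time.perf_counter()
        best_response_update(prey, pred.policy, buffer, cfg, streams["training"])
        best_response_update(pred, prey.policy, buffer, cfg, streams["training"])
        state, stats = _collect(state, pred.policy, prey.policy, buffer,
                                env_cfg, cfg.h, streams["rollout"],
                                streams["placement"])
        # strengthening gradient update for both policy networks
        for learner in (prey, pred):
            sp = SPECIES_NAMES.index(learner.policy.species)
            batch = buffer.sample(sp, cfg.batch_size, streams["training"])
            init_obs = buffer.sample_initial(sp, 64, streams["training"])
            actor_update(learner.policy, learner.critic, batch, init_obs,
                         cfg.gamma, cfg.entropy_coef, learner.actor_opt)
        history.append({
            "iteration": it,
            "critic_loss_predator": pred.last_losses[0],
            "actor_value_predator": pred.last_losses[1],
            "critic_loss_prey": prey.last_losses[0],
            "actor_value_prey": prey.last_losses[1],
            "buffer_size": len(buffer),
            "wall_time_s": time.perf_counter() - t0,
            **stats,
        })
    return pred.policy, prey.policy, history


# ---------------------------------------------------------------------------
# Deep-Q-style baseline (tabular over the same observation encoding)
# ---------------------------------------------------------------------------

class TabularQ:
    """Q table keyed by the byte pattern of the (binary) observation."""

    def __init__(self, species: str, n_actions: int = N_ACTIONS) -> None:
        self.species = species
        self.n_actions = n_actions
        self.table: Dict[bytes, np.ndarray] = {}

    def _key(self, obs: np.ndarray) -> bytes:
        return np.asarray(obs, dtype=np.int8).tobytes()

    def q_values(self, obs: np.ndarray) -> np.ndarray:
        return self.table.setdefault(self._key(obs), np.zeros(self.n_actions))

    def get(self, obs: np.ndarray, action: int) -> float:
        return float(self.q_values(obs)[action])


def dqn_baseline_update(qnet: TabularQ, rec: TransitionRecord,
                        alpha: float, gamma: float) -> TabularQ:
    """The comparison method's printed update rule:

    ``Q(s,a) <- (1-alpha) Q(s,a) + alpha [r + gamma max_a' Q(s',a')]``

    with zero continuation on terminal records.
    """
    q = qnet.q_values(rec.obs)
    target = rec.reward
    if not rec.done and rec.next_obs is not None:
        target = rec.reward + gamma * float(np.max(qnet.q_values(rec.next_obs)))
    q[rec.action] = (1.0 - alpha) * q[rec.action] + alpha * target
    return qnet


class EpsilonGreedyPolicy:
    """Epsilon-greedy behavior policy over a tabular Q function."""

    def __init__(self, qnet: TabularQ, epsilon: float = 0.05) -> None:
        self.qnet = qnet
        self.species = qnet.species
        self.epsilon = epsilon

    def act(self, flat_obs: np.ndarray, rng: np.random.Generator) -> int:
        if rng.random() < self.epsilon:
            return int(rng.integers(self.qnet.n_actions))
        q = self.qnet.q_values(flat_obs)
        best = np.flatnonzero(q == q.max())
        return int(best[0]) if len(best) == 1 else int(rng.choice(best))


def train_dqn(env_cfg: EnvConfig, n_steps: int = 2000, seed: int = 0,
              alpha_pred: float = 1e-5, alpha_prey: float = 1e-3,
              epsilon: float = 0.05, gamma: float = 0.99
              ) -> Tuple[EpsilonGreedyPolicy, EpsilonGreedyPolicy, List[Dict]]:
    """Train both species online with the tabular Q baseline.

    Default learning rates follow the comparison setup: 1e-5 for predators
    and 1e-3 for prey, with epsilon = 0.05 exploration.
    """
    streams = seed_streams(seed)
    q_pred = TabularQ("predator")
    q_prey = TabularQ("prey")
    pol_pred = EpsilonGreedyPolicy(q_pred, epsilon)
    pol_prey = EpsilonGreedyPolicy(q_prey, epsilon)
    state = init_env(env_cfg, streams["placement"])
    history: List[Dict] = []
    for _ in range(n_steps):
        state, records, _ = env_step(state, pol_pred, pol_prey,
                                     streams["rollout"], collect=True)
        for rec in records:
            if rec.species == PREDATOR:
                dqn_baseline_update(q_pred, rec, alpha_pred, gamma)
            else:
                dqn_baseline_update(q_prey, rec, alpha_prey, gamma)
        n_pred, n_prey = state.counts()
        history.append({"t": state.t, "n_predator": n_pred, "n_prey": n_prey})
        terminal, _reason = is_terminal(state)
        if terminal:
            state = init_env(env_cfg, streams["placement"])
    return pol_pred, pol_prey, history
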