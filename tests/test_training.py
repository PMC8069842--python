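"""Training-stack tests: objective math against linear-solve oracles,
best-response mechanics, co-evolution loop accounting, and the Q baseline."""

import dataclasses

import numpy as np
import pytest

import predprey as pp
from predprey.gridworld import PREY, TransitionRecord
from predprey.nn import AdamW, softmax
from predprey.policies import PolicyParams
from predprey.training import (CriticParams, ReplayBuffer, SpeciesLearner,
                               TabularQ, actor_update, algaedice_objective,
                               bellman_residual, best_response_update,
                               critic_update, dqn_baseline_update, f_conjugate)

N_ACTIONS = 9


# ---------------------------------------------------------------------------
# Tabular MDP harness: deterministic transitions, one-hot state observations
# ---------------------------------------------------------------------------

class TabularMDP:
    """Random deterministic MDP whose policy is read off an actual network."""

    def __init__(self, n_states, gamma, seed, reward_scale=1.0):
        rng = np.random.default_rng(seed)
        self.nS, self.gamma = n_states, gamma
        self.T = rng.integers(n_states, size=(n_states, N_ACTIONS))
        self.R = reward_scale * rng.random((n_states, N_ACTIONS))
        self.obs = np.eye(n_states)
        self.policy = PolicyParams("prey", n_states, hidden=(16, 16),
                                   rng=np.random.default_rng(seed + 1))
        # mildly non-uniform policy
        self.policy.weights = self.policy.weights + \
            0.1 * np.random.default_rng(seed + 2).normal(size=self.policy.weights.size)
        logits, _ = self.policy.net.forward_batch(self.obs)
        self.pi = softmax(logits)                       # (nS, 9)
        self.mu0 = np.full(n_states, 1 / n_states)      # uniform start states

    def records(self):
        """One record per (s, a) pair: the uniform data distribution dD."""
        out = []
        for s in range(self.nS):
            for a in range(N_ACTIONS):
                out.append(TransitionRecord(
                    PREY, self.obs[s].astype(np.float32), a,
                    float(self.R[s, a]),
                    self.obs[self.T[s, a]].astype(np.float32), False))
        return out

    def batch(self):
        recs = self.records()
        return {
            "obs": np.stack([r.obs for r in recs]),
            "action": np.array([r.action for r in recs]),
            "reward": np.array([r.reward for r in recs]),
            "next_obs": np.stack([r.next_obs for r in recs]),
            "done": np.zeros(len(recs), dtype=bool),
        }

    # -- dense linear-algebra oracles -----------------------------------
    def p_matrix(self):
        n = self.nS * N_ACTIONS
        P = np.zeros((n, n))
        for s in range(self.nS):
            for a in range(N_ACTIONS):
                s2 = self.T[s, a]
                P[s * N_ACTIONS + a, s2 * N_ACTIONS:(s2 + 1) * N_ACTIONS] = \
                    self.pi[s2]
        return P

    def exact_q(self):
        M = np.eye(self.nS * N_ACTIONS) - self.gamma * self.p_matrix()
        return np.linalg.solve(M, self.R.ravel()).reshape(self.nS, N_ACTIONS)

    def exact_return(self):
        """rho(pi) by exact policy evaluation."""
        mu = (self.mu0[:, None] * self.pi).ravel()
        return (1 - self.gamma) * float(mu @ self.exact_q().ravel())

    def occupancy(self):
        """Normalized discounted state-action occupancy of the policy."""
        mu = (self.mu0[:, None] * self.pi).ravel()
        n = self.nS * N_ACTIONS
        return (1 - self.gamma) * np.linalg.solve(
            np.eye(n) - self.gamma * self.p_matrix().T, mu)

    def minimized_objective_oracle(self):
        """Closed-form minimum of the regularized primal objective when the
        data distribution is uniform over all (s, a) pairs."""
        n = self.nS * N_ACTIONS
        dD = np.full(n, 1 / n)
        w = self.occupancy() / dD
        return self.exact_return() - 0.5 * float(dD @ (w ** 2))


def zeroed_critic(n_inputs, species="prey"):
    """Critic whose output is exactly zero everywhere."""
    critic = CriticParams(species, n_inputs, hidden=(16, 16),
                          rng=np.random.default_rng(0))
    critic.net.params[4][:] = 0.0
    critic.net.params[5][:] = 0.0
    return critic


# ---------------------------------------------------------------------------
# Convex conjugate
# ---------------------------------------------------------------------------

def test_f_conjugate_by_grid_search():
    """f*(y) = max_x [x y - f(x)] for f(x) = x^2/2, checked by enumeration."""
    xs = np.linspace(-20, 20, 200_001)
    for y in np.random.default_rng(0).normal(0, 3, size=8):
        brute = np.max(xs * y - 0.5 * xs ** 2)
        assert f_conjugate(y) == pytest.approx(brute, abs=1e-6)


# ---------------------------------------------------------------------------
# Bellman residual
# ---------------------------------------------------------------------------

def test_residual_gamma_zero_substitution():
    critic = zeroed_critic(3)
    policy = PolicyParams("prey", 3, hidden=(16, 16),
                          rng=np.random.default_rng(1))
    rec = TransitionRecord(PREY, np.eye(3)[0], 2, 1.0, np.eye(3)[1], False)
    assert bellman_residual(critic, policy, rec, gamma=0.0) == pytest.approx(1.0)


def test_residual_fixed_point_single_state():
    """With Q = r/(1-gamma) constant, the residual vanishes."""
    gamma, r = 0.7, 0.4
    critic = zeroed_critic(1)
    critic.net.params[5][:] = r / (1 - gamma)   # constant output via bias
    policy = PolicyParams("prey", 1, hidden=(16, 16),
                          rng=np.random.default_rng(1))
    rec = TransitionRecord(PREY, np.ones(1), 0, r, np.ones(1), False)
    assert bellman_residual(critic, policy, rec, gamma) == pytest.approx(0.0, abs=1e-12)


def test_residual_matches_dense_oracle():
    """Per-record residuals equal the dense matrix computation."""
    mdp = TabularMDP(3, gamma=0.8, seed=4)
    critic = CriticParams("prey", 3, hidden=(16, 16),
                          rng=np.random.default_rng(9))
    Q, _ = critic.net.forward_batch(mdp.obs)        # dense Q table (nS, 9)
    oracle = mdp.R + mdp.gamma * (mdp.pi[mdp.T] * Q[mdp.T]).sum(-1) - Q
    for rec in mdp.records():
        s = int(np.argmax(rec.obs))
        got = bellman_residual(critic, mdp.policy, rec, mdp.gamma)
        assert got == pytest.approx(oracle[s, rec.action], abs=1e-9)


def test_residual_species_mismatch_rejected():
    critic = zeroed_critic(3, species="prey")
    policy = PolicyParams("predator", 3, hidden=(16, 16),
                          rng=np.random.default_rng(1))
    rec = TransitionRecord(PREY, np.eye(3)[0], 0, 0.0, None, True)
    with pytest.raises(pp.PredPreyError):
        bellman_residual(critic, policy, rec, 0.9)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def test_objective_single_record_closed_form():
    """gamma=0, Q=0, one record with reward 1: objective is f*(1) = 0.5."""
    critic = zeroed_critic(3)
    policy = PolicyParams("prey", 3, hidden=(16, 16),
                          rng=np.random.default_rng(1))
    batch = {"obs": np.eye(3)[:1], "action": np.array([0]),
             "reward": np.array([1.0]), "next_obs": np.eye(3)[1:2],
             "done": np.zeros(1, dtype=bool)}
    val = algaedice_objective(critic, policy, batch, np.eye(3)[:1], gamma=0.0)
    assert val == pytest.approx(0.5)


def test_objective_zero_case():
    critic = zeroed_critic(3)
    policy = PolicyParams("prey", 3, hidden=(16, 16),
                          rng=np.random.default_rng(1))
    batch = {"obs": np.eye(3), "action": np.array([0, 1, 2]),
             "reward": np.zeros(3), "next_obs": np.eye(3),
             "done": np.zeros(3, dtype=bool)}
    assert algaedice_objective(critic, policy, batch, np.eye(3), 0.9) == \
        pytest.approx(0.0)


def test_objective_rejects_empty_batch():
    critic = zeroed_critic(3)
    policy = PolicyParams("prey", 3, hidden=(16, 16),
                          rng=np.random.default_rng(1))
    empty = {"obs": np.zeros((0, 3)), "action": np.zeros(0, dtype=int),
             "reward": np.zeros(0), "next_obs": np.zeros((0, 3)),
             "done": np.zeros(0, dtype=bool)}
    with pytest.raises(pp.NoDataError):
        algaedice_objective(critic, policy, empty, np.eye(3), 0.9)


def minimize_critic(mdp, n_steps=4000, lr=5e-3):
    critic = CriticParams("prey", mdp.nS, hidden=(16, 16),
                          rng=np.random.default_rng(5))
    opt = AdamW(critic.net.params, lr=lr)
    batch, init_obs = mdp.batch(), mdp.obs
    for _ in range(n_steps):
        critic_update(critic, mdp.policy, batch, init_obs, mdp.gamma, opt)
    return critic


@pytest.mark.parametrize("seed", [0, 1])
def test_minimized_objective_matches_linear_solve_oracle(seed):
    """Descending the critic to convergence on an enumerated tabular MDP
    reproduces the closed-form minimum of the regularized return objective
    (exact return minus the half-squared-occupancy-ratio term)."""
    mdp = TabularMDP(3, gamma=0.8, seed=seed, reward_scale=0.5)
    critic = minimize_critic(mdp)
    val = algaedice_objective(critic, mdp.policy, mdp.batch(), mdp.obs,
                              mdp.gamma)
    assert val == pytest.approx(mdp.minimized_objective_oracle(), abs=1e-3)


# ---------------------------------------------------------------------------
# Updates: null steps, detachment, improvement, entropy
# ---------------------------------------------------------------------------

def env_buffer(env_cfg, n_steps=60, seed=0):
    from predprey.policies import RandomPolicy
    buf = ReplayBuffer(50_000, env_cfg.obs_dim)
    state = pp.init_env(env_cfg, seed)
    from predprey.training import _record_initial_obs
    _record_initial_obs(state, buf)
    rng = np.random.default_rng(seed)
    pols = (RandomPolicy("predator"), RandomPolicy("prey"))
    for _ in range(n_steps):
        state, recs, _ = pp.env_step(state, *pols, rng)
        buf.add(recs)
    return buf


def test_zero_learning_rates_leave_parameters_unchanged(tiny_env):
    buf = env_buffer(tiny_env)
    cfg = pp.TrainConfig(n_inner_steps=3, actor_lr=0.0, critic_lr=0.0,
                         actor_lr_predator=None, actor_lr_prey=None)
    learner = SpeciesLearner.fresh("prey", tiny_env.obs_dim, cfg,
                                   np.random.default_rng(0))
    w_pol, w_cri = learner.policy.weights, learner.critic.weights
    opponent = PolicyParams("predator", tiny_env.obs_dim,
                            rng=np.random.default_rng(1))
    best_response_update(learner, opponent, buf, cfg, np.random.default_rng(2))
    np.testing.assert_array_equal(learner.policy.weights, w_pol)
    np.testing.assert_array_equal(learner.critic.weights, w_cri)


def test_opponent_parameters_detached(tiny_env):
    buf = env_buffer(tiny_env)
    cfg = pp.TrainConfig(n_inner_steps=5)
    learner = SpeciesLearner.fresh("prey", tiny_env.obs_dim, cfg,
                                   np.random.default_rng(0))
    opponent = PolicyParams("predator", tiny_env.obs_dim,
                            rng=np.random.default_rng(1))
    before = opponent.weights
    best_response_update(learner, opponent, buf, cfg, np.random.default_rng(2))
    np.testing.assert_array_equal(opponent.weights, before)


def test_best_response_requires_data(tiny_env):
    buf = ReplayBuffer(100, tiny_env.obs_dim)
    cfg = pp.TrainConfig()
    learner = SpeciesLearner.fresh("prey", tiny_env.obs_dim, cfg,
                                   np.random.default_rng(0))
    with pytest.raises(pp.NoDataError):
        best_response_update(learner, None, buf, cfg, np.random.default_rng(1))


class StationaryPrey:
    species = "prey"

    def act(self, obs, rng):
        return 4


def test_predator_best_response_improves_capture_rate():
    """Against stationary prey, trained predators capture more per step."""
    env = pp.EnvConfig(N=9, nX=2, nY=12, bX=0.0, bY=0.0,
                       TX=10 ** 6, TY=10 ** 6, max_steps=10 ** 9)
    cfg = pp.TrainConfig(gamma=0.9, h=70, n_inner_steps=50, batch_size=256,
                         actor_lr=3e-4, actor_lr_predator=None,
                         actor_lr_prey=None, entropy_coef=0.01, seed=0)
    streams = pp.seed_streams(0)
    learner = SpeciesLearner.fresh("predator", env.obs_dim, cfg,
                                   streams["policy_init"])
    initial = learner.policy.copy()
    prey = StationaryPrey()
    buf = ReplayBuffer(cfg.buffer_capacity, env.obs_dim)
    from predprey.training import _collect, _record_initial_obs
    state = pp.init_env(env, streams["placement"])
    _record_initial_obs(state, buf)
    for _ in range(16):
        state, _ = _collect(state, learner.policy, prey, buf, env, cfg.h,
                            streams["rollout"], streams["placement"])
        best_response_update(learner, None, buf, cfg, streams["training"])

    def capture_rate(policy):
        total = steps = 0
        for s in range(8):
            st = pp.init_env(env, 1000 + s)
            rng = np.random.default_rng(2000 + s)
            for _ in range(60):
                st, _, ev = pp.env_step(st, policy, prey, rng, collect=False)
                total += ev.captures_by_predator_action
                steps += 1
                if st.counts()[1] == 0:
                    break
        return total / steps

    assert capture_rate(learner.policy) > capture_rate(initial)


def test_entropy_regularization_keeps_policies_stochastic(tiny_env):
    """A large entropy weight holds the trained policy near uniform."""
    buf = env_buffer(tiny_env, n_steps=80)
    entropies = {}
    for coef in (0.0, 10.0):
        cfg = pp.TrainConfig(n_inner_steps=150, entropy_coef=coef,
                             actor_lr=3e-3, actor_lr_predator=None,
                             actor_lr_prey=None)
        learner = SpeciesLearner.fresh("prey", tiny_env.obs_dim, cfg,
                                       np.random.default_rng(0))
        best_response_update(learner, None, buf, cfg, np.random.default_rng(2))
        batch = buf.sample(PREY, 256, np.random.default_rng(3))
        logits, _ = learner.policy.net.forward_batch(batch["obs"].astype(float))
        probs = softmax(logits)
        entropies[coef] = float(np.mean(-np.sum(probs * np.log(probs + 1e-12),
                                                axis=1)))
    assert entropies[10.0] > entropies[0.0]
    assert entropies[10.0] > 0.95 * np.log(9)


# ---------------------------------------------------------------------------
# Replay buffer
# ---------------------------------------------------------------------------

def test_buffer_fifo_and_species_views():
    buf = ReplayBuffer(capacity=5, obs_dim=2)
    recs = [TransitionRecord(PREY, np.full(2, i, dtype=np.float32), 0,
                             float(i), None, True) for i in range(8)]
    buf.add(recs)
    assert buf.size(PREY) == 5 and buf.size(0) == 0
    batch = buf.sample(PREY, 64, np.random.default_rng(0))
    assert set(batch["reward"]) <= {3.0, 4.0, 5.0, 6.0, 7.0}  # oldest evicted
    with pytest.raises(pp.NoDataError):
        buf.sample(0, 4, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Co-evolution loop
# ---------------------------------------------------------------------------

def test_coevolve_zero_iterations_returns_fresh_policies():
    env = pp.EnvConfig(N=12, nX=4, nY=20)
    cfg = pp.TrainConfig(n_iterations=0)
    pol_pred, pol_prey, history = pp.coevolve(env, cfg)
    assert history == []
    # freshly initialized networks act near-uniformly
    dist = pp.policy_forward(pol_pred, np.zeros(env.obs_dim))
    np.testing.assert_allclose(dist.probabilities, np.full(9, 1 / 9), atol=1e-2)


def test_coevolve_loop_accounting():
    env = pp.EnvConfig(N=15, nX=6, nY=30, max_steps=200)
    cfg = pp.TrainConfig(n_iterations=2, h=20, n_inner_steps=2, seed=1)
    _, _, history = pp.coevolve(env, cfg)
    assert len(history) == 2
    assert history[-1]["buffer_size"] >= 2 * cfg.h
    assert all("mean_n_prey" in rec for rec in history)


def test_coevolve_reproducible():
    env = pp.EnvConfig(N=12, nX=4, nY=20, max_steps=100)
    cfg = pp.TrainConfig(n_iterations=2, h=15, n_inner_steps=3, seed=9)
    p1, y1, h1 = pp.coevolve(env, cfg)
    p2, y2, h2 = pp.coevolve(env, cfg)
    np.testing.assert_array_equal(p1.weights, p2.weights)
    np.testing.assert_array_equal(y1.weights, y2.weights)
    strip = lambda h: [{k: v for k, v in rec.items() if k != "wall_time_s"}
                       for rec in h]
    assert strip(h1) == strip(h2)


# ---------------------------------------------------------------------------
# Q-learning baseline
# ---------------------------------------------------------------------------

def test_dqn_update_substitution():
    q = TabularQ("prey")
    rec = TransitionRecord(PREY, np.zeros(4, dtype=np.float32), 3, 1.0,
                           np.ones(4, dtype=np.float32), False)
    dqn_baseline_update(q, rec, alpha=0.5, gamma=0.9)
    assert q.get(rec.obs, 3) == pytest.approx(0.5)


def test_dqn_update_null_step():
    q = TabularQ("prey")
    rec = TransitionRecord(PREY, np.zeros(4, dtype=np.float32), 3, 1.0,
                           None, True)
    dqn_baseline_update(q, rec, alpha=0.0, gamma=0.9)
    assert q.get(rec.obs, 3) == 0.0


def test_dqn_update_full_overwrite():
    q = TabularQ("prey")
    q.q_values(np.zeros(4, dtype=np.float32))[:] = 7.0
    rec = TransitionRecord(PREY, np.zeros(4, dtype=np.float32), 2, -1.0,
                           np.ones(4, dtype=np.float32), False)
    dqn_baseline_update(q, rec, alpha=1.0, gamma=0.0)
    assert q.get(rec.obs, 2) == pytest.approx(-1.0)
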