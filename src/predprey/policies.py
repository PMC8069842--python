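"""Species-shared stochastic policies over the nine-move action space.

Every agent of a species acts with the same parameters (parameter sharing
with decentralized execution): behavior stays heterogeneous only because
each agent feeds its own egocentric observation through the shared network.
The network is a two-hidden-layer perceptron mapping the flattened
``r*r*C`` window to nine logits; actions are sampled from the softmax
distribution.  Freshly initialized policies emit near-zero logits and hence
act close to uniformly at random, so the "random policy" baseline is the
t=0 special case of the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .errors import PredPreyError
from .gridworld import N_ACTIONS, Observation, flatten_observation
from .nn import MLP, softmax

__all__ = [
    "ActionDistribution", "PolicyParams", "RandomPolicy",
    "policy_forward", "sample_action", "policy_entropy",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ActionDistribution:
    """Softmax distribution over the nine moves, with its logits."""

    probabilities: np.ndarray
    logits: np.ndarray


class PolicyParams:
    """Shared policy network of one species.

    Parameters
    ----------
    species : ``"predator"`` or ``"prey"``.
    input_dim : flattened observation length (``r * r * C``).
    hidden : the two hidden-layer widths.
    rng : generator used for weight initialization.
    """

    def __init__(self, species: str, input_dim: int,
                 hidden: Tuple[int, int] = (64, 64),
                 rng: Optional[np.random.Generator] = None) -> None:
        if species not in ("predator", "prey"):
            raise PredPreyError(f"unknown species {species!r}")
        self.species = species
        self.input_dim = int(input_dim)
        self.hidden = tuple(int(h) for h in hidden)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.net = MLP([self.input_dim, *self.hidden, N_ACTIONS], rng)

    # -- acting ----------------------------------------------------------
    def logits(self, flat_obs: np.ndarray) -> np.ndarray:
        return self.net.forward(flat_obs)

    def act(self, flat_obs: np.ndarray, rng: np.random.Generator) -> int:
        """Sample one action for a flattened observation (fast path)."""
        p = softmax(self.net.forward(flat_obs))
        return int(np.searchsorted(np.cumsum(p), rng.random()))

    # -- parameter access ------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        """The flat parameter vector theta."""
        return self.net.get_flat()

    @weights.setter
    def weights(self, flat: np.ndarray) -> None:
        self.net.set_flat(np.asarray(flat, dtype=float))

    def copy(self) -> "PolicyParams":
        clone = object.__new__(PolicyParams)
        clone.species = self.species
        clone.input_dim = self.input_dim
        clone.hidden = self.hidden
        clone.net = self.net.copy()
        return clone


class RandomPolicy:
    """Uniform policy over the nine moves (the untrained baseline)."""

    def __init__(self, species: str) -> None:
        self.species = species

    def act(self, flat_obs: np.ndarray, rng: np.random.Generator) -> int:
        return int(rng.integers(N_ACTIONS))

    def logits(self, flat_obs: np.ndarray) -> np.ndarray:
        return np.zeros(N_ACTIONS)


def policy_forward(params: PolicyParams,
                   obs: Union[Observation, np.ndarray]) -> ActionDistribution:
    """Deterministic map from an observation to its action distribution."""
    if isinstance(obs, Observation):
        if obs.species_of_observer != params.species:
            raise PredPreyError(
                f"{params.species} policy got a {obs.species_of_observer} observation"
            )
        flat = flatten_observation(obs.window)
    else:
        flat = np.asarray(obs, dtype=float).ravel()
    if flat.size != params.input_dim:
        raise PredPreyError(
            f"observation length {flat.size} != policy input {params.input_dim}"
        )
    logits = params.logits(flat)
    return ActionDistribution(probabilities=softmax(logits), logits=logits)


def sample_action(dist: ActionDistribution, rng: np.random.Generator) -> int:
    """Draw one action index 0..8 according to the distribution."""
    return int(np.searchsorted(np.cumsum(dist.probabilities), rng.random()))


def policy_entropy(dist: ActionDistribution) -> float:
    """Shannon entropy of the action distribution, in nats (<= ln 9)."""
    p = dist.probabilities
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


# -- checkpoint io ---------------------------------------------------------

def save_checkpoint(params: PolicyParams, path: Union[str, Path],
                    iteration: Optional[int] = None,
                    seed: Optional[int] = None) -> None:
    """Serialize a policy to JSON; round-trips bit-identically."""
    doc = {
        "species": params.species,
        "architecture": {"input_dim": params.input_dim,
                         "hidden": list(params.hidden),
                         "output_dim": N_ACTIONS},
        "weights": [float.hex(float(w)) for w in params.weights],
        "iteration": iteration,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path: Union[str, Path]) -> PolicyParams:
    doc = json.loads(Path(path).read_text())
    arch = doc["architecture"]
    params = PolicyParams(doc["species"], arch["input_dim"],
                          tuple(arch["hidden"]), np.random.default_rng(0))
    params.weights = np.array([float.fromhex(w) for w in doc["weights"]])
    return params
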