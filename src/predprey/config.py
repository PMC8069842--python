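"""Environment and training configuration.

The environment defaults are the parameter set of the simulated ecosystem:
a 50x50 periodic lattice holding 100 predators and 500 prey, predator
reproduction probability ``bX = 0.2`` (on capture), prey reproduction
probability ``bY = 0.6`` (on a successful move), predator starvation limit
``TX = 15`` steps and prey maximum age ``TY = 30`` steps, with each agent
observing a 5x5 egocentric window.  Training defaults (discount, learning
rates, entropy weight, inner-loop sizes) are this package's own choices and
are documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .errors import InvalidConfigError

__all__ = ["EnvConfig", "TrainConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class EnvConfig:
    """Parameters of the lattice ecosystem.

    Attributes
    ----------
    N : side length of the square toroidal grid (cells).
    bX : predator reproduction probability on a capture event.
    bY : prey reproduction probability on a successful move.
    TX : maximum predator starvation level (steps without eating).
    TY : maximum prey age (steps).
    TX_age : optional maximum predator age; ``None`` disables predator aging.
    nX, nY : initial predator / prey counts.
    r : odd side length of the egocentric observation window.
    max_steps : episode step cap.
    obs_padding : if True, cells beyond the grid edge are observed as empty
        (zero padding) instead of wrapping around the torus.  Movement is
        always periodic.
    """

    N: int = 50
    bX: float = 0.2
    bY: float = 0.6
    TX: int = 15
    TY: int = 30
    TX_age: Optional[int] = None
    nX: int = 100
    nY: int = 500
    r: int = 5
    max_steps: int = 2000
    obs_padding: bool = False

    def __post_init__(self) -> None:
        if self.N < self.r:
            raise InvalidConfigError(f"grid side N={self.N} smaller than window r={self.r}")
        if self.r % 2 != 1 or self.r < 1:
            raise InvalidConfigError(f"observation window r={self.r} must be odd and positive")
        for name in ("bX", "bY"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name}={p} is not a probability")
        if self.TX < 1 or self.TY < 1:
            raise InvalidConfigError("TX and TY must be >= 1")
        if self.TX_age is not None and self.TX_age < 1:
            raise InvalidConfigError("TX_age must be >= 1 when set")
        if self.nX < 0 or self.nY < 0:
            raise InvalidConfigError("initial counts must be non-negative")
        if self.nX + self.nY > self.N * self.N:
            raise InvalidConfigError(
                f"{self.nX + self.nY} agents do not fit on a {self.N}x{self.N} grid"
            )
        if self.max_steps < 0:
            raise InvalidConfigError("max_steps must be >= 0")

    @property
    def n_channels(self) -> int:
        """Number of species channels in the grid tensor view."""
        return 2

    @property
    def obs_dim(self) -> int:
        """Flattened observation length fed to the policy networks."""
        return self.r * self.r * self.n_channels


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the co-evolution procedure.

    ``h`` is the sampling horizon: the number of environment steps collected
    between policy-update iterations.  ``f_divergence`` names the regularizer
    of the off-policy objective and is fixed to the squared form
    ``f(x) = x^2/2`` (conjugate ``f*(y) = y^2/2``).

    Actor step sizes are per species by default: prey adapt much faster than
    predators (1e-3 vs 1e-5).  Symmetric actor rates let predator best
    responses overshoot and exterminate the prey; the strong prey-favoring
    asymmetry keeps the co-evolution in the sustainable regime (see
    ``docs/methods.md``).  Set both overrides to ``None`` to use the shared
    ``actor_lr`` for the two species.
    """

    gamma: float = 0.99
    h: int = 70
    n_iterations: int = 20
    entropy_coef: float = 0.01
    critic_lr: float = 1e-3
    actor_lr: float = 1e-4
    actor_lr_predator: Optional[float] = 1e-5
    actor_lr_prey: Optional[float] = 1e-3
    batch_size: int = 256
    buffer_capacity: int = 100_000
    n_inner_steps: int = 50
    hidden: Tuple[int, int] = (64, 64)
    f_divergence: str = "half_square"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise InvalidConfigError(f"gamma={self.gamma} must lie in (0,1)")
        if self.h < 1:
            raise InvalidConfigError("sampling horizon h must be >= 1")
        if self.n_iterations < 0:
            raise InvalidConfigError("n_iterations must be >= 0")
        if self.f_divergence != "half_square":
            raise InvalidConfigError("only the half-square f-divergence is supported")
        if self.batch_size < 1 or self.buffer_capacity < 1 or self.n_inner_steps < 0:
            raise InvalidConfigError("batch/buffer/inner-step sizes out of range")

    def actor_lr_for(self, species: str) -> float:
        """Actor step size for one species (per-species override or shared)."""
        override = self.actor_lr_predator if species == "predator" \
            else self.actor_lr_prey
        return self.actor_lr if override is None else override


_ENV_FIELDS = {f.name: f for f in dataclasses.fields(EnvConfig)}
_TRAIN_FIELDS = {f.name: f for f in dataclasses.fields(TrainConfig)}


def _coerce(section: str, key: str, value):
    if section == "env" and key not in _ENV_FIELDS:
        raise InvalidConfigError(
            f"unknown env key {key!r}; valid keys: {sorted(_ENV_FIELDS)}"
        )
    if section == "train" and key not in _TRAIN_FIELDS:
        raise InvalidConfigError(
            f"unknown train key {key!r}; valid keys: {sorted(_TRAIN_FIELDS)}"
        )
    if section == "train" and key == "hidden" and value is not None:
        return tuple(int(v) for v in value)
    return value


def load_config(path: Union[str, Path]) -> Tuple[EnvConfig, TrainConfig]:
    """Read a YAML config file into ``(EnvConfig, TrainConfig)``.

    The dialect is a flat mapping with dotted section prefixes
    (``env.N: 60``) or nested ``env:`` / ``train:`` mappings; unprefixed keys
    are resolved by field name.  Unspecified keys keep their defaults; unknown
    keys raise :class:`InvalidConfigError` listing the valid ones.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError("config file must contain a key-value mapping")
    env_kw, train_kw = {}, {}
    for key, value in raw.items():
        if key in ("env", "train") and isinstance(value, dict):
            target = env_kw if key == "env" else train_kw
            for k, v in value.items():
                target[k] = _coerce(key, k, v)
        elif isinstance(key, str) and key.startswith("env."):
            env_kw[key[4:]] = _coerce("env", key[4:], value)
        elif isinstance(key, str) and key.startswith("train."):
            train_kw[key[6:]] = _coerce("train", key[6:], value)
        elif key in _ENV_FIELDS:
            env_kw[key] = _coerce("env", key, value)
        elif key in _TRAIN_FIELDS:
            train_kw[key] = _coerce("train", key, value)
        else:
            valid = sorted(set(_ENV_FIELDS) | set(_TRAIN_FIELDS) | {"env", "train"})
            raise InvalidConfigError(f"unknown config key {key!r}; valid keys: {valid}")
    try:
        return EnvConfig(**env_kw), TrainConfig(**train_kw)
    except TypeError as exc:  # pragma: no cover - guarded by _coerce
        raise InvalidConfigError(str(exc)) from exc


def save_config(env_cfg: EnvConfig, train_cfg: TrainConfig, path: Union[str, Path]) -> None:
    """Write the pair of configs back to YAML; ``load_config`` round-trips it."""
    doc = {
        "env": dataclasses.asdict(env_cfg),
        "train": {**dataclasses.asdict(train_cfg), "hidden": list(train_cfg.hidden)},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
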