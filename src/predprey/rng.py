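"""Seed management.

A single user-facing seed is expanded into named, statistically independent
streams so that, e.g., changing the rollout seed leaves agent placement and
network initialization untouched.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

STREAMS = ("placement", "policy_init", "rollout", "training")


def seed_streams(seed: int) -> Dict[str, np.random.Generator]:
    """Expand ``seed`` into one independent generator per named stream."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAMS, children)}


def spawn_seeds(seed: int, n: int) -> list:
    """Derive ``n`` reproducible sub-seeds (each < 2**31) from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
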