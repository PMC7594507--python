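"""Derived random streams.

All randomness in a run flows from one user seed.  Each component
(inducing-line selection, CV partitions, Gibbs sampler, simulator) draws
from its own named stream so that components are independently
reproducible: changing the number of CV replicates, say, does not perturb
the sampler's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "stream"]


def derive_seed(seed: int, name: str, index: int = 0) -> int:
    """Stable sub-seed for the named stream (always < 2**31)."""
    tag = zlib.crc32(f"{name}:{index}".encode())
    return (int(seed) * 1_000_003 + tag) % (2**31 - 1)


def stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """A Generator seeded from the named derived stream."""
    return np.random.default_rng(derive_seed(seed, name, index))
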