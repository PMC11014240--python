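"""Seed plumbing: named child random streams derived from one master seed.

Every stochastic stage (timing, velocity, noise, hrv, amplitude) pulls from
its own stream so adding a draw in one stage never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_REDRAWS = 1000
"""Bound on rejection-sampling loops; exceeding it raises RuntimeError."""


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named stream under the master seed.

    The stream key is a CRC32 of the name, so streams are stable across
    runs and independent of the order in which they are created.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def child_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named child streams for several stages at once."""
    return {name: child_rng(seed, name) for name in names}
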