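"""Deterministic substream derivation.

Every source of randomness in the package is driven by a
:class:`numpy.random.SeedSequence`.  A master integer seed is expanded into
per-instance (and per-color, per-stage) substreams by extending the spawn
key, so that

* the same master seed always reproduces the same ensemble,
* any single instance can be regenerated in isolation from its spawn key,
* instances are independent and may be generated in any order or in
  parallel.

``child(seed, i, j, ...)`` is identical to the ``SeedSequence.spawn``
children: the child with spawn key ``parent_key + (i, j, ...)``.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence"


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an integer (or SeedSequence) to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, (int, np.integer)):
        return np.random.SeedSequence(int(seed))
    raise TypeError(f"seed must be an int or SeedSequence, got {type(seed)!r}")


def child(seed, *key: int) -> np.random.SeedSequence:
    """Deterministic child stream obtained by extending the spawn key."""
    ss = as_seed_sequence(seed)
    return np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(ss.spawn_key) + tuple(key))


def rng(seed, *key: int) -> np.random.Generator:
    """A PCG64 generator on the ``child(seed, *key)`` stream."""
    return np.random.default_rng(child(seed, *key) if key else as_seed_sequence(seed))
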