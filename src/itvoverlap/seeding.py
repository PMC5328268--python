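"""Deterministic, order-independent derivation of random substreams.

Every stochastic stage derives one substream per logical unit of work (a
species in a forest, a forest, a replicate) from a master seed and a stable
string key, so shuffling input rows or parallelizing over groups cannot
change any result.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed_sequence(seed: int, *key) -> np.random.SeedSequence:
    digest = hashlib.sha256("\x1f".join(map(str, key)).encode()).digest()
    return np.random.SeedSequence([int(seed), int.from_bytes(digest[:8], "little")])


def derive_rng(seed: int, *key) -> np.random.Generator:
    """Generator keyed by (seed, *key); identical arguments give identical streams."""
    return np.random.default_rng(derive_seed_sequence(seed, *key))
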