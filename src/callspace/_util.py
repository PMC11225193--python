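"""Seed plumbing shared by every stochastic stage.

A single user-facing integer seed fans out into independent, stable
substreams keyed by stage name, so changing the amount of randomness one
stage consumes never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "MAX_SEED"]

# configs pass small integers; keep derived entropy in range
MAX_SEED = 2**31 - 1


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the (seed, *keys) substream.

    The same (seed, keys) pair always yields an identically-seeded
    generator; distinct key tuples yield independent streams.
    """
    entropy = [int(seed) & MAX_SEED]
    for key in keys:
        if isinstance(key, int):
            entropy.append(key & MAX_SEED)
        else:
            entropy.append(zlib.crc32(str(key).encode("utf-8")) & MAX_SEED)
    return np.random.default_rng(np.random.SeedSequence(entropy))
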