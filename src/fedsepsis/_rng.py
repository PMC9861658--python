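"""Seed plumbing: every stochastic component draws from a spawn of one root seed."""

from __future__ import annotations

import hashlib

import numpy as np


def root_sequence(seed: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(int(seed))


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-purpose generator.

    ``keys`` are arbitrary hashable labels (module name, patient id, round
    index ...) folded into the root seed, so independent consumers never share
    a stream and adding a consumer never perturbs the others.
    """
    digest = hashlib.blake2b(
        ("\x1f".join(str(k) for k in keys)).encode(), digest_size=8
    ).digest()
    entropy = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), entropy]))
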