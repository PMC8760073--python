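"""Shared helpers: deterministic seed splitting and RNG construction."""

from __future__ import annotations

import hashlib

import numpy as np

_SEED_MOD = 2**31


def child_seed(master: int, *keys: object) -> int:
    """Derive a child seed from a master seed and a key path.

    The rule is stable across runs and platforms: SHA-256 of
    ``"wmcode:<master>:<key1>:<key2>:..."`` truncated to 31 bits. Stages and
    repetitions keyed this way are independently re-runnable.
    """
    payload = "wmcode:" + ":".join(str(k) for k in (master, *keys))
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % _SEED_MOD


def rng_for(master: int, *keys: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *keys))
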