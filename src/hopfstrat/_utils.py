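"""Seed derivation and content hashing shared across pipeline stages."""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(*entropy: int) -> int:
    """Deterministically derive a child seed (< 2**31) from integer entropy.

    Every stochastic stage derives its own seed from the master seed plus a
    stage/index tag, so results are independent of execution order and worker
    count.
    """
    ss = np.random.SeedSequence(list(entropy))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % MAX_SEED)


def rng_from(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def content_hash(*parts: Any) -> str:
    """SHA-256 hex digest of a heterogeneous tuple of arrays/scalars/strings."""
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, np.ndarray):
            h.update(np.ascontiguousarray(part).tobytes())
            h.update(str(part.shape).encode())
        elif isinstance(part, (dict, list, tuple)):
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
        else:
            h.update(str(part).encode())
    return h.hexdigest()
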