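"""Deterministic child random streams keyed by entity ids.

Every stochastic component draws from a ``numpy`` Generator whose seed is
derived from one root seed plus a stable hash of a string tag (for example
``"patient/P0007"``).  Streams for different entities are therefore
independent, and adding entities never reshuffles the draws of existing
ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _stable_hash(tag: str) -> int:
    """First 8 bytes of SHA-256 of the tag, as an unsigned int."""
    return int.from_bytes(hashlib.sha256(tag.encode("utf-8")).digest()[:8], "big")


def child_rng(root_seed: int, *tags: str) -> np.random.Generator:
    """Generator for the stream identified by ``tags`` under ``root_seed``."""
    entropy = [int(root_seed) & 0xFFFFFFFF] + [_stable_hash(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
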