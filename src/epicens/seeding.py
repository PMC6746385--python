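"""Domain-separated seed derivation.

A single top-level seed fans out to every stochastic component through a
stable hash of (seed, labels), so any stage can be re-run in isolation and
reproduce exactly the stream it saw inside the full pipeline.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(seed: int, *labels: object) -> int:
    """Derive a child seed from a master seed and a label path.

    Deterministic, platform-independent (blake2b over a canonical string).
    """
    key = ":".join([str(int(seed))] + [str(lab) for lab in labels])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def derive_rng(seed: int, *labels: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, *labels))
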