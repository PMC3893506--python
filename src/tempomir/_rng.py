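"""Single-seed stream splitting.

Every randomized stage derives its generator from one global integer seed
plus a stable stage tag, so stages can be re-run in isolation and adding a
stage never shifts another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(seed: int, *tags: str | int) -> int:
    """A stable 31-bit seed for a named stream under the global seed."""
    h = zlib.crc32(repr(int(seed)).encode())
    for tag in tags:
        h = zlib.crc32(repr(tag).encode(), h)
    return h % (2**31)


def derive_rng(seed: int, *tags: str | int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), *(derive_seed(seed, t) for t in tags)])
    )
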