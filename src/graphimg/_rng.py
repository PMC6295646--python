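"""Named, independent random streams derived from one master seed.

Every stochastic stage (walk sampling, skip-gram init, batch shuffling,
CNN init, fold partitioning, ...) draws from its own stream so that any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def derive_seed(master_seed: int, name: str) -> int:
    """A stable child seed (< 2**31) for the stream called *name*."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_name_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def derive_rng(master_seed: int, name: str) -> np.random.Generator:
    """A Generator for the stream called *name*, independent of other names."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)
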