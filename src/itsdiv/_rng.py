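"""Named random substreams derived from one run seed.

Each stochastic stage (bootstrap, permutation test, country subsampling,
generator) draws from its own named substream, so changing one stage's
workload never shifts another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))


def substream_int(seed: int, name: str) -> int:
    """A derived 31-bit integer seed for APIs that take a plain int."""
    return int(substream_seed(seed, name).generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
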