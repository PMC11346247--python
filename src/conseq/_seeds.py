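"""Seed plumbing: one master seed, independent substreams per layer."""

from __future__ import annotations

import numpy as np


def as_seedseq(seed) -> np.random.SeedSequence:
    """Coerce an int / None / SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError("pass an integer seed or SeedSequence, not a Generator")
    return np.random.SeedSequence(seed)


def as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(as_seedseq(seed))
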