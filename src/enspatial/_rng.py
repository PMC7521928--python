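"""Deterministic seed plumbing.

One user seed fans out into independent child streams via
``numpy.random.SeedSequence.spawn`` — per frame, per reshuffle, per
replicate — so serial and restructured execution orders agree and no two
stages share a stream.
"""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce ints, None, or an existing SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
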