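"""Random-number plumbing shared across modules."""

from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | None"


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
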