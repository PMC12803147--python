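"""Named, reproducible random substreams.

Every stochastic stage of the toolkit draws from its own substream derived
from a single root seed, so changing e.g. the number of units never perturbs
the force generator or the noise fit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    Deterministic: the same (seed, name) pair always yields the same stream,
    and distinct names yield statistically independent streams.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))
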