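"""Named, reproducible random substreams.

One user-facing seed governs a whole run; each stage (scene geometry,
acquisition noise, Monte-Carlo statistics) draws from its own substream so
stages can be re-run in isolation without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The name is hashed with CRC-32, which is stable across platforms and
    Python versions (unlike ``hash``).
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
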