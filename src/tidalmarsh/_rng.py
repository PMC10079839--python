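"""Named random substreams.

All stochastic stages draw from substreams derived from one root seed, so a
stage can be re-run in isolation and still produce the bytes it would have
produced inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is derived from a CRC of the name, so the mapping is
    stable across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
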