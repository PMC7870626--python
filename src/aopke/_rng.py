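"""Named random substreams.

One global seed is expanded into independent per-purpose generators keyed by a
stream name, so adding a new stream never perturbs draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, combined with the seed through a
    ``SeedSequence`` so distinct names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
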