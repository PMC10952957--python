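"""Named random substreams.

A single master seed governs every stochastic component; each variable draws
from its own named substream so that adding a new variable never perturbs the
draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    The stream key is the CRC-32 of the name, folded into a SeedSequence
    together with the master seed, so streams are independent and stable
    across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), key)))
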