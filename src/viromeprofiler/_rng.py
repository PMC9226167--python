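"""Named, reproducible random substreams.

Every stochastic draw in the package flows from one global integer seed via
a named substream, so adding a draw to one component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of the global ``seed``.

    The substream is keyed by CRC32 of the name, so streams with distinct
    names are statistically independent and stable across runs.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
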