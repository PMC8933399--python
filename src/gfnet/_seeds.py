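"""Deterministic per-stage seed derivation.

A master seed expands into independent child seeds keyed by string tags
(stage name, subject id, band, ...), so adding a stage or subject never
perturbs the random stream of any other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master: int, *tags) -> int:
    """A reproducible child seed < 2**31 for (master seed, tag path)."""
    entropy = [int(master) & 0xFFFFFFFF] + [
        zlib.crc32(str(t).encode("utf-8")) for t in tags
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
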