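"""Deterministic seed derivation.

A single pipeline seed is fanned out into per-(stage, block, algorithm,
repeat, fold) child seeds so that every repeat of a repeated-CV protocol
draws fresh but reproducible randomness. Children are independent of which
other children are drawn, so e.g. the fingerprint-side member seeds of the
dual-block ensemble do not change when the descriptor side is removed.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31 for every backend


def derive_seed(base: int, *tags: object) -> int:
    """Derive a child seed from ``base`` and a sequence of hashable tags.

    The same (base, tags) pair always yields the same child; distinct tag
    sequences yield (with overwhelming probability) distinct children.
    """
    key = zlib.crc32("|".join(map(str, tags)).encode("utf-8"))
    ss = np.random.SeedSequence([int(base) & _MASK, key])
    return int(ss.generate_state(1)[0]) & _MASK
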