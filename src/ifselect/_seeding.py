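"""Deterministic seed derivation.

All randomness in the pipeline flows from a single user-supplied seed.
Stage- and fold-level seeds are derived by hashing the parent seed together
with string tokens naming the consumer, so that adding or reordering stages
never perturbs the streams of unrelated stages.
"""

from __future__ import annotations

import zlib


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a child seed from ``seed`` and a path of string-able tokens.

    Returns a nonnegative integer below 2**31, stable across platforms and
    Python versions (CRC32 of the UTF-8 token path).
    """
    path = ":".join([str(int(seed))] + [str(t) for t in tokens])
    return zlib.crc32(path.encode("utf-8")) & 0x7FFFFFFF
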