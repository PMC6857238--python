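"""Deterministic seed derivation.

A single master seed fans out to per-component seeds through a keyed hash, so
that any sub-computation (a scanning forest, a cascade layer fold, a CV split)
gets a stable, independent stream regardless of execution order.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31  # sklearn accepts ints in [0, 2**32); stay below 2**31 for safety


def derive_seed(master: int, *parts: object) -> int:
    """Derive a child seed from ``master`` and a label path.

    The same (master, parts) always yields the same child; distinct part
    paths yield (effectively) independent children.
    """
    key = repr((int(master),) + tuple(str(p) for p in parts)).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest[:4], "little") % _MOD
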