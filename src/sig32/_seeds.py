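"""Deterministic child-seed derivation.

One global integer seed drives every stage; sub-generators derive their own
seeds from the pair (seed, stage name) via SHA-256, so adding or reordering
stages never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31 - 1


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic child seed (< 2**31) from a parent seed and a stage name."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
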