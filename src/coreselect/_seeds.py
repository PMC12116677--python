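"""Stage-scoped seed derivation.

All randomness in the package flows from a single user-supplied integer
seed. Each pipeline stage derives its own sub-seed by hashing a stage
name into an offset, so stages are individually reproducible and do not
share RNG streams.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31 - 1


def derive_seed(base_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from a base seed.

    The stage name is hashed (BLAKE2b) into a fixed offset; the result is
    reduced mod 2**31 - 1 so it stays a small non-negative integer.
    """
    digest = hashlib.blake2b(stage.encode("utf-8"), digest_size=8).digest()
    offset = int.from_bytes(digest, "big")
    return (int(base_seed) + offset) % _MOD
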