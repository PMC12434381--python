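"""Hierarchical, platform-stable seed derivation.

Every random draw in the pipeline traces back to a single master seed through
``derive_seed(master, *tokens)``, so that stages (splitting, permutations,
subsampling) can be re-run independently and in any order without changing
each other's streams.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a child seed from a master seed and a path of tokens.

    Uses BLAKE2b over the repr of the token path, so the mapping is stable
    across processes and platforms (unlike ``hash()``). The result is a
    non-negative int below 2**31, suitable for any RNG constructor.
    """
    key = repr((int(master_seed),) + tokens).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
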