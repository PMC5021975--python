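"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Deterministically derive a sub-seed from a master seed and string tokens.

    Uses the first four bytes of a SHA-256 digest, reduced modulo 2**31, so
    the result is a valid seed for any RNG and is independent of Python's
    per-process hash randomization. Sub-streams keyed by distinct tokens are
    effectively independent, which makes per-condition (or per-institution)
    results insensitive to iteration order.
    """
    msg = "|".join([str(int(master_seed)), *map(str, tokens)])
    digest = hashlib.sha256(msg.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
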