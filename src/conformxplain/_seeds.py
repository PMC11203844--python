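"""Deterministic per-stage seed derivation from a single master seed."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from ``master_seed``.

    Hash-based (BLAKE2) so stages can be re-run in isolation without
    consuming a shared random stream; stable across platforms and runs.
    """
    h = hashlib.blake2b(f"{int(master_seed)}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little") % (2**31)
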