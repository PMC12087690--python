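"""Small shared helpers (seed derivation, hashing)."""

from __future__ import annotations

import zlib


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a global seed.

    A single user-facing seed fans out to independent per-stage streams via
    a CRC of ``"{seed}:{stage}"`` so each stage is reproducible in
    isolation.
    """
    return zlib.crc32(f"{int(seed)}:{stage}".encode()) & 0x7FFFFFFF
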