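"""Run-length coding: (value, run length) pairs over a byte stream.

Effective exactly when the stream has long constant runs — which the
zero background and piecewise-constant tissue regions of medical volumes
provide in abundance.  The serialized baseline form uses an 8-bit value
plus a 16-bit run length; runs longer than 65535 are split.
"""

from __future__ import annotations

import struct
from collections.abc import Sequence

import numpy as np

from .._bits import Bits

__all__ = ["rle_encode", "rle_decode", "rle_pack", "rle_unpack"]

_MAX_RUN = 0xFFFF


def rle_encode(data: bytes) -> list[tuple[int, int]]:
    """Encode bytes as maximal (value, run_length) pairs.

    Adjacent pairs never share a value and every run length is ≥ 1; the
    empty input yields the empty list.
    """
    if len(data) == 0:
        return []
    arr = np.frombuffer(data, dtype=np.uint8)
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [arr.size]))
    return [(int(arr[s]), int(e - s)) for s, e in zip(starts, ends)]


def rle_decode(pairs: Sequence[tuple[int, int]]) -> bytes:
    """Inverse of :func:`rle_encode` (also accepts split runs)."""
    out = bytearray()
    for value, run in pairs:
        if run < 1:
            raise ValueError(f"run length must be >= 1, got {run}")
        out.extend(bytes([value]) * run)
    return bytes(out)


def rle_pack(pairs: Sequence[tuple[int, int]]) -> tuple[Bits, int]:
    """Serialize pairs as u8 value + u16-LE run length, splitting long runs.

    Returns the packed payload and the number of serialized pairs (the
    symbol count a decoder needs).
    """
    buf = bytearray()
    count = 0
    for value, run in pairs:
        while run > 0:
            chunk = min(run, _MAX_RUN)
            buf += struct.pack("<BH", value, chunk)
            run -= chunk
            count += 1
    return Bits(bytes(buf), 8 * len(buf)), count


def rle_unpack(bits: Bits, n_pairs: int) -> list[tuple[int, int]]:
    """Inverse of :func:`rle_pack` for exactly ``n_pairs`` serialized pairs."""
    need = 3 * n_pairs
    if len(bits.data) < need:
        raise ValueError("RLE payload shorter than the declared pair count")
    return [
        struct.unpack_from("<BH", bits.data, 3 * i) for i in range(n_pairs)
    ]
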