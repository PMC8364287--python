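"""LZW dictionary coding with a fixed-capacity, freeze-on-full dictionary.

The dictionary starts with the 256 single-byte strings; each greedy
longest-match step emits the index of the matched string and adds the
match extended by the next byte, up to a capacity of 4096 entries, after
which the dictionary is frozen (no resets).  The encoder output is a
sequence of integer codes — either fed directly to the arithmetic stage
of the hybrid codec, or packed at a fixed 12-bit width for the standalone
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .._bits import Bits

__all__ = ["CodeSequence", "lzw_encode", "lzw_decode", "pack_codes", "unpack_codes"]

DEFAULT_CAPACITY = 4096


@dataclass(frozen=True)
class CodeSequence:
    """Ordered LZW dictionary indices plus bookkeeping for decode checks."""

    codes: list[int] = field(default_factory=list)
    source_length: int = 0

    @property
    def max_code(self) -> int:
        """Largest emitted index (-1 for the empty sequence)."""
        return max(self.codes, default=-1)

    def __len__(self) -> int:
        return len(self.codes)


def lzw_encode(data: bytes, capacity: int = DEFAULT_CAPACITY) -> CodeSequence:
    """Greedy longest-match LZW parse of ``data``.

    Dictionary entries beyond the initial 256 are keyed (prefix code, next
    byte) so each input byte costs one dict lookup.
    """
    if capacity < 256:
        raise ValueError(f"capacity must be >= 256, got {capacity}")
    if len(data) == 0:
        return CodeSequence([], 0)
    table: dict[tuple[int, int], int] = {}
    next_code = 256
    codes: list[int] = []
    cur = data[0]
    for b in memoryview(data)[1:]:
        key = (cur, b)
        hit = table.get(key)
        if hit is not None:
            cur = hit
        else:
            codes.append(cur)
            if next_code < capacity:
                table[key] = next_code
                next_code += 1
            cur = b
    codes.append(cur)
    return CodeSequence(codes, len(data))


def lzw_decode(
    codes: CodeSequence | list[int], capacity: int = DEFAULT_CAPACITY
) -> bytes:
    """Inverse of :func:`lzw_encode`.

    Handles the self-referential case — a code equal to the next unassigned
    index, produced by cScSc-patterned input — by reconstructing the entry
    as previous-string + its own first byte.  Any other out-of-range code
    raises ``ValueError``.
    """
    seq = codes.codes if isinstance(codes, CodeSequence) else list(codes)
    if not seq:
        return b""
    entries: list[bytes] = [bytes([i]) for i in range(256)]
    first = seq[0]
    if first >= 256:
        raise ValueError(f"corrupt code stream: leading code {first} is not a literal")
    out = bytearray(entries[first])
    prev = entries[first]
    for code in seq[1:]:
        if code < len(entries):
            entry = entries[code]
        elif code == len(entries) and len(entries) < capacity:
            entry = prev + prev[:1]  # cScSc: entry being defined by this code
        else:
            raise ValueError(f"corrupt code stream: code {code} not yet in dictionary")
        out += entry
        if len(entries) < capacity:
            entries.append(prev + entry[:1])
        prev = entry
    return bytes(out)


def pack_codes(codes: list[int], width: int = 12) -> Bits:
    """Pack integer codes at a fixed bit width (baseline serialization)."""
    chars = []
    for c in codes:
        if c < 0 or c >= (1 << width):
            raise ValueError(f"code {c} does not fit in {width} bits")
        chars.append(format(c, f"0{width}b"))
    return Bits.from01("".join(chars))


def unpack_codes(bits: Bits, n: int, width: int = 12) -> list[int]:
    """Inverse of :func:`pack_codes` for exactly ``n`` codes."""
    s = bits.to01()
    if len(s) < n * width:
        raise ValueError("packed code stream shorter than declared code count")
    return [int(s[i * width : (i + 1) * width], 2) for i in range(n)]
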