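"""Minimal MSB-first bit-string container used by all entropy coders.

Payloads are stored packed (bytes + an explicit bit length) so container
files are byte-aligned while the exact bit count is preserved.
"""

from __future__ import annotations


class Bits:
    """An immutable sequence of bits, packed MSB-first into bytes.

    ``data`` holds ``ceil(length / 8)`` bytes; pad bits in the final byte
    are zero.  Equality compares both the bit length and the bit content.
    """

    __slots__ = ("data", "length")

    def __init__(self, data: bytes = b"", length: int = 0):
        nbytes = (length + 7) // 8
        if len(data) != nbytes:
            raise ValueError(
                f"bit length {length} requires {nbytes} bytes, got {len(data)}"
            )
        object.__setattr__(self, "data", bytes(data))
        object.__setattr__(self, "length", length)

    def __setattr__(self, *_):  # pragma: no cover - immutability guard
        raise AttributeError("Bits is immutable")

    @classmethod
    def from01(cls, s: str) -> "Bits":
        """Build from a string of '0'/'1' characters."""
        n = len(s)
        if n == 0:
            return cls()
        pad = (-n) % 8
        value = int(s, 2) << pad
        return cls(value.to_bytes((n + pad) // 8, "big"), n)

    def to01(self) -> str:
        """Render as a '0'/'1' string (the exact ``length`` bits)."""
        if self.length == 0:
            return ""
        value = int.from_bytes(self.data, "big")
        return format(value, f"0{8 * len(self.data)}b")[: self.length]

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other) -> bool:
        if not isinstance(other, Bits):
            return NotImplemented
        return self.length == other.length and self.to01() == other.to01()

    def __hash__(self) -> int:
        return hash((self.length, self.data))

    def __repr__(self) -> str:
        preview = self.to01()
        if len(preview) > 32:
            preview = preview[:32] + "..."
        return f"Bits({preview!r}, length={self.length})"
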