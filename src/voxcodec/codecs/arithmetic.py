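"""Static integer arithmetic coding.

The coder keeps a [low, high] interval in P-bit integer state (default
P = 32) and narrows it symbol by symbol in proportion to the symbol's
probability under a static frequency model.  Matching most-significant
bits are emitted and the interval rescaled (MSB renormalization); the
near-half straddle case is handled by E3 underflow counting, with the
pending bits flushed at the next MSB decision.  Integer state makes the
coder exactly invertible — a floating-point interval could not be.

Payload length is within a couple of bits of the Shannon information
content of the stream under the model, plus at most two termination bits.
"""

from __future__ import annotations

from bisect import bisect_right
from collections.abc import Sequence

import numpy as np

from .._bits import Bits

__all__ = ["FrequencyModel", "arithmetic_encode", "arithmetic_decode"]

DEFAULT_PRECISION = 32


class FrequencyModel:
    """Static per-symbol occurrence counts with cumulative totals.

    Symbols are the integers ``0 .. alphabet_size-1``; a count of zero is
    allowed only for symbols that never occur in the stream being coded
    (encoding such a symbol raises).
    """

    __slots__ = ("counts", "cumulative", "total", "alphabet_size")

    def __init__(self, counts: Sequence[int]):
        counts = [int(c) for c in counts]
        if not counts:
            raise ValueError("alphabet must have at least one symbol")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        total = sum(counts)
        if total == 0:
            raise ValueError("model total must be positive")
        self.counts = counts
        self.alphabet_size = len(counts)
        self.total = total
        cum = [0] * (len(counts) + 1)
        acc = 0
        for i, c in enumerate(counts):
            acc += c
            cum[i + 1] = acc
        self.cumulative = cum

    @classmethod
    def from_symbols(
        cls, symbols: Sequence[int], alphabet_size: int | None = None
    ) -> "FrequencyModel":
        """Count symbol occurrences (first pass of the static coder)."""
        arr = np.asarray(symbols, dtype=np.int64)
        if arr.size and arr.min() < 0:
            raise ValueError("symbols must be non-negative")
        size = alphabet_size if alphabet_size is not None else int(arr.max()) + 1
        if arr.size and int(arr.max()) >= size:
            raise ValueError("symbol outside the declared alphabet")
        return cls(np.bincount(arr, minlength=size).tolist())

    def scaled(self, cap: int = 0xFFFF) -> "FrequencyModel":
        """Halve counts until each fits in ``cap``; occurring symbols keep ≥ 1.

        Used before storing the model in a container (16-bit count fields);
        encoder and decoder share the scaled model so no information is lost.
        """
        counts = list(self.counts)
        while max(counts) > cap:
            counts = [(c + 1) // 2 if c else 0 for c in counts]
        return FrequencyModel(counts)

    def interval(self, symbol: int) -> tuple[int, int]:
        if not 0 <= symbol < self.alphabet_size:
            raise ValueError(f"symbol {symbol} outside alphabet of size {self.alphabet_size}")
        lo, hi = self.cumulative[symbol], self.cumulative[symbol + 1]
        if lo == hi:
            raise ValueError(f"symbol {symbol} has zero probability under the model")
        return lo, hi


def _check_precision(model: FrequencyModel, precision: int) -> None:
    if not 16 <= precision <= 62:
        raise ValueError(f"precision must be in [16, 62], got {precision}")
    if model.total > (1 << (precision - 2)):
        raise ValueError("model total too large for the coder precision")


def arithmetic_encode(
    symbols: Sequence[int],
    model: FrequencyModel,
    precision: int = DEFAULT_PRECISION,
) -> Bits:
    """Encode a symbol sequence under a static model."""
    _check_precision(model, precision)
    half = 1 << (precision - 1)
    quarter = half >> 1
    full = (1 << precision) - 1
    total = model.total
    low, high = 0, full
    pending = 0
    out: list[str] = []

    def emit(bit: str) -> None:
        nonlocal pending
        out.append(bit)
        if pending:
            out.append(("1" if bit == "0" else "0") * pending)
            pending = 0

    for s in symbols:
        c_lo, c_hi = model.interval(s)
        rng = high - low + 1
        high = low + (rng * c_hi) // total - 1
        low = low + (rng * c_lo) // total
        while True:
            if high < half:
                emit("0")
            elif low >= half:
                emit("1")
                low -= half
                high -= half
            elif low >= quarter and high < half + quarter:
                pending += 1  # E3 straddle: defer until the MSB resolves
                low -= quarter
                high -= quarter
            else:
                break
            low <<= 1
            high = (high << 1) | 1
    # Termination: one disambiguating bit (plus pending) pins the interval.
    pending += 1
    emit("0" if low < quarter else "1")
    return Bits.from01("".join(out))


def arithmetic_decode(
    bits: Bits,
    model: FrequencyModel,
    n: int,
    precision: int = DEFAULT_PRECISION,
) -> list[int]:
    """Decode exactly ``n`` symbols; exact inverse of the encoder.

    Up to ``precision`` zero pad bits may be read past the payload end (the
    encoder's termination guarantees they resolve correctly); needing more
    than that means the payload was truncated and raises ``ValueError``.
    """
    _check_precision(model, precision)
    if n == 0:
        return []
    half = 1 << (precision - 1)
    quarter = half >> 1
    full = (1 << precision) - 1
    total = model.total
    cum = model.cumulative
    stream = bits.to01()
    limit = len(stream) + precision
    pos = 0

    def read_bit() -> int:
        nonlocal pos
        if pos >= limit:
            raise ValueError("bitstring exhausted before all symbols resolved")
        bit = 1 if pos < len(stream) and stream[pos] == "1" else 0
        pos += 1
        return bit

    value = 0
    for _ in range(precision):
        value = (value << 1) | read_bit()
    low, high = 0, full
    out: list[int] = []
    for _ in range(n):
        rng = high - low + 1
        scaled = ((value - low + 1) * total - 1) // rng
        sym = bisect_right(cum, scaled) - 1
        out.append(sym)
        c_lo, c_hi = cum[sym], cum[sym + 1]
        high = low + (rng * c_hi) // total - 1
        low = low + (rng * c_lo) // total
        while True:
            if high < half:
                pass
            elif low >= half:
                value -= half
                low -= half
                high -= half
            elif low >= quarter and high < half + quarter:
                value -= quarter
                low -= quarter
                high -= quarter
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | read_bit()
    return out
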