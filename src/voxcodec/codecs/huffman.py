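"""Static Huffman coding over integer symbols (bytes in the baseline use).

The code tree is built bottom-up by repeatedly merging the two least
frequent subtrees; less frequent symbols end up with longer codewords.
Tree construction is made deterministic with a (count, smallest-symbol)
heap tie-break, so both coder sides rebuild the identical table from a
shared frequency table and the table never has to be serialized.
"""

from __future__ import annotations

import heapq
from collections import Counter
from collections.abc import Mapping, Sequence

from .._bits import Bits

__all__ = [
    "code_table_from_counts",
    "huffman_encode",
    "huffman_encode_with_table",
    "huffman_decode",
]


def code_table_from_counts(counts: Mapping[int, int]) -> dict[int, str]:
    """Build the prefix-free codeword table for a symbol→count mapping.

    Deterministic: ties in subtree weight are broken by the smallest symbol
    contained in the subtree; the lighter (or lower-symbol) subtree takes
    branch '0'.  A single-symbol alphabet gets the 1-bit code '0' so the
    stream stays decodable with a symbol count.
    """
    symbols = sorted(s for s, c in counts.items() if c > 0)
    if not symbols:
        raise ValueError("empty alphabet: no symbol has a positive count")
    if len(symbols) == 1:
        return {symbols[0]: "0"}
    # heap entries: (weight, min symbol in subtree, tree); tree is a symbol
    # (leaf) or a (left, right) pair.
    heap: list[tuple[int, int, object]] = [(counts[s], s, s) for s in symbols]
    heapq.heapify(heap)
    while len(heap) > 1:
        w1, m1, t1 = heapq.heappop(heap)
        w2, m2, t2 = heapq.heappop(heap)
        heapq.heappush(heap, (w1 + w2, min(m1, m2), (t1, t2)))
    table: dict[int, str] = {}

    def assign(tree, prefix: str):
        if isinstance(tree, tuple):
            assign(tree[0], prefix + "0")
            assign(tree[1], prefix + "1")
        else:
            table[tree] = prefix

    assign(heap[0][2], "")
    return table


def huffman_encode_with_table(
    data: Sequence[int], table: Mapping[int, str]
) -> Bits:
    """Encode ``data`` with an explicit codeword table."""
    return Bits.from01("".join(map(table.__getitem__, data)))


def huffman_encode(data: Sequence[int]) -> tuple[Bits, dict[int, str]]:
    """Encode a non-empty symbol sequence; returns (payload, code table)."""
    if len(data) == 0:
        raise ValueError("cannot Huffman-encode an empty input")
    table = code_table_from_counts(Counter(data))
    return huffman_encode_with_table(data, table), table


def huffman_decode(bits: Bits, table: Mapping[int, str], n: int) -> bytes:
    """Decode exactly ``n`` symbols; inverse of :func:`huffman_encode`.

    Raises ``ValueError`` if the bitstring runs out before ``n`` symbols or
    if dangling bits remain that decode no complete symbol.
    """
    inverse = {code: sym for sym, code in table.items()}
    out = bytearray()
    cur = ""
    stream = bits.to01()
    pos = 0
    length = len(stream)
    while len(out) < n:
        if pos == length:
            raise ValueError("bitstring exhausted before all symbols decoded")
        cur += stream[pos]
        pos += 1
        sym = inverse.get(cur)
        if sym is not None:
            out.append(sym)
            cur = ""
    if pos != length or cur:
        raise ValueError("dangling bits after the final symbol")
    return bytes(out)
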