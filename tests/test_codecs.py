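"""Entropy coders: round trips, optimality, entropy bounds, oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxcodec._bits import Bits
from voxcodec.codecs import (
    CodeSequence,
    FrequencyModel,
    arithmetic_decode,
    arithmetic_encode,
    code_table_from_counts,
    huffman_decode,
    huffman_encode,
    lzw_decode,
    lzw_encode,
    pack_codes,
    rle_decode,
    rle_encode,
    rle_pack,
    rle_unpack,
    unpack_codes,
)

# ---------------------------------------------------------------------------
# independent oracles


def naive_lzw_encode(data: bytes, capacity: int = 4096) -> list[int]:
    """Straightforward longest-prefix scan over an explicit bytes dictionary."""
    d = {bytes([i]): i for i in range(256)}
    codes, i, n = [], 0, len(data)
    while i < n:
        j = i + 1
        while j + 1 <= n and data[i:j + 1] in d:
            j += 1
        codes.append(d[data[i:j]])
        if j < n and len(d) < capacity:
            d[data[i:j + 1]] = len(d)
        i = j
    return codes


def naive_lzw_decode(codes: list[int], capacity: int = 4096) -> bytes:
    entries = [bytes([i]) for i in range(256)]
    out, prev = b"", None
    for c in codes:
        entry = entries[c] if c < len(entries) else prev + prev[:1]
        out += entry
        if prev is not None and len(entries) < capacity:
            entries.append(prev + entry[:1])
        prev = entry
    return out


def depth_multisets(k: int) -> set[tuple[int, ...]]:
    """All leaf-depth multisets of full binary trees with k leaves."""
    if k == 1:
        return {(0,)}
    out: set[tuple[int, ...]] = set()
    for i in range(1, k):
        for left in depth_multisets(i):
            for right in depth_multisets(k - i):
                out.add(tuple(sorted([d + 1 for d in left + right])))
    return out


def optimal_weighted_length(counts: list[int]) -> int:
    """Exhaustive minimum of sum(count*codelength) over all prefix-free codes."""
    if len(counts) == 1:
        return counts[0]  # 1-bit convention for the degenerate alphabet
    best = math.inf
    weights = sorted(counts, reverse=True)
    for depths in depth_multisets(len(counts)):
        best = min(best, sum(w * d for w, d in zip(weights, sorted(depths))))
    return best


def shannon_bits(symbols) -> float:
    counts = Counter(symbols)
    total = len(symbols)
    return sum(-c * math.log2(c / total) for c in counts.values())


# ---------------------------------------------------------------------------
# Huffman


class TestHuffman:
    def test_single_symbol_stream_uses_one_bit_codes(self):
        bits, table = huffman_encode(b"\x07" * 11)
        assert table == {7: "0"}
        assert len(bits) == 11
        assert huffman_decode(bits, table, 11) == b"\x07" * 11

    def test_three_symbol_code_lengths(self):
        # counts {a:2, b:4, c:2}: the most frequent symbol gets the 1-bit code
        data = b"aabbbbcc"
        _, table = huffman_encode(data)
        lengths = {sym: len(code) for sym, code in table.items()}
        assert lengths[ord("b")] == 1
        assert lengths[ord("a")] == 2 and lengths[ord("c")] == 2

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_weighted_length_is_optimal_for_small_alphabets(self, k, rng):
        for _ in range(20):
            counts = [int(c) for c in rng.integers(1, 50, size=k)]
            table = code_table_from_counts(dict(enumerate(counts)))
            achieved = sum(c * len(table[s]) for s, c in enumerate(counts))
            assert achieved == optimal_weighted_length(counts)

    def test_average_code_length_within_one_bit_of_entropy(self, rng):
        for _ in range(20):
            data = bytes(rng.integers(0, 16, size=500, dtype=np.uint8))
            bits, _ = huffman_encode(data)
            h = shannon_bits(data)
            assert h <= len(bits) < h + len(data)  # avg in [H, H+1)

    def test_truncated_bitstring_raises(self):
        data = b"abcabcab"
        bits, table = huffman_encode(data)
        cut = Bits.from01(bits.to01()[:-3])
        with pytest.raises(ValueError):
            huffman_decode(cut, table, len(data))

    def test_dangling_bits_raise(self):
        bits, table = huffman_encode(b"abab")
        padded = Bits.from01(bits.to01() + "0" * 7)
        with pytest.raises(ValueError, match="dangling"):
            huffman_decode(padded, table, 4)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            huffman_encode(b"")

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.binary(min_size=1, max_size=400))
    def test_roundtrip_identity(self, data):
        bits, table = huffman_encode(data)
        assert huffman_decode(bits, table, len(data)) == data


# ---------------------------------------------------------------------------
# RLE


class TestRLE:
    @pytest.mark.parametrize(
        "data,expected",
        [
            (bytes([5, 5, 5, 0, 0]), [(5, 3), (0, 2)]),
            (b"", []),
            (bytes(range(5)), [(i, 1) for i in range(5)]),
        ],
    )
    def test_known_encodings(self, data, expected):
        assert rle_encode(data) == expected

    def test_run_lengths_sum_to_input_length(self, rng):
        data = bytes(rng.integers(0, 4, size=1000, dtype=np.uint8))
        pairs = rle_encode(data)
        assert sum(r for _, r in pairs) == len(data)
        assert all(r >= 1 for _, r in pairs)
        assert all(a != b for (a, _), (b, _) in zip(pairs, pairs[1:]))

    def test_long_runs_split_at_serialization(self):
        data = bytes([9]) * 70000
        payload, n_pairs = rle_pack(rle_encode(data))
        assert n_pairs == 2  # 65535 + 4465
        assert rle_decode(rle_unpack(payload, n_pairs)) == data

    def test_nonpositive_run_raises(self):
        with pytest.raises(ValueError):
            rle_decode([(5, 0)])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.binary(max_size=400))
    def test_roundtrip_identity(self, data):
        pairs = rle_encode(data)
        assert rle_decode(pairs) == data
        payload, n = rle_pack(pairs)
        assert rle_decode(rle_unpack(payload, n)) == data


# ---------------------------------------------------------------------------
# LZW


class TestLZW:
    def test_empty_input(self):
        seq = lzw_encode(b"")
        assert seq.codes == [] and len(seq) == 0
        assert lzw_decode(seq) == b""

    def test_all_distinct_bytes_emit_literals_only(self):
        data = bytes(range(100))
        seq = lzw_encode(data)
        assert len(seq.codes) == 100
        assert all(c < 256 for c in seq.codes)

    def test_classic_repetitive_string_matches_naive_oracle(self):
        data = b"TOBEORNOTTOBEORNOTTOBEORNOT"
        assert lzw_encode(data).codes == naive_lzw_encode(data)

    def test_matches_naive_oracle_on_random_and_periodic_streams(self, rng):
        streams = [
            bytes(rng.integers(0, 8, size=600, dtype=np.uint8)),
            bytes(rng.integers(0, 256, size=600, dtype=np.uint8)),
            b"ab" * 300,
            b"\x00" * 997,
            bytes(rng.integers(0, 3, size=5000, dtype=np.uint8)),
        ]
        for data in streams:
            codes = lzw_encode(data).codes
            assert codes == naive_lzw_encode(data)
            assert lzw_decode(codes) == data
            assert naive_lzw_decode(codes) == data

    def test_self_referential_code_roundtrip(self):
        # cScSc pattern: the decoder receives a code equal to the next
        # unassigned dictionary index
        data = b"abababab" * 10
        seq = lzw_encode(data)
        # decoding codes[t] sees a dictionary of 256 + t - 1 entries; the
        # special case fires when the code equals that next unassigned index
        assert any(c == 255 + t for t, c in enumerate(seq.codes) if t >= 1)
        assert lzw_decode(seq) == data

    def test_codes_never_reach_capacity(self, rng):
        data = bytes(rng.integers(0, 256, size=20000, dtype=np.uint8))
        seq = lzw_encode(data)
        assert seq.max_code < 4096
        assert lzw_decode(seq) == data

    def test_dictionary_freezes_at_reduced_capacity(self, rng):
        data = bytes(rng.integers(0, 256, size=5000, dtype=np.uint8))
        seq = lzw_encode(data, capacity=300)
        assert seq.max_code < 300
        assert lzw_decode(seq, capacity=300) == data

    def test_corrupt_code_stream_raises(self):
        with pytest.raises(ValueError, match="corrupt"):
            lzw_decode([65, 300])  # 300 not yet assignable after one literal

    def test_pack_unpack_roundtrip(self, rng):
        codes = [int(c) for c in rng.integers(0, 4096, size=500)]
        bits = pack_codes(codes)
        assert len(bits) == 12 * len(codes)
        assert unpack_codes(bits, len(codes)) == codes

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.binary(max_size=400))
    def test_roundtrip_identity(self, data):
        assert lzw_decode(lzw_encode(data)) == data


# ---------------------------------------------------------------------------
# Arithmetic


class TestArithmetic:
    def test_single_symbol_alphabet_costs_only_termination(self):
        model = FrequencyModel([10])
        bits = arithmetic_encode([0] * 100, model)
        assert len(bits) <= 2
        assert arithmetic_decode(bits, model, 100) == [0] * 100

    def test_two_equiprobable_symbols_cost_one_bit_each(self, rng):
        model = FrequencyModel([1, 1])
        symbols = [int(s) for s in rng.integers(0, 2, size=256)]
        bits = arithmetic_encode(symbols, model)
        assert 256 <= len(bits) <= 258
        assert arithmetic_decode(bits, model, 256) == symbols

    def test_skewed_three_symbol_stream_meets_entropy_bound(self):
        counts = {0: 6, 1: 2, 2: 2}
        symbols = [0] * 6 + [1] * 2 + [2] * 2
        model = FrequencyModel([6, 2, 2])
        bound = math.ceil(
            sum(-math.log2(counts[s] / 10) for s in symbols)
        )
        bits = arithmetic_encode(symbols, model)
        assert len(bits) <= bound + 2
        assert arithmetic_decode(bits, model, len(symbols)) == symbols

    def test_symbol_outside_alphabet_raises(self):
        model = FrequencyModel([1, 1])
        with pytest.raises(ValueError):
            arithmetic_encode([2], model)

    def test_zero_probability_symbol_raises(self):
        model = FrequencyModel([4, 0, 4])
        with pytest.raises(ValueError, match="zero probability"):
            arithmetic_encode([1], model)

    def test_exhausted_bitstring_raises(self):
        model = FrequencyModel([1, 1])
        with pytest.raises(ValueError, match="exhausted"):
            arithmetic_decode(Bits(), model, 100)

    def test_scaled_model_preserves_roundtrip(self, rng):
        symbols = [int(s) for s in rng.integers(0, 4, size=300)]
        model = FrequencyModel(
            [1_000_000, 300_000, 50_000, 1]
        ).scaled()
        assert max(model.counts) <= 0xFFFF and min(model.counts) >= 1
        bits = arithmetic_encode(symbols, model)
        assert arithmetic_decode(bits, model, 300) == symbols

    def test_zero_count_symbols_skipped_in_decode(self):
        # gaps in the alphabet (unused LZW indices) must not confuse decode
        model = FrequencyModel([5, 0, 0, 3, 0, 2])
        symbols = [0, 3, 5, 0, 0, 3, 5, 0, 3, 0]
        bits = arithmetic_encode(symbols, model)
        assert arithmetic_decode(bits, model, len(symbols)) == symbols

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=300))
    def test_roundtrip_identity(self, symbols):
        model = FrequencyModel(np.bincount(symbols, minlength=8))
        bits = arithmetic_encode(symbols, model)
        assert arithmetic_decode(bits, model, len(symbols)) == symbols
        h = shannon_bits(symbols)
        assert len(bits) <= math.ceil(h) + 16
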