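"""The hybrid VOI → LZW → arithmetic compression pipeline and its inverse.

The encoder: (1) locate and extract the volume of interest with the
selective bounding volume procedure; (2) serialize the VOI slice-major to
a byte stream; (3) LZW-code the stream and arithmetic-code the resulting
dictionary indices under a static frequency model; (4) store payload, VOI
coordinates, and the model table in the container.  The decoder runs the
chain in reverse and fuses the decoded VOI into a zero background of the
original shape, which makes the round trip bit-exact.

The four baseline coders (Huffman, RLE, LZW at fixed 12-bit codes, plain
arithmetic) operate on the *same* serialized VOI byte stream, so codec
comparisons are apples-to-apples; disabling ``use_voi`` runs any codec on
the full grid instead (the comparison arm without VOI extraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._bits import Bits
from .codecs import arithmetic, huffman, lzw, rle
from .sbv import VOIRecord, compute_sbv, extract_voi, fuse_voi
from .volume_io import (
    Codec,
    CompressedContainer,
    stream_to_volume,
    volume_to_stream,
)

__all__ = ["CodecConfig", "compress", "decompress", "compress_with_baseline"]


@dataclass(frozen=True)
class CodecConfig:
    """Knobs of the compression pipeline.

    ``use_voi`` off runs the identical entropy chain on the full grid —
    the ablation arm that quantifies what VOI extraction itself buys.
    """

    codec: Codec = Codec.L_TO_A
    use_voi: bool = True
    lzw_capacity: int = 4096
    ac_precision_bits: int = 32

    def __post_init__(self):
        if self.lzw_capacity < 256:
            raise ValueError("lzw_capacity must be >= 256")
        if not 16 <= self.ac_precision_bits <= 62:
            raise ValueError("ac_precision_bits must be in [16, 62]")


def _encode_payload(
    stream: bytes, config: CodecConfig
) -> tuple[Bits, tuple[int, ...] | None, int]:
    """Entropy-code a byte stream; returns (payload, model table, symbol count)."""
    codec = config.codec
    if codec is Codec.L_TO_A:
        codes = lzw.lzw_encode(stream, config.lzw_capacity)
        model = arithmetic.FrequencyModel.from_symbols(
            codes.codes, codes.max_code + 1
        ).scaled()
        payload = arithmetic.arithmetic_encode(
            codes.codes, model, config.ac_precision_bits
        )
        return payload, tuple(model.counts), len(codes)
    if codec is Codec.AC:
        model = arithmetic.FrequencyModel.from_symbols(
            np.frombuffer(stream, dtype=np.uint8), 256
        ).scaled()
        payload = arithmetic.arithmetic_encode(
            memoryview(stream), model, config.ac_precision_bits
        )
        return payload, tuple(model.counts), len(stream)
    if codec is Codec.HUFFMAN:
        model = arithmetic.FrequencyModel(
            np.bincount(np.frombuffer(stream, np.uint8), minlength=256)
        ).scaled()
        table = huffman.code_table_from_counts(dict(enumerate(model.counts)))
        payload = huffman.huffman_encode_with_table(stream, table)
        return payload, tuple(model.counts), len(stream)
    if codec is Codec.LZW:
        codes = lzw.lzw_encode(stream, config.lzw_capacity)
        width = max(12, (config.lzw_capacity - 1).bit_length())
        return lzw.pack_codes(codes.codes, width), None, len(codes)
    if codec is Codec.RLE:
        payload, n_pairs = rle.rle_pack(rle.rle_encode(stream))
        return payload, None, n_pairs
    raise ValueError(f"unknown codec {codec!r}")


def _decode_payload(container: CompressedContainer, expected_len: int) -> bytes:
    """Invert :func:`_encode_payload`; validates the decoded byte count."""
    codec = container.codec
    n = container.symbol_count
    if codec is Codec.L_TO_A:
        model = arithmetic.FrequencyModel(container.model_counts)
        codes = arithmetic.arithmetic_decode(
            container.payload, model, n, container.ac_precision
        )
        stream = lzw.lzw_decode(codes, container.lzw_capacity)
    elif codec is Codec.AC:
        model = arithmetic.FrequencyModel(container.model_counts)
        stream = bytes(
            arithmetic.arithmetic_decode(
                container.payload, model, n, container.ac_precision
            )
        )
    elif codec is Codec.HUFFMAN:
        table = huffman.code_table_from_counts(
            dict(enumerate(container.model_counts))
        )
        stream = huffman.huffman_decode(container.payload, table, n)
    elif codec is Codec.LZW:
        width = max(12, (container.lzw_capacity - 1).bit_length())
        codes = lzw.unpack_codes(container.payload, n, width)
        stream = lzw.lzw_decode(codes, container.lzw_capacity)
    elif codec is Codec.RLE:
        stream = rle.rle_decode(rle.rle_unpack(container.payload, n))
    else:  # pragma: no cover
        raise ValueError(f"unknown codec {codec!r}")
    if len(stream) != expected_len:
        raise ValueError(
            f"decoded stream has {len(stream)} bytes, expected {expected_len}"
        )
    return stream


def compress(volume: np.ndarray, config: CodecConfig | None = None) -> CompressedContainer:
    """Compress a volume into a container under ``config`` (hybrid by default).

    An all-zero volume with VOI extraction enabled yields a degenerate
    header-only container (symbol count 0) that decompresses back to the
    all-zero volume of the original shape.
    """
    if config is None:
        config = CodecConfig()
    volume = np.asarray(volume)
    if volume.dtype != np.uint8:
        if volume.size and (volume.min() < 0 or volume.max() > 255):
            raise ValueError("bit depth exceeds 8: intensities outside [0, 255]")
        volume = volume.astype(np.uint8)
    shape = tuple(int(s) for s in volume.shape)
    if config.use_voi:
        if not volume.any():
            return CompressedContainer(
                codec=config.codec,
                original_shape=shape,
                voi=VOIRecord.full_grid(shape),
                payload=Bits(),
                symbol_count=0,
                empty=True,
                lzw_capacity=config.lzw_capacity,
                ac_precision=config.ac_precision_bits,
            )
        voi = compute_sbv(volume)
        sub = extract_voi(volume, voi)
    else:
        voi = VOIRecord.full_grid(shape)
        sub = volume
    payload, model, symbol_count = _encode_payload(volume_to_stream(sub), config)
    return CompressedContainer(
        codec=config.codec,
        original_shape=shape,
        voi=voi,
        payload=payload,
        symbol_count=symbol_count,
        model_counts=model,
        lzw_capacity=config.lzw_capacity,
        ac_precision=config.ac_precision_bits,
    )


def compress_with_baseline(
    volume: np.ndarray, codec: Codec | str, use_voi: bool = True
) -> CompressedContainer:
    """Compress with one named baseline codec over the same VOI stream."""
    return compress(volume, CodecConfig(codec=Codec(codec), use_voi=use_voi))


def decompress(container: CompressedContainer) -> np.ndarray:
    """Reconstruct the exact original volume from a container."""
    if container.empty:
        return np.zeros(container.original_shape, dtype=np.uint8)
    box = container.voi.box_shape
    stream = _decode_payload(container, box[0] * box[1] * box[2])
    sub = stream_to_volume(stream, box)
    return fuse_voi(sub, container.voi)
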