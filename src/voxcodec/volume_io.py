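"""Volume and container I/O.

Volumes are 3D ``uint8`` arrays indexed ``[row, column, slice]``.  Two
on-disk volume formats are supported: NIfTI-1 (via nibabel; the affine is
preserved on write but ignored by the codec) and a bespoke raw ``.vol``
format — a 12-byte little-endian shape header followed by voxel bytes in
slice-major order (slices consecutive, each slice row-major).  Intensities
above 8 bits are a hard error, never rescaled: the codec's contract is
lossless and the method targets 8-bit volumes.

The compressed artifact is the ``.v3dc`` container: a fixed little-endian
header (magic, version, codec id, flags, original shape, VOI coordinates,
codec parameters, symbol count, payload bit length), an optional
length-prefixed symbol-frequency table, and the entropy-coded payload
padded to a byte boundary.  Header plus VOI record are sufficient to
reconstruct the full volume with zero side information.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from ._bits import Bits
from .sbv import VOIRecord

__all__ = [
    "Codec",
    "CompressedContainer",
    "ContainerError",
    "read_volume",
    "write_volume",
    "read_container",
    "write_container",
    "volume_to_stream",
    "stream_to_volume",
    "CONTAINER_MAGIC",
    "CONTAINER_HEADER_SIZE",
]

CONTAINER_MAGIC = b"V3DC"
CONTAINER_VERSION = 1
# magic(4) version(1) codec(1) flags(1) capacity(u32) precision(1)
# shape(3*u32) voi(6*u32) symbol_count(u64) payload_bit_length(u64)
# model_len(u32)
_HEADER_FMT = "<4sBBBIB3I6IQQI"
CONTAINER_HEADER_SIZE = struct.calcsize(_HEADER_FMT)

_FLAG_EMPTY = 0x01  # degenerate container of an all-zero volume


class Codec(str, enum.Enum):
    """Identifier of the entropy chain used for the payload."""

    HUFFMAN = "huffman"
    RLE = "rle"
    LZW = "lzw"
    AC = "ac"
    L_TO_A = "l_to_a"


_CODEC_IDS = {c: i for i, c in enumerate(Codec)}
_IDS_CODEC = {i: c for c, i in _CODEC_IDS.items()}


class ContainerError(ValueError):
    """Malformed or truncated container file."""


@dataclass(frozen=True)
class CompressedContainer:
    """In-memory form of one ``.v3dc`` file."""

    codec: Codec
    original_shape: tuple[int, int, int]
    voi: VOIRecord
    payload: Bits
    symbol_count: int
    model_counts: tuple[int, ...] | None = None
    empty: bool = False
    lzw_capacity: int = 4096
    ac_precision: int = 32

    def serialized_size(self) -> int:
        """Byte size of the container on disk (the n2 of the CR metric)."""
        size = CONTAINER_HEADER_SIZE + len(self.payload.data)
        if self.model_counts is not None:
            size += 2 * len(self.model_counts)
        return size


# ---------------------------------------------------------------------------
# voxel-stream serialization (the byte order every codec consumes)

def volume_to_stream(volume: np.ndarray) -> bytes:
    """Serialize a volume slice-major (slices consecutive, rows within)."""
    return np.ascontiguousarray(np.transpose(volume, (2, 0, 1))).tobytes()


def stream_to_volume(stream: bytes, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`volume_to_stream`."""
    x, y, z = shape
    if len(stream) != x * y * z:
        raise ValueError(f"stream of {len(stream)} bytes cannot fill shape {shape}")
    arr = np.frombuffer(stream, dtype=np.uint8).reshape(z, x, y)
    return np.ascontiguousarray(np.transpose(arr, (1, 2, 0)))


# ---------------------------------------------------------------------------
# volumes

def _validate_volume(arr: np.ndarray) -> np.ndarray:
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {arr.ndim} dimensions")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError("volume intensities must be integers")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("bit depth exceeds 8: intensities outside [0, 255]")
    return arr.astype(np.uint8)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("nifti", "raw"):
            raise ValueError(f"unknown volume format {fmt!r}")
        return fmt
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "raw"


def read_volume(path, format: str | None = None) -> np.ndarray:
    """Read a 3D 8-bit volume from NIfTI or raw ``.vol``.

    Values outside [0, 255] raise — no silent clamping or rescaling.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        return _validate_volume(np.asarray(data))
    raw = path.read_bytes()
    if len(raw) < 12:
        raise ValueError(f"{path}: raw volume file too short for a shape header")
    x, y, z = struct.unpack("<3I", raw[:12])
    if len(raw) - 12 != x * y * z:
        raise ValueError(f"{path}: raw payload does not match shape ({x},{y},{z})")
    return stream_to_volume(raw[12:], (x, y, z))


def write_volume(volume: np.ndarray, path, format: str | None = None) -> None:
    """Write a volume so that :func:`read_volume` returns it voxel-identical."""
    volume = _validate_volume(np.asarray(volume))
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        nib.save(nib.Nifti1Image(volume, affine=np.eye(4)), str(path))
        return
    x, y, z = volume.shape
    path.write_bytes(struct.pack("<3I", x, y, z) + volume_to_stream(volume))


# ---------------------------------------------------------------------------
# containers

def write_container(container: CompressedContainer, path) -> int:
    """Serialize a container; returns the number of bytes written."""
    voi = container.voi
    model = container.model_counts
    flags = _FLAG_EMPTY if container.empty else 0
    header = struct.pack(
        _HEADER_FMT,
        CONTAINER_MAGIC,
        CONTAINER_VERSION,
        _CODEC_IDS[container.codec],
        flags,
        container.lzw_capacity,
        container.ac_precision,
        *container.original_shape,
        voi.row_min, voi.col_min, voi.row_max, voi.col_max,
        voi.z_first, voi.z_last,
        container.symbol_count,
        container.payload.length,
        0 if model is None else len(model),
    )
    blob = bytearray(header)
    if model is not None:
        if any(not 0 <= c <= 0xFFFF for c in model):
            raise ValueError("model counts must fit in 16 bits")
        blob += struct.pack(f"<{len(model)}H", *model)
    blob += container.payload.data
    Path(path).write_bytes(blob)
    return len(blob)


def read_container(path) -> CompressedContainer:
    """Parse a ``.v3dc`` file back into a :class:`CompressedContainer`."""
    raw = Path(path).read_bytes()
    if len(raw) < CONTAINER_HEADER_SIZE or raw[:4] != CONTAINER_MAGIC:
        raise ContainerError(f"{path}: not a voxcodec container")
    (
        _magic, version, codec_id, flags, lzw_capacity, ac_precision,
        sx, sy, sz,
        row_min, col_min, row_max, col_max, z_first, z_last,
        symbol_count, payload_bit_length, model_len,
    ) = struct.unpack_from(_HEADER_FMT, raw)
    if version != CONTAINER_VERSION:
        raise ContainerError(f"{path}: unsupported container version {version}")
    if codec_id not in _IDS_CODEC:
        raise ContainerError(f"{path}: unknown codec id {codec_id}")
    offset = CONTAINER_HEADER_SIZE
    model: tuple[int, ...] | None = None
    if model_len:
        end = offset + 2 * model_len
        if len(raw) < end:
            raise ContainerError(f"{path}: truncated model table")
        model = struct.unpack_from(f"<{model_len}H", raw, offset)
        offset = end
    payload_bytes = raw[offset:]
    if 8 * len(payload_bytes) < payload_bit_length:
        raise ContainerError(f"{path}: truncated payload")
    nbytes = (payload_bit_length + 7) // 8
    payload = Bits(payload_bytes[:nbytes], payload_bit_length)
    return CompressedContainer(
        codec=_IDS_CODEC[codec_id],
        original_shape=(sx, sy, sz),
        voi=VOIRecord(row_min, col_min, row_max, col_max, z_first, z_last, (sx, sy, sz)),
        payload=payload,
        symbol_count=symbol_count,
        model_counts=model,
        empty=bool(flags & _FLAG_EMPTY),
        lzw_capacity=lzw_capacity,
        ac_precision=ac_precision,
    )
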