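"""Selective bounding volume (SBV) extraction of the volume of interest.

Medical 3D volumes (MRI/CT/PET) are typically surrounded by an exactly-zero
background, and the leading/trailing slices of an acquisition are often
entirely blank.  The SBV procedure exploits this: it drops the blank head
and tail slices, takes the tight 2D bounding box of the nonzero support of
every remaining slice, and aggregates the per-slice boxes into one global
axis-aligned box — the volume of interest (VOI).  Only the VOI enters the
entropy coder; the box coordinates are enough to rebuild the full volume
exactly, which is what makes the whole codec lossless.

Conventions: volumes are ``uint8`` arrays indexed ``[row, column, slice]``;
all coordinates are 0-based inclusive.  A "blank" slice is one whose every
voxel is exactly 0 — no tolerance is applied, since any threshold would
break the zero-background reconstruction contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class BlankVolumeError(ValueError):
    """Raised when a VOI is requested for an all-zero volume."""


@dataclass(frozen=True)
class VOIRecord:
    """Reconstruction metadata for one extracted VOI.

    All six coordinates are 0-based inclusive indices into the original
    volume; ``original_shape`` is the (rows, columns, slices) extent of the
    source grid.  Together they are the only side information the decoder
    needs to re-fuse a decoded VOI into a full-size volume.
    """

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    z_first: int
    z_last: int
    original_shape: tuple[int, int, int]

    def __post_init__(self):
        x, y, z = self.original_shape
        if not (0 <= self.row_min <= self.row_max < x):
            raise ValueError(f"row range [{self.row_min}, {self.row_max}] not in [0, {x})")
        if not (0 <= self.col_min <= self.col_max < y):
            raise ValueError(f"column range [{self.col_min}, {self.col_max}] not in [0, {y})")
        if not (0 <= self.z_first <= self.z_last < z):
            raise ValueError(f"slice range [{self.z_first}, {self.z_last}] not in [0, {z})")

    @property
    def box_shape(self) -> tuple[int, int, int]:
        """Extent of the VOI box (rows, columns, slices)."""
        return (
            self.row_max - self.row_min + 1,
            self.col_max - self.col_min + 1,
            self.z_last - self.z_first + 1,
        )

    @classmethod
    def full_grid(cls, shape: tuple[int, int, int]) -> "VOIRecord":
        """A record covering the entire grid (the no-VOI arm)."""
        x, y, z = shape
        return cls(0, 0, x - 1, y - 1, 0, z - 1, (x, y, z))


def find_nonblank_range(volume: np.ndarray) -> tuple[int, int]:
    """Return (z_first, z_last), the inclusive range of non-blank slices.

    Interior all-zero slices between the first and last non-blank slice are
    deliberately kept inside the range: the procedure records only the
    starting and ending non-blank slice, not a per-slice mask.

    Raises
    ------
    BlankVolumeError
        If every voxel of the volume is zero.
    """
    volume = np.asarray(volume)
    nonblank = volume.any(axis=(0, 1))
    if not nonblank.any():
        raise BlankVolumeError("no VOI: volume is blank")
    idx = np.flatnonzero(nonblank)
    return int(idx[0]), int(idx[-1])


def slice_bounding_box(slice2d: np.ndarray) -> tuple[int, int, int, int] | None:
    """Tightest (row_min, col_min, row_max, col_max) box of a slice's nonzero
    pixels, or ``None`` for an all-zero slice."""
    slice2d = np.asarray(slice2d)
    rows = np.flatnonzero(slice2d.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(slice2d.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])


def compute_sbv(volume: np.ndarray) -> VOIRecord:
    """Compute the global selective bounding volume of a volume.

    Scans each slice in the non-blank range, takes its 2D bounding box, and
    aggregates the per-slice minima/maxima into one global box — tight by
    construction: every face touches at least one nonzero voxel.
    """
    volume = np.asarray(volume)
    z_first, z_last = find_nonblank_range(volume)
    row_min = col_min = None
    row_max = col_max = None
    for k in range(z_first, z_last + 1):
        box = slice_bounding_box(volume[:, :, k])
        if box is None:
            continue  # interior blank slice: stays in the z range, no box update
        r0, c0, r1, c1 = box
        row_min = r0 if row_min is None else min(row_min, r0)
        col_min = c0 if col_min is None else min(col_min, c0)
        row_max = r1 if row_max is None else max(row_max, r1)
        col_max = c1 if col_max is None else max(col_max, c1)
    return VOIRecord(
        row_min, col_min, row_max, col_max, z_first, z_last,
        tuple(int(s) for s in volume.shape),
    )


def extract_voi(volume: np.ndarray, voi: VOIRecord) -> np.ndarray:
    """Copy the VOI box out of ``volume`` (voxels untransformed)."""
    volume = np.asarray(volume)
    if tuple(volume.shape) != voi.original_shape:
        raise ValueError(
            f"volume shape {tuple(volume.shape)} != record shape {voi.original_shape}"
        )
    return volume[
        voi.row_min : voi.row_max + 1,
        voi.col_min : voi.col_max + 1,
        voi.z_first : voi.z_last + 1,
    ].copy()


def fuse_voi(voi_volume: np.ndarray, voi: VOIRecord) -> np.ndarray:
    """Fuse a decoded VOI back into a zero background of the original shape.

    Inverse of :func:`extract_voi` for any volume whose nonzero voxels all
    lie inside the box; the round trip is bit-exact.
    """
    voi_volume = np.asarray(voi_volume)
    if tuple(voi_volume.shape) != voi.box_shape:
        raise ValueError(
            f"VOI shape {tuple(voi_volume.shape)} != box shape {voi.box_shape}"
        )
    out = np.zeros(voi.original_shape, dtype=voi_volume.dtype)
    out[
        voi.row_min : voi.row_max + 1,
        voi.col_min : voi.col_max + 1,
        voi.z_first : voi.z_last + 1,
    ] = voi_volume
    return out
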