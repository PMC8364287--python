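"""Compression and reconstruction-quality metrics.

Compression ratio CR = n1 / n2 (original bits over compressed bits) and
bit rate BPV = C / N (compressed bits per voxel) are returned as exact
rationals, so the algebraic identities CR × n2 = n1 and BPV = 8 / CR
(for 8-bit sources) hold literally rather than to rounding error.  n1 is
defined as 8 bits per voxel times the voxel count — deterministic and
independent of the source file format — and n2 is the full container
size on disk, side information included.

Reconstruction quality: MSE (exact, computed in wide integers), PSNR
= 10·log10(MAX² / MSE) with +inf at MSE = 0, and a mean structural
similarity index computed slice-wise with a uniform sliding window.
SSIM combines per-window luminance, contrast, and structure terms

    l = (2 μx μy + c1) / (μx² + μy² + c1)
    c = (2 σx σy + c2) / (σx² + σy² + c2)
    s = (σxy + c3) / (σx σy + c3)

raised to exponents α, β, γ (all 1 by default) and averaged over all
windows and slices.  For a lossless codec MSE is 0, PSNR is +inf and
SSIM is exactly 1 — the quantities the pipeline's tests pin down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SSIMParams",
    "MetricsReport",
    "compression_ratio",
    "bits_per_voxel",
    "mse",
    "psnr",
    "ssim",
    "evaluate",
]


@dataclass(frozen=True)
class SSIMParams:
    """Window and stabilizer settings for the mean SSIM.

    Defaults: 8×8 uniform window, dynamic range L = 255 (8-bit),
    c1 = (0.01 L)², c2 = (0.03 L)², c3 = c2 / 2, α = β = γ = 1.
    """

    window: int = 8
    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


@dataclass(frozen=True)
class MetricsReport:
    """All comparison metrics for one original/decompressed/container triple."""

    cr: Fraction
    bpv: Fraction
    mse: float
    psnr: float
    ssim: float
    n1: int
    n2: int
    voxels: int


def compression_ratio(n1: int, n2: int) -> Fraction:
    """CR = n1 / n2, exact."""
    if n2 <= 0:
        raise ValueError("compressed size must be positive")
    return Fraction(n1, n2)


def bits_per_voxel(compressed_bits: int, voxels: int) -> Fraction:
    """BPV = C / N, exact."""
    if voxels <= 0:
        raise ValueError("voxel count must be positive")
    return Fraction(compressed_bits, voxels)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity error, exact (wide-integer accumulation)."""
    a, b = np.asarray(a), np.asarray(b)
    _check_shapes(a, b)
    diff = a.astype(np.int64) - b.astype(np.int64)
    return int(np.sum(diff * diff)) / a.size


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf iff the volumes are identical."""
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val * max_val / err)


def _ssim_slice(x: np.ndarray, y: np.ndarray, params: SSIMParams) -> np.ndarray:
    """Per-window SSIM values for one 2D slice pair (uniform window)."""
    w = params.window
    wx = sliding_window_view(x, (w, w)).reshape(-1, w * w).astype(np.float64)
    wy = sliding_window_view(y, (w, w)).reshape(-1, w * w).astype(np.float64)
    mx = wx.mean(axis=1)
    my = wy.mean(axis=1)
    # population moments (ddof = 0)
    vx = (wx * wx).mean(axis=1) - mx * mx
    vy = (wy * wy).mean(axis=1) - my * my
    cov = (wx * wy).mean(axis=1) - mx * my
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    sx = np.sqrt(vx)
    sy = np.sqrt(vy)
    c1, c2, c3 = params.c1, params.c2, params.c3
    lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
    con = (2 * sx * sy + c2) / (vx + vy + c2)
    stru = (cov + c3) / (sx * sy + c3)
    return (
        np.power(lum, params.alpha)
        * np.power(con, params.beta)
        * np.power(stru, params.gamma)
    )


def ssim(a: np.ndarray, b: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean SSIM over all 2D windows of all slices; 1.0 iff structure matches.

    Identical volumes give exactly 1 for any window and stabilizer choice.
    """
    if params is None:
        params = SSIMParams()
    a, b = np.asarray(a), np.asarray(b)
    _check_shapes(a, b)
    if a.ndim == 2:
        a = a[:, :, None]
        b = b[:, :, None]
    if a.ndim != 3:
        raise ValueError("ssim expects 2D slices or 3D volumes")
    w = params.window
    if a.shape[0] < w or a.shape[1] < w:
        raise ValueError(
            f"window {w}x{w} larger than slice extent {a.shape[0]}x{a.shape[1]}"
        )
    values = [
        _ssim_slice(a[:, :, k], b[:, :, k], params) for k in range(a.shape[2])
    ]
    return float(np.mean(np.concatenate(values)))


def evaluate(
    original: np.ndarray,
    decompressed: np.ndarray,
    compressed_bytes: int,
    ssim_params: SSIMParams | None = None,
) -> MetricsReport:
    """Full metrics for one original/reconstruction pair and container size."""
    original = np.asarray(original)
    voxels = int(original.size)
    n1 = 8 * voxels
    n2 = 8 * int(compressed_bytes)
    return MetricsReport(
        cr=compression_ratio(n1, n2),
        bpv=bits_per_voxel(n2, voxels),
        mse=mse(original, decompressed),
        psnr=psnr(original, decompressed),
        ssim=ssim(original, decompressed, ssim_params),
        n1=n1,
        n2=n2,
        voxels=voxels,
    )
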