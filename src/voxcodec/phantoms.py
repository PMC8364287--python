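"""Deterministic synthetic 3D phantoms with medical-image structure.

Real MRI/CT/PET head volumes share three structural features the codec
exploits: an exactly-zero background surrounding the anatomy, blank
leading/trailing slices, and a compact, piecewise-smooth foreground.  The
generator emulates exactly these: a soft ellipsoid whose intensity is
quantized into a few tissue-like gray bands (producing the long zero runs
and repeated local patterns that run-length and dictionary coders feed
on), optionally perturbed by salt noise on a fraction of foreground
voxels.  It does not attempt anatomical realism (no cortical folding,
partial-volume edges, or scanner noise floors), so comparative codec
rankings measured on phantoms are qualitative, not clinical benchmarks.

All randomness comes from ``numpy.random.default_rng`` (PCG64) seeded
from the spec's ``seed`` field, so the same spec yields byte-identical
volumes on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "fixture_suite",
    "background_fraction",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20210507


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one ellipsoidal phantom.

    ``center``/``semi_axes`` are in voxel units; the ellipsoid must fit
    strictly inside the grid and inside the non-blank slice range.
    ``intensity_levels`` distinct gray bands are laid out radially;
    ``noise_fraction`` of foreground voxels are replaced by random
    nonzero intensities (salt noise).
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    blank_slices_head: int = 2
    blank_slices_tail: int = 2
    center: tuple[float, float, float] | None = None
    semi_axes: tuple[float, float, float] | None = None
    intensity_levels: int = 4
    noise_fraction: float = 0.0
    seed: int = DEFAULT_SEED

    def resolved_geometry(self):
        x, y, z = self.shape
        head, tail = self.blank_slices_head, self.blank_slices_tail
        if head + tail >= z:
            raise ValueError("blank head+tail slices leave no active slices")
        z0, z1 = head, z - tail - 1  # inclusive active range
        center = self.center
        if center is None:
            center = ((x - 1) / 2, (y - 1) / 2, (z0 + z1) / 2)
        axes = self.semi_axes
        if axes is None:
            # span the full active slice range so its boundary slices are
            # non-blank, without leaking into the blank head/tail
            axes = (0.35 * x, 0.4 * y, 0.5 * (z1 - z0) + 0.75)
        cx, cy, cz = center
        ax, ay, az = axes
        if min(ax, ay, az) <= 0:
            raise ValueError("semi-axes must be positive")
        if not (0 < cx - ax and cx + ax < x - 1 and 0 < cy - ay and cy + ay < y - 1):
            raise ValueError("ellipsoid does not fit strictly inside the grid")
        if not (z0 - 1 < cz - az and cz + az < z1 + 1):
            raise ValueError("ellipsoid extends into the blank slice range")
        if not 1 <= self.intensity_levels <= 255:
            raise ValueError("intensity_levels must be in [1, 255]")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        return center, axes


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom described by ``spec`` as a uint8 volume."""
    (cx, cy, cz), (ax, ay, az) = spec.resolved_geometry()
    x, y, z = spec.shape
    ii, jj, kk = np.meshgrid(
        np.arange(x), np.arange(y), np.arange(z), indexing="ij"
    )
    r2 = (
        ((ii - cx) / ax) ** 2
        + ((jj - cy) / ay) ** 2
        + ((kk - cz) / az) ** 2
    )
    inside = r2 <= 1.0
    vol = np.zeros(spec.shape, dtype=np.uint8)
    if spec.intensity_levels == 1:
        vol[inside] = 200
    else:
        # radial bands: innermost brightest, quantized to distinct gray levels
        band = np.minimum(
            (np.sqrt(np.clip(r2, 0.0, 1.0)) * spec.intensity_levels).astype(int),
            spec.intensity_levels - 1,
        )
        levels = np.linspace(220, 60, spec.intensity_levels).astype(np.uint8)
        vol[inside] = levels[band[inside]]
    if spec.noise_fraction > 0.0:
        rng = np.random.default_rng(spec.seed)
        fg = np.flatnonzero(inside.ravel())
        n_noise = int(round(spec.noise_fraction * fg.size))
        if n_noise:
            picks = rng.choice(fg, size=n_noise, replace=False)
            flat = vol.ravel()
            flat[picks] = rng.integers(1, 256, size=n_noise, dtype=np.uint8)
    return vol


def background_fraction(volume: np.ndarray) -> float:
    """Fraction of exactly-zero voxels (the codec's notion of background)."""
    volume = np.asarray(volume)
    return float(np.count_nonzero(volume == 0) / volume.size)


def fixture_suite(seed: int = DEFAULT_SEED) -> dict[str, np.ndarray]:
    """The named test-volume suite used throughout the package's tests.

    Spans the structural regimes the codec must handle: an all-zero
    volume, a single nonzero voxel, a full-grid foreground, MRI-like and
    CT-like phantoms with high zero background, an interior blank slice,
    a periodic texture, and an incompressible uniform-random control.
    All shapes are at most 64×64×32 so the whole suite runs in seconds.
    """
    rng = np.random.default_rng(seed)
    fixtures: dict[str, np.ndarray] = {}

    fixtures["all_zero"] = np.zeros((16, 16, 8), dtype=np.uint8)

    single = np.zeros((16, 16, 8), dtype=np.uint8)
    single[7, 9, 3] = 180
    fixtures["single_voxel"] = single

    ii, jj, kk = np.meshgrid(
        np.arange(32), np.arange(32), np.arange(12), indexing="ij"
    )
    fixtures["full_grid"] = ((ii + jj + kk) % 200 + 1).astype(np.uint8)

    fixtures["mri_like"] = generate_phantom(
        PhantomSpec(
            shape=(64, 64, 24),
            blank_slices_head=3,
            blank_slices_tail=3,
            semi_axes=(14.0, 16.0, 7.0),
            intensity_levels=4,
            noise_fraction=0.02,
            seed=int(rng.integers(0, 2**31)),
        )
    )

    fixtures["ct_like"] = generate_phantom(
        PhantomSpec(
            shape=(64, 64, 24),
            blank_slices_head=2,
            blank_slices_tail=2,
            semi_axes=(24.0, 26.0, 9.0),
            intensity_levels=6,
            noise_fraction=0.01,
            seed=int(rng.integers(0, 2**31)),
        )
    )

    interior = np.zeros((32, 32, 12), dtype=np.uint8)
    interior[8:20, 10:24, 2:5] = 120
    interior[12:18, 12:20, 7:10] = 90  # slices 5-6 stay blank inside the range
    fixtures["interior_blank"] = interior

    periodic = np.zeros((48, 48, 16), dtype=np.uint8)
    tile = np.array([[10, 40], [40, 10]], dtype=np.uint8)
    periodic[8:40, 8:40, 3:13] = np.tile(tile, (16, 16))[:32, :32, None]
    fixtures["periodic"] = periodic

    fixtures["uniform_random"] = rng.integers(
        0, 256, size=(32, 32, 16), dtype=np.uint8
    )

    return fixtures
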