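"""Codec comparison harness.

Runs every (volume × codec × VOI-arm) combination, verifies each round
trip bit-exactly before reporting it, and collects one row of metrics per
run.  Wall-clock encode/decode times are reported for orientation only —
they are hardware-dependent and never asserted on.
"""

from __future__ import annotations

import csv
import logging
import time
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

from .metrics import MetricsReport, SSIMParams, evaluate
from .pipeline import CodecConfig, compress, decompress
from .volume_io import Codec

__all__ = ["BenchmarkRow", "run_benchmark", "write_csv", "CSV_COLUMNS"]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "image", "codec", "voi", "cr", "bpv", "mse", "psnr", "ssim",
    "n1", "n2", "voxels", "encode_s", "decode_s",
]


@dataclass(frozen=True)
class BenchmarkRow:
    """One (image, codec, VOI-arm) result; lossless-verified before emission."""

    image: str
    codec: Codec
    use_voi: bool
    report: MetricsReport
    encode_s: float
    decode_s: float

    def as_record(self) -> dict:
        r = self.report
        return {
            "image": self.image,
            "codec": self.codec.value,
            "voi": int(self.use_voi),
            "cr": float(r.cr),
            "bpv": float(r.bpv),
            "mse": r.mse,
            "psnr": r.psnr,
            "ssim": r.ssim,
            "n1": r.n1,
            "n2": r.n2,
            "voxels": r.voxels,
            "encode_s": self.encode_s,
            "decode_s": self.decode_s,
        }


def run_benchmark(
    volumes: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]],
    codecs: Iterable[Codec] = tuple(Codec),
    voi_arms: Iterable[bool] = (True, False),
    ssim_params: SSIMParams | None = None,
) -> list[BenchmarkRow]:
    """Compress/decompress every combination and collect verified metrics.

    Raises ``RuntimeError`` if any round trip is not bit-exact (cannot
    happen with correct codecs; the check is the harness's safety net).
    """
    items = volumes.items() if isinstance(volumes, Mapping) else volumes
    rows: list[BenchmarkRow] = []
    for name, volume in items:
        for codec in codecs:
            for use_voi in voi_arms:
                config = CodecConfig(codec=codec, use_voi=use_voi)
                t0 = time.perf_counter()
                container = compress(volume, config)
                t1 = time.perf_counter()
                restored = decompress(container)
                t2 = time.perf_counter()
                if not np.array_equal(volume, restored):
                    raise RuntimeError(
                        f"non-lossless round trip: {name} / {codec.value} "
                        f"(voi={use_voi})"
                    )
                report = evaluate(
                    volume, restored, container.serialized_size(), ssim_params
                )
                logger.debug(
                    "%s/%s voi=%d: voi_voxels=%d symbols=%d payload_bits=%d",
                    name, codec.value, use_voi,
                    int(np.prod(container.voi.box_shape)),
                    container.symbol_count, container.payload.length,
                )
                row = BenchmarkRow(name, codec, use_voi, report, t1 - t0, t2 - t1)
                logger.info(
                    "%s %s voi=%d: CR=%.3f BPV=%.3f",
                    name, codec.value, use_voi, float(report.cr), float(report.bpv),
                )
                rows.append(row)
    return rows


def write_csv(rows: Iterable[BenchmarkRow], path) -> None:
    """Write benchmark rows as CSV in the fixed column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row.as_record())
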