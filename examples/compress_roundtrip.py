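"""Compress a synthetic MRI-like phantom and verify the lossless round trip.

Builds a high-background ellipsoid phantom, runs the full VOI + LZW-to-
arithmetic pipeline, decompresses, and checks bit-exactness.  The printed
CR is original bits over container bits (header and model table included);
BPV is container bits per voxel of the original grid.
"""

import numpy as np

from voxcodec import CodecConfig, PhantomSpec, compress, decompress, generate_phantom

volume = generate_phantom(
    PhantomSpec(shape=(64, 64, 24), noise_fraction=0.02, seed=7)
)
container = compress(volume, CodecConfig(use_voi=True))
restored = decompress(container)

n1 = 8 * volume.size
n2 = 8 * container.serialized_size()
print(f"volume shape      : {volume.shape} ({volume.size} voxels)")
print(f"container size    : {container.serialized_size()} bytes")
print(f"compression ratio : {n1 / n2:.2f}")
print(f"bits per voxel    : {n2 / volume.size:.3f}")
print(f"bit-exact         : {np.array_equal(volume, restored)}")
# A CR well above 1 with bit-exact True means the anatomy-free background
# cost nothing and the foreground was coded below 8 bits per voxel.
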