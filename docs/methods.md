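# Methods

## Problem and approach

3D medical volumes (MRI, CT, PET) must often be stored and transmitted
without any loss of intensity information. Such volumes have two strong
structural regularities: the anatomy is surrounded by an exactly-zero
background, and acquisitions begin and end with blank slices. `voxcodec`
exploits both with a two-phase lossless codec:

1. **Selective bounding volume (SBV).** Scan the slice axis for the first
   and last non-blank slice (a blank slice has every voxel exactly 0);
   within that range take each slice's tight 2D bounding box of nonzero
   pixels and aggregate the per-slice boxes into one global axis-aligned
   box — the volume of interest (VOI). Interior all-zero slices between
   the first and last non-blank slice stay inside the VOI: only the slice
   *range* is recorded, never a per-slice mask. The box is tight by
   construction (every face touches a nonzero voxel) and never discards
   an active voxel.
2. **Hybrid L-to-A entropy chain.** The VOI is serialized slice-major
   (slices consecutive, each slice row-major), LZW-coded with a
   256-entry-seeded dictionary capped at 4096 entries, and the resulting
   integer code stream is arithmetic-coded under a static frequency model
   of the codes themselves. Payload, model table, and the six VOI
   coordinates travel in a self-describing container; the decoder inverts
   the chain and fuses the decoded VOI into a zero background of the
   original shape. The round trip is bit-exact.

Four classic coders — Huffman, run-length, LZW with fixed 12-bit code
packing, and plain arithmetic coding — are implemented over the *same*
serialized VOI stream as baselines, and each can also be run on the full
grid (`use_voi=False`), the ablation that isolates what VOI extraction
itself contributes.

## Design choices where the design was open

- **Coordinates** are 0-based inclusive everywhere (container included);
  the procedure's loop semantics are inclusive, and one convention avoids
  off-by-one translation at every layer.
- **Symbols fed to the arithmetic stage are the LZW codes themselves**
  (alphabet = max code + 1), not a byte-split of the codes. Splitting
  each 12-bit code into bytes would destroy the code-frequency skew that
  the arithmetic stage exploits.
- **LZW dictionary-full policy: freeze.** Once 4096 entries exist, no new
  entries are added and the dictionary is never reset. Freezing is
  deterministic and keeps encoder and decoder trivially in lock-step. The
  capacity is configurable (`lzw_capacity`, ≥ 256) and recorded in the
  container.
- **Arithmetic coder:** static-model integer implementation, 32-bit
  interval state by default (configurable in [16, 62]), MSB
  renormalization with E3 underflow counting, two termination bits.
  Floating-point intervals are not an option for a lossless contract.
  Frequencies are counted in one first pass; adaptivity is deliberately
  out of scope. Per-symbol counts stored in the container are halved
  until they fit 16 bits (occurring symbols never drop below 1); both
  sides use the scaled model, so scaling affects only compression
  efficiency, never correctness. Symbols absent from the stream keep
  count 0 — giving them mass would cost real bits on every stream.
- **Huffman determinism:** the code tree is built with a
  (weight, smallest-symbol) heap tie-break, so the decoder rebuilds the
  identical table from the stored counts and no table is serialized. A
  single-symbol alphabet gets a 1-bit code, keeping the stream decodable
  by symbol count. The structure term of SSIM and the Huffman tie-break
  are the two places where an arbitrary-but-fixed convention was required.
- **RLE serialization:** 8-bit value + 16-bit little-endian run length;
  runs over 65535 are split. Bounded fields keep the format trivial.
- **All-zero volumes** are a hard error for the SBV operations (there is
  no VOI to find) but compress to a degenerate header-only container
  (symbol count 0, empty payload) so the pipeline is total over inputs.
- **Container accounting:** the compression-ratio denominator n2 is the
  *whole* container — header, VOI coordinates, model table, payload —
  never the payload alone. Excluding side information would overstate CR.
  The numerator n1 is defined as 8 bits × voxel count, independent of the
  source file format. CR and BPV are returned as exact rationals
  (`fractions.Fraction`), so CR × n2 = n1 and BPV = 8/CR hold literally.
- **8-bit contract:** intensities outside [0, 255] are an error, never
  rescaled or clamped — any silent transformation would violate the
  lossless contract. Natively deeper modalities must be reduced upstream,
  explicitly.

## Metrics

MSE is computed exactly in wide integers; PSNR = 10·log₁₀(255²/MSE) with
+∞ exactly when MSE = 0. SSIM is computed slice-wise in 2D with a uniform
8×8 sliding window and population (ddof = 0) moments, stabilizers
c1 = (0.01·255)², c2 = (0.03·255)², c3 = c2/2, exponents α = β = γ = 1,
averaged over all windows and slices. The structure term is
s = (σxy + c3)/(σx·σy + c3): with c3 = c2/2 the l·c·s product reduces to
the canonical SSIM form and evaluates to exactly 1 on identical inputs
(the one value a lossless codec must reproduce, and which is invariant to
the window and stabilizer choices).

## Synthetic phantoms

The generator emulates precisely the features the codec exploits: an
ellipsoidal foreground with radially quantized tissue-like gray bands,
optional salt noise on a fraction of foreground voxels, an exactly-zero
background, and configurable blank head/tail slices. The default
ellipsoid spans the active slice range so the boundary slices of that
range are non-blank by construction. All randomness flows through
NumPy's PCG64 generator seeded from the spec (default seed 20210507), so
fixtures are byte-identical across platforms.

The fixture suite spans eight regimes: all-zero, single nonzero voxel,
full-grid foreground, MRI-like (≈93% background), CT-like (≈76%
background), interior blank slice, periodic texture, and a
uniform-random incompressible control. Shapes are at most 64×64×32 so
the entire suite round-trips through all ten codec arms in a couple of
seconds; this size is a deliberate working scale for a pure-Python
entropy-coder stack, not a limit of the format (the container's shape
and coordinate fields are 32-bit).

What phantoms do **not** model: anatomical texture, partial-volume
edges, scanner noise floors (which would make the background nonzero and
defeat VOI extraction entirely), anisotropic voxel spacing, and bit
depths above 8. Passing tests therefore demonstrate the codec's
correctness contracts and the *direction* of its comparative behaviour
(VOI helps when background dominates; dictionary+arithmetic coding beats
naive packing on repetitive content), not clinical-scale compression
ratios.

## Known limitations

- On small volumes the hybrid codec's stored frequency table (two bytes
  per LZW code value) can outweigh the payload bits it saves over plain
  12-bit-packed LZW; the overhead is fixed-size per distinct code and
  amortizes away on clinically sized volumes.
- Incompressible content expands (CR < 1): none of the five coders
  escape the counting argument, and the container adds its header. The
  uniform-random control fixture documents this deliberately.
- A volume whose background is *near*-zero but not exactly zero yields a
  full-grid VOI; the codec still works, but the VOI benefit disappears.
  Denoising/thresholding is explicitly out of scope (it would be lossy).
- Wall-clock timings are reported by the benchmark harness for
  orientation only and are never asserted anywhere: they are
  hardware- and implementation-bound, and this implementation optimizes
  for clarity and verifiability, not throughput.
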