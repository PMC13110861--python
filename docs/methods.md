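# Methods

This note records the modeling choices behind `mdcz`: what is predicted and
how, what the parameters mean, what the synthetic data generator does and does
not reproduce, and the numerical conventions that make compression and
decompression bit-exact mirrors of each other. The byte-level layouts live in
[format.md](format.md).

## 1. Quantization

Coordinates are stored in nanometers and quantized by rounding half-to-even
to an integer number of steps; the step is `precision_pm / 1000` nm with
`precision_pm ∈ {1, 3, 10, 30, 100}`. Everything downstream of quantization
is lossless, so the end-to-end reconstruction error is bounded by half a
step (0.0005 nm at the 1 pm default). Quantized values must fit a signed
32-bit integer, which at 1 pm covers ±2.1 mm — far beyond any simulation box.

## 2. Segment-aware prediction

Atoms are predicted differently depending on the kind of molecule they belong
to, because the exploitable structure differs:

* **MOL** (molecules with ≥ 6 atoms, e.g. protein chains): bonded neighbours
  move almost rigidly together. During model building, each atom `i` (local
  index ≥ 3 in its subsegment) is assigned the three previously-coded atoms
  with the smallest mean distance to it over the first `m` frames (candidates
  are drawn from a window of `b` predecessors, widened backwards so at least
  three exist; ties break to the smaller index). The model stores the median
  distance to each reference and whether the atom sits above or below the
  reference plane (majority vote, ties count as above). Medians of
  even-length samples take the lower middle value so they are exactly
  reproducible.

  At compression levels 1–3, anchor-frame atoms copy reference `p` and
  delta-frame atoms translate their previous position by `p`'s movement. At
  levels 4–5, anchor atoms are *trilaterated* from the three reference
  positions and the stored distances — the two mirror-image solutions are
  disambiguated by a coded choice bit (level 4) or the stored plane flag
  (level 5) — and delta atoms are carried through the local orthonormal
  coordinate system spanned by the references at the previous and current
  frame, which makes rigid translations exact and rigid rotations exact up to
  rounding.

* **WAT** (runs of 3-point waters, resnames SOL/WAT/HOH/TIP3/H2O with atoms
  ordered O, H, H): the molecule is treated as a rigid body of known
  dimensions. The model is just the median O–H and H–H distances of the
  subsegment. Oxygen is coded positionally (previous molecule / previous
  frame); hydrogens are reconstructed mostly from geometry: each hydrogen
  coordinate is predicted by intersecting spheres of radius dOH/dHH around
  already-decoded atoms with the lines/planes fixed by the coordinates coded
  earlier in the same molecule, so for a truly rigid water only the choice
  bits and ±1-unit corrections remain.

* **OTH** (ions and other < 6-atom non-water molecules): no usable geometry;
  anchor atoms copy their predecessor and delta atoms copy their own
  previous-frame position. This is deliberately the weakest predictor and
  serves as the control: anything with structure should beat it.

Degenerate geometry (near-colinear references, non-intersecting spheres)
falls back to the copy/movement predictor on both sides of the codec. The
tolerance for "degenerate" is `1e-6` on normalized cross products and
discriminants; it is part of the format.

## 3. Batches, subsegments, and random access

Frames are processed in batches of `batch_size` consecutive frames; the first
frame of each batch (the *anchor*) is coded without temporal context, so a
batch is decodable on its own. Segments are split into subsegments of
`subsegment_size` atoms (water subsegments are rounded down to whole
molecules; `None` disables splitting; minimum size 6). No prediction, model
reference, or entropy-coder state crosses a (batch × subsegment) block
boundary. Frame queries therefore decode only the touched batches, and
per-atom queries decode only the touched subsegments — verified in the test
suite by counting part reads.

Larger batches cost fewer anchors (anchor frames code ~2× worse than delta
frames); larger subsegments give the adaptive models longer runs to learn.
Both trade random-access granularity for size. Presets: `default` (20, 100),
`archive` (100, 1000), `trajectory` (100, 100), `frames` (10, 1000).

Work units are encoded in parallel with a thread pool (the kernels release
the GIL), but archives are written in canonical (batch, segment, subsegment)
order, so the output bytes are independent of `workers`.

## 4. Entropy coding

Residuals are coded with an adaptive binary range coder (12-bit
probabilities, shift-5 adaptation — see format.md section 5.1). The magnitude class
(bit length) of each residual adapts in a context of frame kind × axis ×
previous magnitude on that axis, capturing both the anchor/delta cost
difference and short-range magnitude correlation; mantissa bits below the
implicit leading 1 are nearly uniform and coded as bypass bits. All model
state resets at block boundaries, trading a small adaptation cost per block
for independent decodability.

## 5. Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `level` | 2 | predictor selection, 1 (cheapest) to 5 (most geometric) |
| `batch_size` | 20 | frames per anchor |
| `subsegment_size` | 100 | atoms per coding unit (`None` = whole segment) |
| `model_frames` (`m`) | 100 | initial frames used to fit models (capped at T) |
| `b` | 100 | predecessor window for reference candidates |
| `precision_pm` | 1 | quantization step |
| `workers` | 1 | encoder threads (no effect on output bytes) |

## 6. Synthetic data generator

The generator produces systems with exactly the statistical structure each
predictor targets, deterministically from `(spec, seed)`:

* **Chain**: a freely rotating chain (0.15 nm bonds, fixed 109.47° bond
  angle, random dihedrals) — every consecutive atom triple is well bent, as
  in any real bonded backbone, which keeps the local coordinate systems used
  by the MOL predictors well-conditioned. Per-frame motion is a rigid-body
  drift + rotation about the centre of mass, torsion-like rotations of the
  head or tail about fixed interior hinge atoms (every 50 atoms), and a small
  mean-reverting per-atom vibration correlated along the chain (AR(1),
  ρ = 0.95). Rotation and hinge magnitudes are re-calibrated every frame by
  bisection on the linearized displacement field so the mean per-atom
  displacement norm matches the isotropic-Gaussian value `sqrt(8/π) ·
  step_sigma_nm`; displacement share: 30% drift, 15% vibration scale, the
  rest rotation/hinges (40/60 split).
* **Waters**: rigid 3-point molecules (dOH = 0.09572 nm, H–O–H = 104.52°,
  so dHH ≈ 0.15139 nm) placed on a jittered grid, diffusing (σ per axis =
  `step_sigma_nm`) and tumbling (0.3 rad/frame); optional per-atom jitter
  replaces exact rigidity when `rigid=False`.
* **Ions**: independent Gaussian random walks — maximal positional entropy,
  the control case.

**Realism and limits.** The generator reproduces the *statistics a coordinate
compressor sees* — stable bonded geometry, locally rigid motion, rigid
waters, diffusive ions, and √s growth of inter-frame displacement under
stride-s downsampling — not physics: there is no force field, no excluded
volume, no periodic wrapping, no solvent–solute coupling, and chain torsions
are pinned to fixed hinge atoms rather than distributed over all bonds.
Compression numbers on it are internally consistent benchmarks, not
predictions for any particular real system.

## 7. Numerical conventions

* All geometry runs in IEEE double precision on exact integer inputs, with
  exactly one final round-half-to-even (`numpy.rint`) per coordinate. Since
  encoder and decoder perform the identical operation sequence on identical
  integers, predictions match bit-for-bit; correctness does not depend on
  floating-point tolerances, only determinism does.
* Medians use the lower middle value for even-length samples (no averaging),
  so model fitting is exactly reproducible and serializable as integers.
* The uncompressed reference is TRR's coordinate payload: 3 × 32-bit floats
  = 96 bits per atom per frame, reported by `info()` alongside the archive's
  measured bits/atom.
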