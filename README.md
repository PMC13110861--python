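# mdcz

Predictive compression of molecular dynamics (MD) trajectories with random
access to frame subsets and to individual atom trajectories.

## The problem

An MD trajectory stores the 3D coordinates of every atom at every saved time
step. Raw formats such as GROMACS TRR spend 96 bits per atom per frame (three
32-bit floats) regardless of how predictable the motion is — yet MD coordinates
are extremely predictable: bonded atoms move almost rigidly together, water
molecules are rigid bodies, and every atom is close to where it was one frame
ago. General-purpose compressors can't exploit this structure, and the formats
that do (e.g. XTC) give up either precision control or random access.

`mdcz` compresses trajectories by *predicting* each quantized coordinate from
information a decoder already has, and entropy-coding only the small residual.
Compression is lossless with respect to the quantized coordinates (default
precision: 1 pm = 0.001 nm), and the archive layout keeps both random-access
axes: extract any subset of frames, or the full time series of any subset of
atoms, without decompressing the rest.

## The algorithm

1. **Quantization.** Coordinates (nm) are rounded half-to-even to integer
   multiples of the chosen precision (1, 3, 10, 30, or 100 pm).
2. **Segmentation.** The atom list is tiled into segments by molecule type:
   `MOL` (molecules with ≥ 6 atoms), `WAT` (runs of rigid 3-point waters),
   `OTH` (ions and other small molecules). Segments are split into fixed-size
   *subsegments* — independent coding units that never reference each other,
   which is what makes per-atom random access possible.
3. **Model building.** For each `MOL` subsegment, the first `m` frames select
   three *reference atoms* per atom (the nearest predecessors on average) and
   record median distances to them plus a plane-side flag. `WAT` subsegments
   store only median O–H and H–H distances.
4. **Prediction.** Frames are grouped into batches (one *anchor* frame plus
   *delta* frames). Depending on the compression level (1–5), atoms are
   predicted by copying a reference atom, by translating with a reference
   atom's movement, by carrying the previous position through a local
   coordinate system defined by the three references (levels 4–5), or — for
   water hydrogens — by intersecting spheres of known bond radii. Where
   geometry yields two candidates, a single *choice bit* selects one.
5. **Residual coding.** Residuals are zigzag-mapped and coded with an adaptive
   binary range coder: the bit length of each residual is coded in a context
   (frame kind × axis × previous magnitude), followed by raw mantissa bits;
   choice bits are interleaved under their own adaptive models.
6. **Container.** Every (batch × subsegment) block is one CRC-protected part
   in a flat archive with a directory, so any block is one seek + one read
   away. The byte layout is documented exactly in [docs/format.md](docs/format.md).

Model and numerical details, parameter defaults, and the synthetic test-data
generator are described in [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic system (600-atom chain, 120 waters, 8 ions, 100 frames),
compress it at level 4, and read it back:

```python
import numpy as np
from mdcz import (GenSpec, gen_system, compress_frames, decompress_all,
                  query_atoms, CompressionParams)

topo, frames = gen_system(GenSpec(n_chain_atoms=600, n_waters=120, n_ions=8,
                                  n_frames=100, seed=42))
summary = compress_frames(topo, frames, "demo.mdcz",
                          CompressionParams(level=4, batch_size=100))
print("bits/atom:", {k: round(v, 2) for k, v in summary["bits_per_atom"].items()})
back = decompress_all("demo.mdcz")
err = max(np.abs(f.coords - g.coords).max() for f, g in zip(frames, back))
print(f"max error: {err:.6f} nm")
series, times = query_atoms("demo.mdcz", [0])
print("atom 0, frame 0:", np.round(series[0, 0], 3), "nm at t =", times[0], "ps")
```

Output:

```
bits/atom: {'MOL': 7.83, 'WAT': 19.03, 'OTH': 18.51}
max error: 0.000500 nm
atom 0, frame 0: [1.016 2.895 4.029] nm at t = 0.0 ps
```

The chain codes at 7.83 bits/atom/frame against the 96-bit TRR baseline
(12.08 bits/atom overall, a 7.9× coordinate-payload reduction), and the
reconstruction error is bounded by half the 1 pm quantization step.

The same works from the command line on a (structure, trajectory) file pair:

```sh
$ mdcz compress -s example.gro -f example.trr -o example.mdcz \
      --level 4 --preset trajectory
$ mdcz info -i example.mdcz | head -12
{
  "baseline_trr_bits_per_atom": 96,
  "batch_size": 100,
  "bits_per_atom": {
    "MOL": 7.830133333333333,
    "OTH": 18.51,
    "WAT": 19.02777777777778
  },
  "bits_per_atom_overall": 12.082809917355371,
  "coords_payload_bytes": 146202,
  "level": 4,
  "n_atoms": 968,
$ mdcz frames -i example.mdcz --idx 0,50,99 -o sub.trr     # 3 frames
$ mdcz atoms  -i example.mdcz --idx 0,600   -o atoms.tsv   # 2 atom series
```

## Reproduction

The headline quantities are computed on a standard mixed fixture (3000 chain
atoms, 600 waters, 20 ions, 200 frames) by:

```sh
python scripts/acceptance.py --seed 7 --out results/acceptance.json
```

The script generates the fixture deterministically from `--seed`, compresses
it at levels 1, 2, and 4 and at batch sizes 5 and 100, and reports bits/atom
by segment kind, payload sizes and ratios, the maximum round-trip error, and
the TRR baseline. The system-level test suite (`tests/test_acceptance.py`)
checks the same pipeline properties — round-trip fidelity, byte-determinism
across worker counts, query/full-decompression equivalence, geometric-oracle
recovery, codec exactness, and payload-size orderings — on the same fixture.
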