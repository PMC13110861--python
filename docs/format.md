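# Archive and stream formats

This document pins every byte of the `mdcz` on-disk format: the container, the
serialized metadata streams, and the entropy-coded coordinate blocks. All
multi-byte integers are little-endian unless stated otherwise. Python
`struct` notation is used for fixed layouts.

## 1. Container

An archive is a flat file of *parts* (opaque byte strings) grouped into named
*streams*, with a directory at the end:

```
offset 0            header
offset 8            part payloads, back to back, in append order
dir_offset          directory
EOF - 16            footer
```

* **Header** (`<4sI`, 8 bytes): magic `b"MDC1"`, format version `1` (u32).
* **Part payloads**: raw bytes, no per-part framing; all framing lives in the
  directory.
* **Directory**: stream count (u32); then per stream, in first-append order:
  * name length (u16), name (UTF-8, that many bytes),
  * part count (u32),
  * per part (`<QQQI`, 28 bytes): absolute file offset (u64), payload length
    (u64), aux value (u64), CRC-32 of the payload (u32, `zlib.crc32`).
* **Footer** (`<QI4s`, 16 bytes): directory offset (u64), format version
  (u32), magic `b"MDC1"`.

The file contains no timestamps or machine identifiers: its bytes are a pure
function of the append sequence, which is what makes archives byte-identical
across runs and worker counts.

## 2. Streams written by the compressor

| stream | parts | aux | payload |
|---|---|---|---|
| `params` | 1 | 0 | JSON object (sorted keys): `level`, `batch_size`, `subsegment_size`, `model_frames`, `precision_pm`, `n_frames`, `n_atoms` |
| `segment_desc` | 1 | 0 | segment description (section 3) |
| `frame_ids` | 1 | 0 | `n_frames` u64: global frame indices (currently `0..T-1`) |
| `anchor_ids` | 1 | 0 | one u64 per batch: index of its anchor frame (`0, B, 2B, …`) |
| `frame_meta` | 1 | 0 | `T` f64 times (ps), then `T` i64 steps, then `T` row-major 3×3 f64 boxes (nm) |
| `topology` | 0–1 | 0 | JSON list of `[element, name, resname, resid, molecule]` per atom |
| `model/<s>/<ss>` | 1 each | 0 | subsegment model (section 4) for segment `s`, subsegment `ss` |
| `coords/<s>/<ss>` | 1 per batch | anchor frame index | coordinate block (section 5) |

`coords/<s>/<ss>` part *k* holds batch *k*; its aux value repeats the batch's
anchor frame index as an integrity cross-check.

## 3. Segment description

```
"<4sI"   magic b"SEGD", segment count
per segment:
  "<BQQI"  kind (0=MOL, 1=WAT, 2=OTH), atom_start (u64),
           atom_count (u64), subsegment count (u32)
  per subsegment: "<QQ"  absolute atom start (u64), atom count (u64)
trailer: "<I"  CRC-32 of everything before it
```

Subsegments tile their segment exactly; WAT subsegment sizes are multiples
of 3 so no water molecule straddles a boundary.

## 4. Subsegment models

One-byte tag, then a tag-specific body:

* `b"O"` (OTH): no body.
* `b"W"` (WAT): `<II` — median dOH and dHH in quantization units.
* `b"M"` (MOL): `<I` entry count, then per modeled atom (local index ≥ 3, in
  order) `<IIIIIIB`: reference indices `p, q, r` (subsegment-local), median
  distances `d_p, d_q, d_r` (quantization units), plane flag (1 = above,
  0 = below).

## 5. Coordinate blocks

One block codes a (batch × subsegment) pair: `T` frames (anchor first) of `n`
atoms, as a single range-coded symbol sequence. Coordinates are signed
integers in quantization units (`precision_pm / 1000` nm per unit); residual
= true − predicted value, where every prediction uses only previously decoded
values of the same block plus the model.

### 5.1 Binary range coder

LZMA-style binary range coder:

* Encoder state: `low` (33-bit with carry), `range` (32-bit, initial
  `0xFFFFFFFF`), byte cache + cache counter. The first emitted byte is always
  `0x00` (the initial cache). After the last symbol the encoder flushes 5
  bytes, so a stream of zero symbols is 5 bytes.
* Decoder: reads 5 bytes into `code` at init (consuming the leading zero),
  then mirrors the encoder. Reads past the end of the payload return zero
  bytes and set an overrun flag, which the caller reports as a format error.
* Adaptive bit with probability state `p` (12-bit, `0 < p < 4096`, initial
  2048 = p(1)·4096): `bound = (range >> 12) * p`; bit 1 takes
  `range = bound`, bit 0 takes `low += bound; range -= bound`. Adaptation:
  after bit 1, `p += (4096 - p) >> 5`; after bit 0, `p -= p >> 5`.
* Bypass (fixed ½) bit: `bound = range >> 1`, no model update.
* Renormalization whenever `range < 2^24`: shift range left 8 bits and move
  the top byte of `low` out through the carry-propagating cache.

### 5.2 Residual symbol

A residual `r` (i64) is zigzag-mapped to `u = (r << 1) ^ (r >> 63)`, and
`k = bit_length(u)` is coded as adaptive unary: `k` one-bits then (if
`k < 36`) a terminating zero-bit, each in model `ctx + j` for position `j`.
Then the mantissa: if `k ≥ 2`, bits `k-2 .. 0` of `u` as bypass bits (the
most significant bit of `u` is implicit). `k` is capped by construction at
36 (residuals of 32-bit coordinates fit).

The unary context base is `ctx = (((fk * 3) + axis) * 8 + prev) * 36` where
`fk` is 0 for the anchor frame and 1 for delta frames, `axis` ∈ {0,1,2}, and
`prev = min(7, k_prev)` is the magnitude class of the previous residual coded
*on the same axis* (initially 0). There are `2 * 3 * 8 * 36 = 1728` unary
models, all initialized to 2048 at the start of every block.

### 5.3 Choice bits

Choice bits are adaptive bits coded in one of 4 dedicated models (also reset
per block): 0 = MOL trilateration side, 1 = WAT H1 z, 2 = WAT H2 y,
3 = WAT H2 z. A choice bit is always emitted immediately *before* the
residual of the coordinate it disambiguates, and `bit = 1` selects the second
candidate (the larger z / y root, or the "below" trilateration point).

### 5.4 Symbol order

All blocks iterate frames outer, atoms inner, axes x, y, z innermost.

**OTH**: prediction is the previous atom of the same frame (origin for the
first atom) in the anchor frame, and the same atom's previous-frame position
in delta frames. No choice bits.

**MOL**: anchor-frame predictions are (0,0,0) for local atom 0, the previous
atom for atoms 1–2, and reference `p`'s position for atoms ≥ 3 — except at
levels 4–5, where trilateration from `(p, q, r)` with the model distances is
attempted: if non-degenerate, level 4 codes one choice bit (model 0) for the
closer candidate before the atom's three residuals, and level 5 picks the
candidate matching the stored plane flag without a bit. Delta-frame
predictions are `prev + (P_t - P_{t-1})` at levels 1–3 and the local-frame
carry (express `prev - P_{t-1}` in the orthonormal frame built from the
references at `t-1`, re-emit in the frame at `t`, round half-to-even) at
levels 4–5, falling back to the movement vector when either frame is
degenerate.

**WAT** (per molecule O, H1, H2): O is predicted from the previous molecule's
O (anchor; (0,0,0) for the first molecule) or its own previous-frame position
(delta). H1: x and y predicted as O's true x, y; z from the sphere
`|H1 - O| = dOH` through H1's true (x, y) — if real, one choice bit
(model 1) then the residual; if degenerate, prediction falls back to `z_O`
with no bit. H2: x is `x_O` (levels 1–4) or the sphere-intersection-circle
center x (level 5, fallback `x_O`); y is `y_O` (levels 1–2) or the two-circle
intersection at H2's true x (levels 3–5; on success one choice bit, model 2);
z from sphere(O, dOH) through H2's true (x, y), with sphere(H1, dHH) as
fallback, coding one choice bit (model 3) on success, else predicted as
`z_O`.

All geometric computation is double precision on integer inputs with one
final round-half-to-even per coordinate (`numpy.rint` semantics); that
rounding, and the degeneracy tolerance of `1e-6` on normalized cross-product
and discriminant tests, are normative — encoder and decoder must match them
bit-for-bit.
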