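# Methods

## Signal model and inversion

The conversion chain treats every pixel's digital number (DN) as a linear
reading of radiance and models the calibrated signal of a source at
absolute temperature `T` and weight `w` as

    S_x = G · w / (R · (e^{B/T} − F)) + O ,

with camera constants `G` (gain), `O` (offset), `B` (exponential constant,
kelvin), `R` (radiance scaling) and `F` (stored generalisation of the
literal 1; almost always exactly 1). The total signal is the three-source
mixture `S = τ·S_obj + τ·S_refl + S_atm`, with weights ε (object
emissivity), `1 − ε` at the apparent reflected temperature, and `1 − τ` at
air temperature. Inversion solves the mixture for `S_obj` and the
calibration model for `T`, using the natural logarithm and the stored `F`
in place of the literal 1 so the pair is algebraically exact for any `F`.

Assumptions worth stating: surfaces are opaque grey bodies (reflectivity
`1 − ε`); the reflected surround is summarised by one apparent reflected
temperature measured off a near-perfect reflector; the atmosphere is
characterised by water content alone (adequate at field distances, not for
long-path or satellite use); and all pixels of a frame share one parameter
set (the per-pixel emissivity in the synthetic generator exists to emulate
scenes, not the inversion).

Offset convention: each of the three component signals carries the `+O`
term and the mixture is inverted exactly as written above, so the
forward/inverse pair is self-consistent by construction. An
`include_offset=False` variant of the component computation is available
for reconciling against third-party formulations that apply the offset
once; the reference-comparison module exists to arbitrate such conventions
against exported data.

## Atmospheric transmissivity

    H = RH · exp(1.5587 + 6.939e−2·t − 2.7816e−4·t² + 6.8455e−7·t³)
    τ = X·e^{−√d(α₁+β₁√H)} + (1−X)·e^{−√d(α₂+β₂√H)}

`t` in °C, `RH` a fraction in [0, 1], `d` in metres. τ is computed once per
frame. Because the stored β coefficients are negative, pathological inputs
(huge `d`·`H`) can push the raw expression outside (0, 1]; τ is clamped to
[1e−6, 1] with a logged warning. At `d = 0` the expression is exactly 1.

Relative humidity is held internally as a fraction; file values above 1 are
interpreted as percent and divided by 100 at ingest (the metadata tag and
parameter-table column are named in percent).

## Parameters and units

| parameter | units | typical default |
|---|---|---|
| emissivity ε | fraction (0, 1] | 0.95 (vegetation) |
| air temperature | °C | 20 |
| relative humidity | fraction | 0.50 |
| apparent reflected temperature | °C | 20 |
| object distance | m | 1 |

All public temperatures are °C; kelvin (offset 273.15) is internal.

## Numerical choices and degenerate inputs

- Pixels whose object signal does not exceed `O` (or whose log argument
  would not exceed 1, reachable only for `F < 1`) are undefined: NaN in
  rasters (count logged, never an exception per pixel), an explicit error
  for scalar calls. Undefined pixels are excluded from statistics, written
  as the token `NaN` in CSVs, and rendered at the palette minimum.
- No lower clamp is applied to temperatures: arbitrarily cold scenes invert
  to their true value (tested at −70 °C, well past the −40 °C display floor
  of common manufacturer software, whose floored pixels the comparison
  module counts separately).
- Temperature CSVs are written with two decimals, comma separator, no
  header; two decimals exceed the radiometric resolution of this camera
  class and make batch outputs byte-reproducible, which the reprocessing
  contract relies on.
- Display-range quantiles are nearest-rank on the sorted defined pixels:
  for tail fraction `f` and `n` pixels, `m = round(f·n)` pixels are
  excluded, `m//2` from the lower tail and the remainder (the odd pixel,
  if any) from the upper; a constant image yields a degenerate range and is
  expanded by ±0.5 °C with a warning.
- Palette index mapping rounds half-up (the exact mid-range temperature
  maps to index 128); out-of-range values clamp to the endpoint colors.
- The inferno LUT is vendored as a frozen 256×3 uint8 table so rendering is
  bit-stable across matplotlib versions; both palettes have strictly
  increasing luma (safe under black-and-white reproduction).

## File handling

Byte order of the embedded raw payload: PNG payloads are little-endian
although PNG itself is big-endian, so decoded samples are byte-swapped;
TIFF payloads decode as written. Camera models that invert this rule are
listed in a user-editable config (`data/byte_order_exceptions.txt`); it
ships with instructions and no entries, because the offending models must
be identified from real files — decoded DN that invert to absurd
temperatures are the symptom.

Real camera JPEGs are read through `exiftool` when present. The synthetic
fixture format stores the identical tag set as JSON plus the chunked raw
payload in JPEG application segments and is parsed natively, keeping the
test suite free of external binaries. Both paths produce the same metadata
structure, and extraction never modifies the input file.

Video export writes uncompressed RGB24 AVI (DIB frames, default 10 fps):
lossless, universally decodable, and free of codec dependencies; frame
payloads are embedded verbatim, at 3·W·H bytes per frame. MP4 is not
produced.

## Synthetic scenes: what they emulate and what they do not

The generator paints rectangles and disks of stated temperature and
emissivity on a uniform background, composes the raw signal with exactly
the mixture above, optionally adds Gaussian DN noise (seeded) and rounds to
unsigned 16 bits, then packages the result either as a radiometric JPEG
fixture or as a sidecar pair (16-bit PNG following the byte-order rule, or
a float TIFF for unquantized DN, plus a one-row parameter CSV).

Default generator conditions: 20 °C background, ε = 0.95, air 20 °C,
RH 50%, reflected 20 °C, distance 1 m — ordinary greenhouse/field imaging
conditions. Default camera constants are representative magnitudes for
consumer long-wave cameras: `G = 21106.77`, `B = 1501 K`, `R = 0.012545`,
`F = 1`, atmosphere `α₁ = 0.006569, α₂ = 0.01262, β₁ = −0.002276,
β₂ = −0.00667, X = 1.9`. The sensor offset default is `O = +7261`: with the
three-component offset composition used here, the offset enters the total
DN three times (weighted `2τ + 1`), and a positive offset of this magnitude
places the DN of scenes from −70 °C to +40 °C in the realistic
8 000–36 000 range of a 16-bit sensor, while a negative offset of the same
magnitude would push every such scene below zero DN. The equations are
unchanged by the sign; only the fixture's storable dynamic range is.

Because the forward model mirrors the inversion term for term, noiseless
unquantized scenes round-trip to machine precision, and 16-bit rounding
bounds the error by the DN resolution (≲ 0.003 °C/DN·0.5 DN near 20 °C at
these constants; the tests assert a conservative 0.05 °C). Passing tests
therefore demonstrate internal consistency, determinism and correct file
plumbing — they do not validate the calibration constants of any physical
camera, sensor non-uniformity, optics (vignetting, focus), dead pixels, or
drift, none of which the generator simulates. Validating against a real
camera is what the reference-comparison (`verify`) module is for.

## Problem sizes

Tests and the acceptance script run on small frames (48×32 to 160×120) and
1000-pixel histogram fixtures; every quantity checked (round-trip error,
tail-exclusion fractions, statistics vs a brute-force scan) is
size-independent, so small frames are the natural choice and the whole
suite completes in seconds.

## Known limitations

- The byte-order exception list is empty until populated from real files.
- Only the radiometric-JPEG single-frame format is handled (no SEQ/CSQ
  sequences, no embedded visible-light photo).
- Reference CSV dialect detection (comma vs semicolon/decimal-comma) is
  heuristic; exotic export formats may need manual conversion.
- Calibration constants are taken from file metadata as ground truth; the
  package does not estimate or refit them.
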