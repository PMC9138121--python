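# irproc

Open, reproducible radiometric processing of thermal camera images.

Consumer thermal cameras (FLIR-style) save radiometric JPEGs: behind the
false-color preview sits the 16-bit raw sensor frame together with the
camera's calibration constants and the user-set acquisition parameters.
Manufacturer software converts those raw digital numbers (DN) to
temperatures with a closed algorithm, which is a problem for research uses —
plant phenotyping from leaf temperature, animal surface temperature, built
environment surveys — where the conversion must be auditable and repeatable.
`irproc` implements the whole chain in the open: raw extraction,
signal-to-temperature physics, batch processing with a saved parameter trail,
mask-based object measurement, quantitatively decodable false-color
rendering, and pixelwise comparison against reference exports.

## The model

Each pixel's signal is linear in radiance, and for one camera the
signal-to-temperature relation is calibrated as

```
S = G · ε / (R · (e^{B/T} − F)) + O
```

with per-camera constants `G, O, B, R, F` (stored in the image metadata) and
surface emissivity ε. The sensor sees three sources mixed by the atmospheric
transmissivity τ over the object distance:

```
S = τ·S_obj + τ·S_refl + S_atm
```

where `S_refl` is radiation from the surroundings reflected off the object
(weight `1 − ε`, at the apparent reflected temperature) and `S_atm` is
emission of the air column (weight `1 − τ`, at air temperature).
τ follows a two-term exponential attenuation model driven by the air water
content `H(t, RH)` and √distance. Solving the mixture for `S_obj` and
inverting the calibration model gives the object temperature:

```
S_obj = S/τ − S_refl − S_atm/τ
T_obj = B / ln( G·ε / (R·(S_obj − O)) + F )
```

No floor or clamp is applied: scenes far below the −40 °C display floor of
typical manufacturer tools invert to their true temperature.

## Worked example

```
$ irproc simulate --out demo --kind jpeg --name leaves
$ irproc process demo
processed 1/1 image(s); parameters: demo/parameters.csv
```

`process` writes four outputs per image (`raw/leaves.png` 16-bit DN,
`temp/leaves.tif` 32-bit float °C, `color/leaves.png`, `text/leaves.csv`)
plus one `parameters.csv` recording every constant and parameter used —
rerunning with `--mode file --params-file demo/parameters.csv` reproduces
the temperature CSVs byte for byte.

Measuring the two simulated leaf disks (18.5 °C and 21.0 °C true surface
temperature, 22 °C background) through a thresholded label mask:

```python
from irproc import flir_io, measure
t = flir_io.read_temperature_csv("demo/text/leaves.csv")
mask = measure.label_binary(t.temp_C < 21.8)
for r in measure.measure_objects([("leaves", t)], mask):
    print(f"leaf {r.label}: mean={r.mean:.2f} min={r.min:.2f} "
          f"max={r.max:.2f} sd={r.sd:.3f} n={r.pixel_count}")
```

prints

```
leaf 1: mean=18.50 min=18.50 max=18.50 sd=0.000 n=1961
leaf 2: mean=21.00 min=21.00 max=21.00 sd=0.000 n=1961
```

i.e. both leaves are recovered at their true temperatures to the 0.01 °C
print precision, through the full JPEG → raw DN → temperature chain
(16-bit quantization keeps the worst-case error below 0.05 °C at these
constants). A leaf-to-air ΔT of −3.5 °C vs −1.0 °C like this one is the kind
of transpirational-cooling contrast the tool is meant to resolve.

False-color output is quantitative: the display range maps linearly onto a
256-entry perceptually uniform palette (inferno, or greyscale), so any
rendered pixel decodes back to a temperature within one bin width.
`irproc color demo --scope global --scale-bar small --video` re-renders a
set on a common scale and writes an uncompressed AVI sequence.

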