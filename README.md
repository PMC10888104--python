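# bruise-evolve

Quantifying how bruise damage spreads through apple flesh over time, from
trypan-blue-stained tissue-section micrograph series.

## The problem

When an apple is bruised, a banded fracture region of concentrated dead
cells — the *cell death zone* — forms at a fixed depth beneath the skin.
Over the following hours, damaged tissue spreads from that zone along the
depth axis, asymmetrically: faster toward the core than toward the
pericarp. Micrograph time series of stained sections (an injury series
T₁…T₃₀ paired with a cutting-control series C₁…C₃₀, imaged every 6 min for
180 min) make this evolution measurable — but only after separating the
injury signal from two nuisance signals: a diffuse dead-cell speckle that
accumulates as the excised tissue senesces, and cutting-induced dead-cell
bands along the sides and bottom of the section.

This package implements that measurement chain for researchers working on
post-harvest fruit damage and early bruise detection:

1. **Phantom generation** (`bruise_evolve.phantom`) — synthetic T/C series
   with exact ground truth, emulating the imaging conditions (three-level
   saturation structure, senescence speckle shared between T and C,
   static edge bands, Gaussian noise, between-specimen variability).
2. **Zone extraction** (`bruise_evolve.extraction`) — HSV saturation
   channel → control-series baseline correction (offsets d₂…d₃₀) →
   tri-level Otsu thresholding into damage and zone masks → morphological
   opening/closing → largest connected component → hole filling →
   middle-third rectangle rule (removes the bottom cutting band) →
   width-based endpoint correction (fixes the lateral cutting bands).
3. **Measurement** (`bruise_evolve.metrics`) — per-column depth and width
   with the discontinuity rule (centre = midpoint of the two furthest
   segment boundaries Y₁, Y₄; width = Σ(Y₂ᵢ−Y₂ᵢ₋₁)), plus damage extents
   toward core (D_c) and pericarp (D_p) from the frame-1 zone centre.
4. **Analysis** (`bruise_evolve.analysis`) — growth-law fits, analytic
   damage-rate curves, stabilization times, cross-scenario Pearson
   comparisons and the core-share band.

## The growth model

The total damage extent follows a rescaled logistic

```
D(t) = D∞ · (σ(k(t−t₀)) − σ(−k t₀)) / (1 − σ(−k t₀)),     σ(x) = 1/(1+e⁻ˣ)
```

which is 0 at t = 0, has its maximum rate at the inflection t₀ and levels
off at D∞. With the calibrated defaults (t₀ = 30 min, k = 0.11 min⁻¹,
D∞ = 7 mm for an upper-site impact from 125 mm) the curve reaches 99% of
its plateau at 72.1 min. The core share p(t) = 0.60 + 0.03·sin(2πt/90)
splits D(t) into D_c = p·D and D_p = (1−p)·D, keeping the core fraction
inside the observed 55–64% band.

## Worked example

```
$ bruise-evolve generate --scenario upper --seed 1 --out frames
wrote 30 T+C frames and ground truth to frames
$ bruise-evolve extract --frames frames --out masks --mode control
extracted 30 frames to masks
$ bruise-evolve measure --masks masks --mm-per-px 0.02 --out trace.csv
wrote trace of 30 frames to trace.csv
$ bruise-evolve analyze --trace trace.csv --out results.json
plateau=7.08 mm  t0=29.6 min  k=0.113 /min  R2=0.999
max rate at 29.6 min, stabilization at 70.6 min
```

The fitted plateau (7.08 mm) matches this specimen's realized total damage
extent; the inflection near 30 min is the time of maximum damage rate, and
the 99%-of-plateau crossing near 71 min is when the damage depth
stabilizes. The trace CSV holds the per-frame measurements; its last frame
reads `total_mm = 7.12`, `core_share = 0.60` — about 60% of the damage lies
on the core side of the zone:

```
time_min,zone_depth_mm,zone_width_mm,core_extent_mm,pericarp_extent_mm,total_mm,core_share,excluded
180.0,2.9987,1.1804,4.2746,2.8436,7.1182,0.6005,False
```

`bruise-evolve run --scenario upper --scenario waist --scenario lower
--seed 1 --out sites/` executes the whole pipeline per scenario and
reports the pairwise Pearson correlations of the progression curves.

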