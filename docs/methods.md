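# Methods

## The measurement problem

A bruised apple develops a banded fracture region of concentrated dead
cells (the cell death zone) at a fixed depth below the skin; damaged
tissue then spreads from that zone along the depth axis. In stained
sections, three populations of dead cells are visible: the injury signal
(zone plus expanding damage halo), a diffuse senescence speckle that
accumulates over the observation window, and static cutting bands along
the section's sides and bottom. The pipeline isolates the injury signal,
measures it per frame, and characterizes its kinetics.

All geometry is 0-based with half-open row intervals; row index increases
with depth, so the core direction is positive. Lengths are mm (converted
with the known pixel scale — no attempt is made to infer scale from image
content), times are minutes, intensities are 8-bit saturation levels.

## Growth law

Total damage extent follows a rescaled logistic
`D(t) = D∞ (σ(k(t−t₀)) − σ(−kt₀)) / (1 − σ(−kt₀))`. This is the minimal
sigmoid consistent with the two timing landmarks the kinetics must show:
maximum rate at the inflection t₀ = 30 min, and levelling-off near 72 min
— with k = 0.11 min⁻¹ the 99%-of-plateau crossing sits at 72.1 min
(closed form: `t = t₀ + logit(0.99 + 0.01·σ(−kt₀))/k`). The rescaling
forces D(0) = 0 exactly, since no damage extent exists at the moment of
impact. The fitted form is pluggable in `analysis.fit_logistic`; rates are
always the analytic derivative of the fitted curve, never finite
differences of noisy measurements, and the stabilization criterion is the
99%-of-plateau crossing (a free choice; the fraction is a parameter).

The core/pericarp split is a prescribed oscillating share
`p(t) = 0.60 + 0.03 sin(2πt/90 min)` rather than two independent growth
laws: it guarantees the 55–64% band with margin and makes the asymmetry a
single interpretable parameter pair. D_c = p·D and D_p = (1−p)·D sum to D
exactly by construction.

## What the phantom emulates — and what it does not

`phantom.render_series` draws, per frame: a zone band centred at
`zone_depth` whose width grows 0.3 → 1.2 mm under the same logistic
timing (the core side receives the share p(t) of each increment, so the
zone centre drifts slightly coreward); a damage halo spanning
[centre − D_p(t), centre + D_c(t)]; speckle blobs whose count grows
linearly in time, with the *same realized field* in T and C frames so the
control correction is exact in expectation; static cutting bands; and
additive Gaussian noise in the saturation plane (sd 6 gray levels),
clipped and requantized. Frames are rendered at the blue primary hue so
the class saturation levels (background 40 / halo 120 / zone 180) survive
the 8-bit RGB round trip exactly; the slide above the skin shares the
background saturation but is brighter in the value channel, which is how
the surface detector finds the skin line.

Two modelling choices deserve emphasis:

- **The pericarp limit.** Damage cannot spread past the skin. With the
  default geometry (zone 3.0 mm deep, plateau 7 mm, share minimum 0.57)
  the parametric pericarp extent brushes 3.01 mm at share-minimum frames,
  so the halo is clipped at the surface. Ground-truth traces are derived
  from the drawn masks (not the parametric curves), so D_c + D_p = D stays
  exact and a perfect extractor reproduces the truth bit for bit.
- **Irregular cutting bands.** The left side band runs the full tissue
  height and joins the bottom band; the right one stops partway down.
  Real cutting damage is irregular, and this matters structurally:
  perfectly closed bands would enclose the section interior and turn hole
  filling into a flood fill of the whole mask interior — a configuration
  that does not occur in real material.

Between-specimen biological variability is drawn once per seed: zone
depth jitter (sd 0.15 mm) and multiplicative plateau jitter (sd 3% on the
damage plateau and the zone-width plateau). Replicated impact experiments
on real fruit scatter in exactly these parameters, and the pooled
depth-vs-time regression is only as weak as observed if between-specimen
depth scatter dominates the small coreward drift. One integer seed drives
all randomness through spawned substreams (specimen, speckle, per-frame
noise), so renders are bit-reproducible.

The phantom does *not* emulate: tilted or rough skin surfaces (flat skin
line; the surface detector handles tilt, tested on synthetic profiles),
stitching seams or illumination gradients (the only drift is the global
speckle trend the correction removes), lateral spread of the bruise
(bands span the full section width), or any contact-mechanics of the
impact. Passing tests therefore demonstrate that the *measurement chain*
is correct under the assumed image structure, not that real sections meet
those assumptions.

## Extraction chain

Per series: saturation channel → baseline correction → tri-level
thresholding → per-mask cleanup. Details and the open decisions:

- **Baseline correction.** Offsets d_i are the mean gray differences of a
  reference region between frame i and frame 1, computed on the control
  series (mode `control`, the default) or on the injury series itself
  (mode `self`, in which case the region is checked against a rough
  final-frame damage estimate and overlap raises a warning or, in strict
  mode, an error). Offsets are real-valued and subtracted before
  requantization; clipping, not wrap-around.
- **Thresholding.** One three-class Otsu (exhaustive, exact search over
  all integer threshold pairs; ties toward the smallest pair) yields both
  masks in a single pass: damage = above the lower threshold, zone =
  above the upper, so zone ⊆ damage by construction. By default the
  threshold pair is computed on the final corrected frame and applied to
  the whole series: the final frame carries all three classes in quantity
  while early frames are nearly two-class, where a per-frame tri-level
  split is unstable (a per-frame policy is available).
- **Cleanup.** Opening then closing with a disc of radius 2 px (the
  composite is idempotent; radius configurable), optional small-object
  removal, largest 8-connected component (ties toward the earliest pixel
  in raster order), hole filling, the middle-third rectangle rule, and
  endpoint correction. The middle-third rule reads the two widest
  components inside the middle third of the columns as the band of
  interest and the bottom cutting band, and erases everything below the
  line midway between their enclosing rectangles; candidates must span at
  least half the middle-third columns, so a stray blob can never be
  mistaken for the bottom band. Endpoint correction clamps columns wider
  than twice the interior mean width (interior = columns within twice the
  median width) to a run of the mean width centred on the column's span
  midpoint.

## Measurement

Per column, the zone centre is the midpoint of the two furthest segment
boundaries and the width is the summed segment length — the rule that
handles discontinuous zones — and the depth is centre minus the skin
surface row. The damage extents D_c/D_p are measured from the *frame-1*
zone centre, not the per-frame centre, because the zone centre drifts
coreward as the band grows asymmetrically. Frame scalars are column means
(robust to single-column outliers; maxima would key on noise). Frames
whose total extent falls below a 1 mm measurability floor are flagged and
excluded from proportion statistics, where a 1-pixel error on a
sub-millimetre extent would dominate the share.

## Numerical choices

- Logistic fits: `scipy.optimize.curve_fit`, initialized from the data
  (plateau = max, t₀ = first half-max crossing, k = 0.1 min⁻¹), bounded
  positive; R² = 1 − SSR/SST; significance by the regression F-test.
  Constant series yield a flagged degenerate result rather than an error.
- Stabilization times are solved in closed form from the fitted
  parameters and reported to 0.1 min.
- Pearson comparisons inner-join traces on their time grids and require
  at least 3 shared frames; zero-variance curves produce NaN with a
  warning rather than failing the whole comparison.
- Scenario families: site plateaus 7.0/7.6/6.4 mm (waist > upper >
  lower); drop heights scale the plateau as √(h/125 mm) — monotone in
  height, anchored at the reference condition; the exponent is a free
  choice. Tall-plateau scenarios grow the image height automatically so
  the plateau halo keeps clear of the bottom cutting band, and the
  renderer validates the realized (jittered) geometry, raising a
  configuration error on overflow.

## Problem sizes

The replicated studies use 10 default-condition specimens for landmark
recovery and 5 specimens per scenario for the 3-site and 7-height
families — enough replicates that seed-averaged curves are smooth while a
full reproduction run stays in the minutes range on one CPU. Unit tests
exercise a geometrically identical phantom at 240×300 px / 0.04 mm px⁻¹;
invariants whose bounds scale with pixel area (speckle drift per pixel,
boundary-pixel share of the Jaccard index) are asserted at the full
600×500 px / 0.02 mm px⁻¹ geometry.

## Known limitations

- The extractor's endpoint clamp centres repaired columns on their
  corrupted span midpoint, which can misplace the band in the few columns
  occupied by side cutting bands; with default geometry this biases
  column-mean extents by well under one pixel but explains why noisy-run
  Jaccard indices sit near 0.93 rather than 1.0.
- The fitted model matches the generating law, so fit quality on phantoms
  is an upper bound for real data; the model is pluggable precisely so a
  different growth law can be swapped in.
- Proportion statistics near the measurability floor remain noisier than
  at plateau; the floor trades early-time coverage for share stability.
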