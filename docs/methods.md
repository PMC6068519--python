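# Methods

This note documents the models, parameter choices and numerical conventions
behind `greenview`, and what the synthetic-data validation does and does not
establish about real street-view corpora.

## Vegetation segmentation in HSI space

Pictures are converted with the Gonzalez–Woods HSI transform: intensity is
the channel mean, saturation is `1 − 3·min(R,G,B)/(R+G+B)`, and hue is the
arccos form measured in degrees on [0, 360). Achromatic pixels (R = G = B)
have undefined hue, stored as NaN, and can never be classified as vegetation.
A pixel is vegetation iff `hue_lo < H < hue_hi` — strict inequalities, with
defaults 75° and 170°. This band brackets green (120°) asymmetrically,
reaching toward cyan more than toward yellow, which is the behaviour of real
foliage hues under varied illumination. A `min_saturation` gate (default 0,
i.e. off) is exposed because hue is numerically unstable for near-gray
pixels; it is not part of the default rule.

The hue scale and formula variant are conventions of this package: printed
threshold pairs only make sense on a 0–360 degree scale where green is 120°,
and the Gonzalez–Woods definition is the common textbook variant. The inverse
transform (`hsi_to_rgb`, sector form) exists for synthesis and testing;
round-trip error is at most one 8-bit count per channel for saturated pixels.

`calibrate_hue_thresholds` re-derives the band by exhaustive grid search
(default 5° step) over all `(lo, hi)` pairs inside a 60–180° window,
maximizing the squared Pearson correlation between segmentation fractions
and reference fractions; ties prefer the widest band, because any band whose
extension adds no pixels is observationally equivalent and the widest one is
the most robust to unseen hues. Strict-inequality counting is done exactly
via sorted per-picture hue arrays, not by histogram binning. Degenerate
inputs — fewer than 3 pairs, zero-variance references, no pixels inside the
window — raise instead of returning an arbitrary band.

## Green View Index

All GVI variants are pooled pixel ratios: green pixels over total pixels
across a site's picture set. Values are stored as fractions in [0, 1];
percentage formatting is presentation only. For equal-resolution pictures
the pooled ratio equals the arithmetic mean of per-picture fractions, and for
mixed resolutions the pixel-weighted mean — both are consequences, not
implementation choices. With one pitch row and zero heading offset the
general m×n formula reduces bit-for-bit to the horizontal formula, and the
code paths are shared so the identity is structural.

Configuration geometry: GVI4 = 4 headings at 90°, GVI6 = 6 at 60° (the
reference configuration), GVI8 = 8 at 45°, GVI18 = 6 headings × pitches
(+30°, 0°, −30°), with (+20°, 0°, −20°) selectable for imagery services whose
pitch range stops at −20°. Heading 0° is north and headings increase
clockwise; any consistent convention gives identical pooled ratios.

### Panorama stitching

The cylindrical stitcher maps output columns to azimuth at the pictures'
native angular resolution (width/fov columns per degree). Each picture spans
`fov` degrees centred on its heading; where coverage overlaps
(`fov > 360/m`) the contributing pictures' columns are averaged, and at
`fov = 360/m` the panorama degenerates to exact concatenation, making
PGVI = GVI6 an exact identity there. Picture field of view is a parameter
(default 90°) because camera geometry varies between providers; overlap, and
hence the PGVI-vs-GVI6 discrepancy, only exists when fov exceeds 360/m.
`fov < 360/m` leaves angular gaps and is rejected. Nearest-column sampling
(no interpolation) keeps the degenerate case bit-exact; this is a simplified
projective model, not a feature-registration stitcher, and reproduces the
qualitative overlap effect rather than any specific software's output.

Configuration comparison reports, per pair against the GVI6 reference:
mean difference, RMSE, and the counts of sites with difference strictly
above and strictly below zero (exact ties count in neither).

## Road-network simplification and sampling

The simplification chain is rasterize → close → thin → trace:

- **Rasterize**: polylines are burnt into a boolean grid (Bresenham segments)
  at `cell_size` = 20 m by default, with a margin so morphology never touches
  the border. Coordinates must be in a projected metric CRS; inputs whose
  bounds fit inside ±180°/±90° are rejected as likely geographic rather than
  silently mis-scaled.
- **Close**: morphological closing with a disk of `fill_radius` cells
  (default 1) fills gaps at crossings and merges carriageways within about
  2 cells of each other. The original gap-filling heuristics of desktop GIS
  raster tools are not reproducible from their documentation; closing is the
  standard morphological equivalent.
- **Thin**: Zhang–Suen thinning, followed by a simple-point pruning pass that
  removes the 2×2 blocks Zhang–Suen can leave at X-crossings. A cell is
  removed only if its punctured 8-neighbourhood stays one connected
  component, so connectivity is preserved by construction.
- **Trace**: the skeleton is an 8-connected graph with redundant diagonal
  links (diagonal steps bridged by an occupied orthogonal cell) dropped;
  polylines are maximal paths between junction/endpoint cells (degree ≠ 2),
  plus isolated cycles. Junctions split polylines per skeleton block — a
  named road crossing k streets becomes k+1 segments, matching how
  street-level aggregates are mapped. Each traced polyline inherits
  attributes from all source roads within 2 cells: width as their mean (a
  merged dual carriageway of 8 m and 12 m lanes gets 10 m), type as the mode.

Sampling places sites at chainages 0, 100 m, 200 m, … along each simplified
road, including the start endpoint and the last full multiple of the
interval; a trailing remainder produces no extra site, so a road of length L
carries ⌊L/100⌋ + 1 sites. Site-to-picture matching takes the nearest
picture location within 50 m, inclusive at the boundary; unmatched is a
recorded value, not an error.

Street-level GVI is the unweighted mean of member-site values. Natural-breaks
classing is exact Fisher–Jenks dynamic programming (O(k·n²)), minimizing
within-class sum of squared deviations; the five classes are labelled
very_low … very_high in ascending order. Fewer distinct values than classes
is an error rather than a degenerate classing.

## Spatial statistics

Global Moran's I uses binary distance-band weights, row-standardized by
default, self excluded, E[I] = −1/(n−1). Significance is by conditional
permutation (default 999), with the pseudo p-value `(extreme + 1)/(perms + 1)`
counted one-sided on the side of the observed statistic, and a z-score
against the permutation moments. Getis-Ord Gi\* uses the starred,
self-inclusive variant in its global-moments z-score form, so site scores are
directly comparable to normal quantiles; two variance conventions circulate
between GIS packages, and the global-moments form implemented here is pinned
by an independent scalar oracle in the tests. Hot/cold categories use the
two-tailed thresholds 1.96 / 2.576 / 3.291 (0.05 / 0.01 / 0.001 levels),
inclusive at the boundary. When the value spread is at machine-noise level
Gi\* returns all-zero scores rather than amplifying rounding noise; exactly
constant input is an error for both statistics.

The distance threshold is data-dependent (a published 563 m band applies to
one particular corpus); when omitted, the pipeline uses the maximum
nearest-neighbour distance — the smallest band that leaves no island.

## Synthetic data: what it does and does not show

Scenes are flat-colour geometric compositions, not photorealistic renders:
pixel bands for sky (hue 220°), built surfaces (30°), achromatic pavement,
and vegetation (hues drawn in 90–150°) are disjoint from each other and from
the segmentation band, so the labelled vegetation fraction — exact to half a
pixel by integer rounding — is recovered perfectly by construction.
Distractors deliberately break this: in-band distractors (green-painted
objects) of fraction q shift measured GVI by exactly +q, reproducing in
controlled form the misrecognition that hue thresholding suffers on real
pictures; out-of-band distractors at 60–70° exercise the calibrator's
ability to exclude near-band clutter.

Site picture sets model the surroundings as a 360° cylinder of vertical
vegetation columns; per-heading fractions are realized exactly at
`fov = 360/m`. The smooth variant interpolates fractions across azimuth and
adds a heading-locked ripple concentrating vegetation between headings.
The ripple is what gives picture-overlap zones different greenness from
picture centres: a piecewise-linear azimuth profile on the heading grid has
no spectral component at the coverage-multiplicity frequency, so without it
the discrete-picture GVI and the stitched panorama agree identically and the
overlap effect would be invisible. Pitched views scale vegetation by
`1 − |p|/90 × (0.8 up / 0.4 down)` — a minimal tilt model (up trades green
for sky faster than down trades it for pavement) sufficient for multi-pitch
configuration comparisons, with no claim of photogrammetric realism.

Networks are concentric ring roads (closed 72-gons, typed as urban
expressways) with radial spokes cycling through the remaining road types —
the radiating-and-lattice layout typical of large ring-road cities. GVI
surfaces are Gaussian random fields with exponential covariance
`sill·exp(−d/range)`, mean 0.17 and sill 0.015 by default (echoing a
low-greenery urban corpus with site variance ≈ 0.016), clipped to [0, 1];
range 0 degenerates to i.i.d. noise.

Passing on this synthetic stack establishes that every formula, invariant
and algorithm is implemented correctly; it does not establish segmentation
accuracy on photographs (shadows, mixed pixels, green artifacts), robustness
to real picture-acquisition failures, or the transferability of any
particular hue band or distance threshold to a new city.

## Problem sizes and determinism

The default test-and-demonstration configuration uses 60–120 px pictures, a
two-ring/four-radial network of ≈ 20 km (≈ 220 sites), 999 permutations, and
50-site configuration comparisons — sizes chosen so the full validation
suite exercises every stage, including two complete pipeline runs, in well
under a minute while leaving every statistic far from its small-sample
regime. Picture resolution is a config parameter (default 600 × 600, the
common street-view tile size). All randomness flows from a single seed per
entry point (`PipelineConfig.seed`, `--seed`); derived stages use fixed
offsets of it, and repeated runs are byte-identical, which the test suite
asserts on the written artefacts.

## Known limitations

- Hue thresholding misclassifies green-painted objects by design; the
  calibrator can only exclude clutter whose hue lies outside the optimal
  band.
- The stitcher is a projective model without feature registration; it
  reproduces the direction and rough magnitude of the panorama effect, not
  any specific stitching software's pixels.
- Centerline attribute inheritance is distance-based and can include roads
  merely touching a junction; widths at junction-adjacent segments are
  means over all contributors.
- Shapefile input is not supported; road geometry I/O is GeoJSON in a
  projected CRS (reprojection is out of scope and geographic input is
  rejected).
- The Gi\* variance form is the global-moments one; packages using the
  conditional form will differ slightly in the far tails.
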