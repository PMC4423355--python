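# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generator does and does not emulate, and
the known limitations.

## Segmentation and alignment

The whole-embryo mask is computed from the DIC image only: Otsu
threshold with the embryo on the dark side, morphological closing
(disk radius 5 px), selection of the largest connected component, and
hole filling. The procedure is fully deterministic. Hard errors replace
manual quality control: "no embryo found" if no component covers ≥5% of
the frame, "multiple embryos" if a second component reaches ≥50% of the
largest, and a mask-quality error if the bounding-box fill fraction
leaves the ellipse-like band [0.5, 0.95].

Alignment rotates by the principal-component angle of the mask pixel
coordinates (tie for a circular mask broken by declaring the image
x-axis the major axis), iterating up to three times until the residual
angle is ≤0.5°. Images are interpolated bilinearly, the mask with
nearest-neighbour to keep it binary; all are cropped to the mask
bounding box plus a fixed 10 px margin. Antero-posterior polarity cannot
be read from morphology, so anterior-left is metadata (manifest flag or
curator input); when anterior is on the right the scene is mirrored.
The membrane image is acquired at a different magnification and passes
through alignment untouched.

## Midline and strip

The midline is initialised from the morphological skeleton of the mask,
pruned to its longest path by double breadth-first search and ordered
left-to-right. The path is collapsed to one y per x and smoothed with a
15 px moving average before knots are placed: knot x-values are
equidistant across the mask's horizontal span (not arc length — the
stored quantities are knot x/y coordinates and the band is read out per
integer x), knot y-values are interpolated from the smoothed path and
clipped into the mask column. A natural cubic spline interpolates the
five knots; a manual override list replaces computed knots verbatim.

Strip height is `round(0.10 × mask height)` with half-up rounding to an
integer pixel count. With integer pixels the height/mask ratio is within
0.005 of 10% for any mask at least 100 px tall (every realistic embryo);
for very small masks the nearest-integer guarantee |h − 0.1H| ≤ 0.5 px
is the best achievable. The full rectangle-normal band is used to the
poles; its consequences there are handled at profile level (below).

## Profile extraction and unmixing

For each integer x between the outer knots, the profile sample is the
arithmetic mean RGB over a column perpendicular to the local spline
tangent, strip-height samples long at unit spacing, nearest-pixel
lookup, out-of-image samples dropped. Near the poles the tapering embryo
covers only part of the column, so the mean mixes in non-embryo
background and can fabricate intensity ramps; samples whose column is
less than 95% inside the mask are therefore dropped. This sacrifices
roughly the outermost 1–3 %EL at each pole, where boundaries are not
scored anyway.

Stain intensities are pure channel arithmetic, pointwise and
monotone: NBT/BCIP (purple) absorbs red, so `I = 255 − R` (blue carries
a similar but weaker signal and is ignored); FastRed depresses green
relative to red, and the red-minus-green difference simultaneously
removes the yellow-like background of unstained tissue. The default
FastRed mode is `I = clamp(R − G, 0, 255)`, reading the subtraction as
already stain-positive on the bright background; a `literal_invert`
mode (`255 − (R − G)`) is selectable in the configuration for the
word-for-word reading of "inverting the outcome". Positions map
affinely to % embryo length between the mask's horizontal extremes.
No background-field or exposure correction is applied: the atlas
integrates boundary positions, not absolute intensities.

## Boundary detection and clamped-spline fitting

Detection runs on the intensity profile smoothed with a 5-sample moving
average: the profile is reduced to its turning points, sub-threshold
wiggles (amplitude < `min_amplitude`, default 20 intensity units) are
pruned smallest-first, and each surviving monotone run becomes a
candidate window with a rising/falling direction. Fitting uses the raw
profile. A window whose largest adverse excursion exceeds half its range
is rejected as ambiguous.

The boundary model is a cubic through (x₁,y₁), (x₂,y₂), (x₃,y₃) with
first derivative exactly zero at x₁ and x₃: two Hermite segments whose
interior slope at x₂ is chosen for second-derivative continuity; outside
[x₁,x₃] the curve continues flat at the plateau values. Initialisation:
y₁/y₃ are robust shoulder means at the window edges, x₂ the
half-amplitude crossing, x₁/x₃ the 10%-of-amplitude plateau edges, and
y₂ = (y₁+y₃)/2; x₁, x₂, x₃ are then refined by bounded least squares
against the raw profile (ordering enforced via gap parameters; if the
solver does not converge within its evaluation budget the initial fit is
returned flagged). Manual override control points bypass fitting.

Position is defined as %EL(x₂) — the half-amplitude point, the standard
convention for sigmoid expression boundaries — and width as
%EL(x₃) − %EL(x₁); control points are stored in pixels, y in the graph
convention (origin upper-left, y = 255 − intensity).

Boundary identity is a per-gene ordered catalogue of (ID, facing)
pairs, shipped as an editable YAML table. An anterior-facing boundary
delimits the anterior edge of its domain, so its intensity rises along
+x; posterior-facing falls. When the number of fits matches the
catalogue and directions agree, assignment is positional; otherwise an
order-preserving alignment maximises facing/direction agreement, and
surplus fits are flagged `unassigned` rather than dropped (tie-breaks
leave a fit unassigned rather than shifting it onto a later ID). The
*gt* entry uses IDs {2, 5, 6, 7} with 3–4 reserved for numbering
consistency across species; other genes' facings are package defaults
chosen to match their qualitative patterns and are explicitly
configuration, not measurements.

## Staging

Cycle assignment uses the nuclear doubling model: 2^(c−1) nuclei at
cycle c, class boundaries at geometric midpoints, i.e.
`c = clamp(round(log2 n) + 1, 1, 14)`. Nuclei are counted with a
difference-of-Gaussians band-pass (σ = 0.8/2.5 px) and local-maximum
detection inside the mask; counting runs on the unaligned nuclear image
because interpolation during rotation merges densely packed late-cycle
nuclei. Blank or saturated nuclear images raise an "uncountable" error.

Within C14A (58 min, eight equal classes of 7.25 min) the time class is
`min(8, floor(depth × 8) + 1)` where depth ∈ [0,1] is the membrane
invagination fraction. On synthetic images depth is read from the
rendered front; on real images it is curator-supplied metadata, which
always overrides inference — mirroring visual classification. The
printed stage durations (C10–C14A: 13, 11, 14, 23, 58 min; earlier
cycles ≈10 min) are encoded in `StagingTimetable`. The depth proxy is a
stand-in for true membrane-morphology criteria, which are out of scope.

## Integration

Per (gene, time class, boundary ID) group: arithmetic mean, median
(mean of the two central order statistics for even n), sample standard
deviation (n−1 denominator) and unscaled MAD (no 1.4826 consistency
factor — reported as a raw deviation in %EL). Single-member groups
report zero dispersion with a `single_embryo` flag, and an `n` column is
added so users can filter (a documented addition to the deposited
schema). RNAi-background measurements are refused unless forced,
because variable knock-down strength makes averaged positions
unmeaningful; forced output is flagged.

## Synthetic generator

The generator renders an analytic ellipse (default canvas 700×350 px,
semi-axes ≈300×120 px, a realistic 2:1 aspect that is fast to process)
at arbitrary rotation, with per-embryo jitter of axes, rotation
(±20°) and centre in batch mode. The four rasters:

* **bright-field** — stain strength s(x) ∈ [0,1] built from logistic
  ramps, one per boundary (anterior-facing rising, posterior-facing
  falling; rising/falling pairs multiply into domain lobes, lobes add);
  pixel colour is linear interpolation between an unstained-background
  colour and a full-stain colour, chosen so the channel arithmetic above
  inverts the rendering exactly up to noise. The nominal boundary width
  is defined as the span of the least-squares zero-end-slope cubic fit
  to the ramp, giving logistic scale k = width/7.05.
* **DIC** — dark textured interior with an edge ring on a bright
  background, sufficient for automatic masking.
* **nuclear** — exactly 2^(cycle−1) Gaussian spots on a jittered grid
  inside the ellipse (a Poisson-disc-like pattern with guaranteed
  minimum spacing, fast even for the 8192 nuclei of C14).
* **membrane** — a dark front advancing down a fixed band to fraction
  depth of its height; stages render the mid-class depth (2t−1)/16.

Noise is i.i.d. Gaussian per channel (default SD 2 intensity units),
clipped to [0,255]. Everything is deterministic given the seed, and the
ground-truth manifest round-trips losslessly through CSV. Boundary
ramps closer than the mean of their widths are rejected at
specification time.

The generator emulates geometry, colorimetry, nuclear density and
staging morphology — not optics: no point-spread function, no DIC
shear, no illumination field, no 3-D curvature, and a single stain per
synthetic embryo. Passing the recovery tests therefore demonstrates
correctness of the measurement chain under the stated image model, not
robustness to the full variability of real micrographs (uneven
staining, debris, focus gradients), which the hard QC errors and manual
override hooks are there to absorb.

## Problem sizes and numerical choices

The test suite and acceptance checks run entirely on generated data:
recovery sweeps use 50 embryos per noise condition at the default
canvas, staging round-trips cover C8–C14A, and the integration oracle
compares 1000 random groups against a sort-based reference. Tolerances:
alignment residual ≤0.5°, end slopes < 1e-9 (exact zeros of the Hermite
construction, asserted numerically), boundary-position recovery ≤0.5 %EL
noise-free and ≤1 %EL at σ = 8. Least-squares refinement is capped at
100 function evaluations; ties and degenerate inputs (circular masks,
flat profiles, zero-span masks) raise typed validation errors rather
than guessing.

## Known limitations

* A–P and D–V polarity are metadata, never inferred.
* Boundaries within ~3 %EL of a pole are not measurable (pole trimming).
* The boundary catalogue beyond *gt* is configuration with invented
  facings; edit `data/boundary_catalogue.yaml` to match a stain panel.
* Pair-rule co-stain registration and gene-network model fitting are out
  of scope; double-stained synthetic embryos are not generated (the
  pipeline itself can unmix both channels of a real double stain).
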