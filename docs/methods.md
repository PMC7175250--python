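# Methods

## The assay being modeled

An in-vitro CaOx crystallization screen: urine (or buffer) is spiked with
oxalate, mixed with an inhibitor dilution, incubated (7 h by default) in
imaging wells, and photographed in brightfield — per condition, 2 wells
with 5 fields of view each, in N = 3 independent experiments. Inhibitor
efficacy is read out as the total crystal area per field relative to the
no-inhibitor control of the same experiment. Crystals are classified into
the two hydrate polymorphs, COM (monohydrate: small, abundant, ~10 µm) and
COD (dihydrate: tetragonal-bipyramidal, ~20 µm, elongating into needles
under strong inhibition), plus "not defined" structures and background
noise.

## Segmentation

Brightfield crystals present a dark rim around a textured mid-gray
interior on a bright background, so the gradient magnitude is the robust
cue. The segmenter smooths with a Gaussian (`edge_sigma`, default 1.4 px),
takes the Sobel gradient magnitude, thresholds it (Otsu by default; a
fixed threshold is available), closes the edge mask (disk radius 2), fills
holes, and erodes by `mask_erosion_radius` (default 2 px) — the gradient
ridge straddles the true boundary, so without this step masks are dilated
by roughly the ridge half-width and per-object IoU against ground truth
drops from ≈0.85 to ≈0.6. Touching objects are split by watershed on the
negated Euclidean distance transform, smoothed by
`distance_smooth_sigma` (1 px) and seeded at regional maxima with a
minimum separation of `marker_min_distance` (10 px); connected components
that receive no seed keep one seed so no object is lost. Segments smaller
than `min_object_area` (4 µm²) are discarded. Border-touching objects are
kept by default (`border_policy="keep"`), because dropping them would bias
per-field area totals; a `drop` policy exists for shape-sensitive work.

Degenerate inputs: a constant or pure-noise field returns zero segments.
The noise guard is the observation that Otsu applied to a gradient image
with no real edges lands inside the noise distribution and marks an
implausibly large edge fraction; a threshold marking more than 25% of
pixels is treated as "no scene".

## Features

Shape features use standard region properties: the equivalent-ellipse
axes and eccentricity from second central moments of pixel centers, the
weighted boundary-step perimeter estimator, circularity = 4π·area /
perimeter² (defined as 1 for a degenerate single-pixel region). Lengths
and areas are calibrated by the pixel size (µm, µm²).

Intensity features are statistics of the raw pixel values under the mask.
The distribution-width scalar `intensity_spread` is the interquartile
range divided by the bit-depth range — a single robust summary of the
intensity distribution chosen from the several possible definitions; it
is dimensionless so 8- and 16-bit images are comparable.

Texture features are Haralick statistics (correlation, contrast,
homogeneity, energy = √ASM) of a gray-level co-occurrence matrix over the
segment's bounding box restricted to its mask: only pixel pairs with both
members inside the mask are counted, at distance 1 px for the four
standard angles, symmetrized, normalized, angles averaged. Quantization
uses 32 levels over the **full bit-depth range** rather than the region's
min–max, so that a global intensity shift moves the matrix predictably (a
shift of exactly one level leaves all GLCM features unchanged). A
constant-intensity or single-pixel region takes the degenerate values
energy = 1, contrast = 0, homogeneity = 1, correlation = 1.

## Classification

Training labels are produced by image-scoped single-feature threshold
rules — within one image the classes separate on e.g. major-axis length
or area, even though no single global threshold works across images.
Rule precedence defaults to list order (later rules override earlier
ones); rules given the same explicit precedence that disagree on a
crystal raise a conflict error listing the crystal ids. Crystals matched
by no rule are excluded from training.

The classifier is an SVM with polynomial kernel of degree 3 ("cubic"),
C = 1, coef0 = 1, automatic kernel scale, one-vs-one multiclass, no class
weighting — imbalance is reported through per-class F1 rather than
reweighted away. Features are standardized; inside cross-validation the
scaler is fit on each training fold only (verified by a leak-free manual
CV oracle in the tests). Cross-validation is stratified fivefold with a
recorded seed; to make the report invariant to input row order, rows are
first sorted by a content hash of (features, label). The final model is
refit on all rows and serialized as a single joblib artifact embedding
its feature schema, class list, format version and a training
fingerprint; reloading reproduces predictions exactly.

## Quantification

Per condition (experiment × compound × concentration), class areas and
counts are summed over the 2 × 5 fields. The crystal total is
COM + COD + n.d.; the noise class is tracked but excluded. Normalization
is strictly within-experiment: each condition's crystal total is divided
by the same experiment's control total (×100). A missing or zero-area
control is a hard error, never a silent NaN.

The MIC is the lowest tested concentration whose across-experiment
**mean** normalized area is strictly below the threshold (default 5%, as
"< 5%" — a mean of exactly 5.0% does not qualify). Concentrations are
never interpolated; MICs are grid members, and "not reached" renders as
"> max tested" (e.g. ">100 µM"). An alternative reading — per-experiment
MICs averaged — is available via `per_experiment=True`. For COM-only
inhibition the default denominator is the control's *total* crystal area
(the literal reading of the reporting rule); `com_denominator="com"`
switches to the control's COM area. With the default denominator
MIC_complete ≥ MIC_COM holds on any series.

## Synthetic scenes

The generator is the study-conditions oracle, not a convenience mock. Its
defaults encode the assay's phenomenology: COM as compact
truncated-rhomboid polygons with lognormal length of mean 10 µm (shape
0.22), COD as elongated diamonds of mean length 20 µm (shape 0.18) whose
`cod_elongation ≥ 1` stretches the long axis and thins the short one
(needle phenotype), "not defined" structures as irregular star polygons
(6–15 µm), and noise as small dark debris specks (3.4–5.4 µm) plus
non-instance sub-resolution speckle. Appearance: background at 0.75 of
the intensity range with a ±8% linear illumination gradient in a random
direction, a 2-px dark rim at 0.30, textured interior at 0.58
(texture sd 0.05; 0.11 for n.d. so texture is class-informative), focus
blur of σ = 0.8 ± 0.4 px jittered per image, additive sensor noise
sd 0.012 of range. These amplitudes were chosen once to look like
mid-quality 16-bit brightfield data and to exercise the illumination- and
focus-robustness concerns of real acquisitions; they are not tuned to any
test.

Placement is sequential bounding-circle rejection (largest objects
first), which raises the packable density well above naive sequential
packing; impossible packings raise an error rather than silently
overlapping. Ground-truth areas are the rasterized polygon areas, so the
oracle and the label map agree exactly. Everything is a pure function of
the spec (the seed is a spec field): re-rendering is bit-identical.

The dose-series generator renders a full plate (N = 3 experiments ×
(control + concentration grid) × 2 wells × 5 fields; 384×384 px fields
with ~22 objects by default) with per-concentration effect factors:
crystal-count scale, COM-size scale, COM→COD proportion shift, COD
elongation ramp, plus a per-experiment yield factor (±20%) emulating
inter-experiment crystallization variability — which the within-experiment
normalization must (and does) cancel. Object counts are Poisson around
the scaled expectations. The default effect sequence (0.8, 0.4, 0.02,
0.01 at 0.1/0.3/1/3 µM) crosses the 5% rule at 1 µM with margins wide
enough that Poisson sampling cannot flip the call.

The training fixture distributes `n_crystals` ground-truth objects over
13 images with proportions 40/25/18/17% (classes 0–3), renders, segments,
extracts features and attaches labels by segment↔instance matching (best
IoU ≥ 0.3; unmatched segments become class 3, as spurious detections).
Because segmentation can merge or drop the odd object, classes that fall
below the CV's 5-example minimum are topped up from supplementary scenes.

### What the generator does not emulate

No physical crystal optics (diffraction fringes, birefringence), no
aggregation into touching clusters beyond the optional overlap mode, no
crystallization kinetics over time (timepoints would be emulated through
effect functions only), no spatial correlation of noise, and COM/COD
appearance is more stereotyped than in real urine. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under realistic geometry and illumination variation — not
field-ready accuracy on any particular microscope's data; on real data
the segmentation thresholds and rule thresholds would need recalibration,
which is why all of them are exposed as parameters.

## Cell-assay quantification

No algorithmic detail is prescribed for these readouts, so the defaults
are declared here. Occupied area: local standard deviation in a 7-px
window, thresholded at 0.04 of the intensity range (flat monolayer noise
sits near 0.01, crystal relief near 0.1), closed, hole-filled, then
eroded by half the window to undo the window's dilation of texture
boundaries; components under 25 px are discarded. Dead-cell dots: Otsu
threshold (a field whose dynamic range is below 0.1 of range counts as
blank → 0), watershed splitting with 3-px seed separation, components
kept within a 4–400 px size band. Otsu makes the count invariant to
global intensity rescaling. Condition summaries mirror the screening
module: mean ± SD per condition, normalized to the in-experiment control.

## Numerical and testing choices

Canonical concentration unit: nanomolar (all screening values, 40 nM to
100 µM, are exactly representable). Pixel size comes from configuration
(default 0.32 µm/px, a 20×-objective class), never from image metadata.
Determinism everywhere: one `numpy` Generator per spec/seed, no global
state; fixtures, label maps and CV reports are bit-reproducible. Problem
sizes in the test suite — 512–960 px scenes, a 1710-crystal benchmark
fixture, five-seed dose-series recovery on 384-px fields — were chosen as
the smallest sizes at which the statistical claims (IoU floors, CV
accuracy, MIC margins) are comfortably stable.
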