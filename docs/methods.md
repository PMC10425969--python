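# Methods

`mpquant` quantifies fluorescently labelled microplastic particles in RGB
micrographs of filter membranes: micrographs of gut or frass digests whose
plastic content fluoresces blue/green under violet excitation through a
long-pass emission filter. This note documents the models, conventions and
numerical choices in enough detail to reproduce or audit any stage.

## Image model and compositing

Input images are 8-bit RGB (TIFF/PNG). 16-bit inputs are linearly rescaled
to [0, 255] with a warning; grayscale inputs are rejected because the
red-channel removal below would be meaningless. The red channel is
discarded — in fluorescence images of this kind it carries mostly sensor
noise and autofluorescence leak rather than particle signal — and the
composite intensity is the average of green and blue with half-up rounding:

    I(r, c) = round((G(r, c) + B(r, c)) / 2).

All later stages operate on this composite and its 256-bin histogram.

## Scale calibration

Physical units come from a microns-per-pixel factor, supplied directly or
derived from a scale-bar measurement (`known_length_um /
scale_bar_length_px`). Areas convert with the squared factor. An
uncalibrated image is still processed, but all µm² quantities are NaN and
the maximum-area exclusion (defined in µm²) is skipped with a warning.

## Automatic thresholding

Particles are bright on a dark background, so mask foreground is the
strict-bright side of a global threshold `t` (`I > t`). Two rules are
implemented:

**Intermodes.** The histogram is repeatedly smoothed with a 3-bin moving
mean until exactly two strict interior local maxima `m1 < m2` remain; the
threshold is `floor((m1 + m2) / 2)`. Smoothing runs on *unnormalized
integer* sums (kernel `[1, 1, 1]` without the division by 3): only
comparisons matter, and exact arithmetic makes the mode structure exactly
symmetric under histogram reflection, which float convolution is not. If
the histogram collapses below two modes, or 10 000 passes do not reach
bimodality, the image is flagged `threshold_failed` rather than guessed at.

**Rényi entropy.** With `p_i = counts_i / N` and background mass
`P_B(t) = Σ_{i≤t} p_i`, the threshold maximizes

    H_α^B(t) + H_α^F(t),  H_α^B(t) = (1/(1−α)) · ln Σ_{i≤t} (p_i / P_B(t))^α

(foreground analogous over `i > t`), over all `t` with occupied bins on
both sides; ties break to the smallest `t`. At `α = 1` the Shannon
(maximum-entropy / Kapur) limit is used. The default order is `α = 2`. The
historical three-order combination variant of some RenyiEntropy
implementations is deliberately out of scope; there is no evidence which
variant any particular legacy analysis used, and the combination rule adds
untestable dialect risk. Implementation detail: validity of a split is
decided on exact integer cumulative counts, and foreground sums are
accumulated from the right, so no cancellation or log-of-zero can occur at
near-degenerate splits.

**Method selection.** Practitioners choose Intermodes for plastic-dense
images and Rényi for sparse ones. The `auto` policy operationalizes this: a
provisional Otsu split of the composite estimates the foreground fraction,
and fractions ≥ `dense_cutoff` (default 0.05) select Intermodes, else
Rényi. The chosen method and threshold are first-class QC outputs per
image, making the per-image choice auditable.

## Watershed separation of touching particles

Binary masks are split with a distance-transform watershed: Euclidean
distance transform of the foreground, internal markers from its regional
maxima with maxima shallower than a peak tolerance (default 1 px of
distance) suppressed via h-maxima, then marker-constrained flooding with
8-connected regions and one-pixel background cuts between adjacent labels.
The tolerance prevents over-segmentation of single discs whose digital
distance map plateaus; two overlapping discs of radius r split reliably
because their saddle is `r − sqrt(r² − d²/4)` deep, which exceeds 1 px for
any center distance `d ≥ 1.1 r` at the default bead scale (≈ 4 px at
r = 25 px). The watershed never creates foreground pixels and never merges
separate connected components.

## Morphometry

Per labelled region: pixel-count area, centroid, and an outer-boundary
perimeter measured by Moore-neighbour chain tracing with axis steps of 1
and diagonal steps of √2. Circularity is `min(1, 4π·A/P²)`; single-pixel
regions (chain length 0) are clamped to 1. Interior holes do not contribute
to the perimeter. This is one of several defensible digital-perimeter
dialects; numeric parity with any particular legacy tool (e.g. ImageJ's
corrected perimeters) is not claimed, and small-particle circularity should
be treated as approximate.

## Exclusion rules and QC

Three per-particle rules, applied as flags (records are never deleted):

* `below_min_px` — area < 5 px (strict), removing thresholding/watershed
  artifacts at the cost of particles at the camera's resolution limit. An
  alternative µm²-based minimum is available but off by default.
* `above_max_area` — area > 20 000 µm² (strict). The bead stock is 90–106
  µm (≈ 8 800 µm² max), so anything over roughly double the largest bead is
  a fused clump, not a single particle. On a reference table of 2 557
  particles with 8 oversized records this excludes ~0.3%.
* `outside_circularity` — outside the configured range, default [0, 1]
  (i.e. keep any shape, matching a protocol that counts fragments of
  arbitrary form).

Border-touching particles are retained by default (configurable). Per-image
QC flags an image `saturated` when the mask's foreground fraction exceeds
`saturation_cutoff` (default 0.30) — an operationalization of "too much
plastic to measure individual particles"; the cutoff is reported in every
QC record so users can tune it. Threshold failures propagate as
`threshold_failed`. Either flag marks the image unprocessable; it is
reported, never silently dropped.

## Synthetic scenes

The generator renders quasi-circular beads as filled discs with a ~1 px
soft rim on a textured background, emitting strongly in blue (default mean
220), partially in green (140), with only a configurable leak plus noise in
red. Background is a mean level (default 20) plus low-frequency texture
(bilinearly upsampled coarse Gaussian noise, amplitude 8) in green/blue,
and per-pixel Gaussian noise (sd 4) in all channels. The default scene is
50 beads of uniform 90–106 µm diameter at 2 µm/px on a 1024×1024 canvas —
the nominal stock size of commercial blue-fluorescent polyethylene
microspheres at a desk-scale image size; a `degraded` preset draws
log-normal fragments (median 20 µm, σ = 0.35) emulating the much smaller
particles seen after gut passage. Placement is rejection sampling with
minimum center distance the sum of radii (+1 px); an `overlap_fraction`
instead attaches that share of particles to a neighbour at 0.6–0.95 of the
radius sum. One seed drives diameters, placement, texture and noise, so a
spec renders bit-identically.

What the generator does **not** emulate: optical PSF/defocus blur,
non-circular fragments and fibres, fibre-texture anisotropy of real
glass-fibre filters, vignetting, and saturation bloom. Passing recovery
tests therefore demonstrate correctness of the measurement chain on
idealized particles, not detection performance on real filter images.

## Validation against reference counts

The minimum-size threshold is swept over 1–5 px; the count at `k` is the
number of particles with `area_px ≥ k` surviving all other rules (counts
are non-increasing in `k` by construction). Automated counts are compared
with per-image reference counts (human raters or synthetic ground truth)
by the slope through the origin `b = Σ(auto·ref) / Σ(ref²)` — `b = 1` is
parity — plus RMSD, an OLS fit with intercept for transparency, and the
per-image SD across raters when more than one is available. Neither
regression form is privileged in tests.

## Developmental-trend models

Per-pellet plastic quantity versus collection week is fit as a GLM with
week as a numeric covariate: Gaussian-identity for total area,
Poisson-log for counts with a quasi-Poisson refit when the Pearson
dispersion exceeds 1.5 (quasi SEs inflated by √dispersion). The week effect
is tested against the intercept-only model — with a single covariate this
coincides with the type-III test of the term. Gaussian models use the
unknown-variance likelihood ratio `n·ln(RSS₀/RSS₁) ~ χ²₁`, Poisson the
deviance difference `~ χ²₁`, and quasi-Poisson a scaled-deviance F-test
(likelihood ratios are undefined under quasi-likelihood). An exactly
constant response returns slope 0 with p = 1 rather than a failed fit.
Week-as-factor coding is intentionally not the tested default: the
scientific claim is a monotone trend.

The frass simulator draws `baseline + effect·week + N(0, sd)` for areas
(clipped at 0; negligible at the default baseline 1000, slope 300, sd 100),
Poisson or negative-binomial (gamma-mixed) counts for the count response,
with defaults matching a six-week collection of 15 pellets per week. At
that design the Gaussian fit covers the true slope within 2 SE in ≈ 95% of
replicates and holds the nominal 5% type-I error (measured 0.053 over
1 000 null replicates at seed 1).

## Known limitations

* Entropy thresholds (Rényi, including the Kapur limit) are known to sit
  just above the dominant mode when the histogram is extremely unbalanced
  (foreground ≪ 5%). On the synthetic background's low-frequency texture
  this produces connected supra-threshold patches that the 5 px rule cannot
  remove, inflating counts on very sparse synthetic scenes. Real filter
  backgrounds differ; for sparse images users should inspect the recorded
  threshold and, if needed, force `--method intermodes` or adjust
  `dense_cutoff`. The pipeline-level recovery guarantees quoted above are
  established in the dense (Intermodes) regime that bead-feeding filters
  occupy.
* No sub-pixel measurement: areas are pixel counts, so relative area error
  grows for particles below ~10 px diameter.
* Exact parity with legacy ImageJ measurements (perimeter corrections,
  RenyiEntropy variant) is explicitly not claimed.

## Problem sizes used in tests

The test suite and the acceptance script regenerate everything they
measure: ten 1024×1024 50-bead scenes for recovery, twenty rendered
touching pairs for watershed splitting, 100 random histograms × three
orders for the thresholding oracle, five scenes of 40–60 beads for the
agreement slope, and 200 recovery + 1 000 null GLM replicates at the
6 × 15 study design. These sizes give stable statistics while keeping a
full run in the low minutes on one core.
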