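# Methods

This note documents the models, parameter choices and numerical behavior
of `podosem`: what each measurement computes, what the synthetic images do
and do not emulate, and where the open design choices were settled.

## Coordinate and calibration conventions

Pixel centers sit at integer coordinates, origin at the top-left pixel
center, x rightward, y downward. ImageJ ROI vertices address pixel
corners and are shifted by (−0.5, −0.5) on read; the package's `.roi`
writer emits sub-pixel float coordinates so arbitrary vertices round-trip
exactly. ROI rasterization uses the even-odd (crossing-number) rule on
pixel centers with the standard half-open boundary treatment, which is
deterministic and agrees with an exhaustive point-in-polygon oracle on
off-boundary centers. Physical calibration is a single isotropic
µm/pixel scale supplied by the user: SEM magnification alone does not
determine pixel size, so no default is hard-coded.

## Pre-smoothing

"Radius" of the smoothing step is interpreted as the Gaussian σ in pixels
(the accurate-blur convention), applied separably with reflection at the
borders and a kernel support of 4σ (configurable ≥ 3σ). The blur is
applied to the full image before ROI masking to avoid mask-edge
artifacts; whether the original workflow blurred the whole frame or only
a crop is not documented, so the choice is recorded here and both are
reachable through the API.

## Method 1 — Yen threshold SD fraction

The ROI histogram (256 bins; 16-bit data is rescaled to 8 bits first) is
cut at the argmax of Yen's maximum-correlation criterion

TC(t) = −ln[G₁(t)·G₂(t)] + 2·ln[P(t)·(1 − P(t))],

with G₁, G₂ the cumulative sums of squared bin probabilities below/above
the cut and P the cumulative probability. Ties break toward the lowest
index; the returned level is the boundary between bins t and t+1, so
"intensity ≤ level" selects exactly the foreground bins and a two-delta
histogram yields a level strictly between the modes. Slit diaphragms are
recessed grooves and image dark in secondary-electron contrast, so the SD
class is the dark side (a polarity flag flips this). The histogram is
restricted to ROI pixels; a whole-image histogram would let out-of-ROI
content bias the cut.

**Error model.** On groove patterns the Yen cut consistently lands just
below the bright foot-process mode, not midway between modes. Every pixel
of the edge-transition band (width ≈ 4σ_edge per slit, where σ_edge
combines the physical edge softness and the method's own blur) then
counts as SD, giving a positive bias of roughly 4σ_edge/period. At the
simulator's default geometry this is ≈ +12 pp, and any continuous
brightness variation of the FP tops (the crest term) is partially swept
in as well. The method therefore only recovers truth within a few
percentage points when slits are well-resolved and sharp-edged
(transition band < 5% of the period) — consistent with its weak
diagnostic performance relative to the ridge method.

## Method 2 — ridge-detection SD fraction

The detector follows the classical curvilinear-structure recipe:

1. **Derivatives.** Sampled Gaussian derivative kernels of order 0/1/2 at
   scale σ, moment-corrected so constants and ramps are annihilated
   exactly and quadratics differentiate exactly; separable correlation
   with reflection boundaries.
2. **Line points.** Per pixel, the Hessian's principal eigenvector
   (largest |λ|) gives the cross-line direction; the second-order Taylor
   extremum along it must fall inside the pixel (|t·n_x| ≤ 0.5 and
   |t·n_y| ≤ 0.5) and λ must be positive for dark lines. Saliency is the
   scale-normalized σ²·λ of the image normalized to [0, 1], making the
   hysteresis thresholds independent of bit depth and σ. On synthetic
   Gaussian-profile lines the subpixel centerline is recovered to
   < 0.02 px at 0–45°.
3. **Linking.** Seeds (saliency ≥ upper threshold) are processed in
   (row, column) order; lines grow in both tangent directions through
   8-neighbors with saliency ≥ lower threshold, choosing the neighbor
   with the smallest normal-orientation discontinuity, then the smallest
   positional jump — fully deterministic. Lines shorter than the minimum
   length are dropped; a maximum length of 0 means unbounded. Lines
   simply terminate at junctions; no splitting heuristics.
4. **Widths.** Per point, the left/right edges are the gradient-magnitude
   maxima along the normal within line_width/2 (0.25 px sampling); a side
   with no interior maximum falls back to the cap. For a groove of half
   width a detected at total scale σ_tot the extrema sit at the root of
   (x+a)·φ((x+a)/σ_tot) = (x−a)·φ((x−a)/σ_tot): essentially ±a when
   a ≳ 2σ_tot, drifting outward toward ±σ_tot as a shrinks. Width
   estimates are therefore nearly unbiased only at matched scale, which
   is why parameter matching matters (below).
5. **SD binary.** Default `line-envelope` mode rasterizes the polygon
   strip swept by the per-point width envelope around each centerline
   (exact for straight constant-width lines, no end caps) and intersects
   it with the ROI. The alternative `inter-ridge` mode closes the
   rasterized centerlines with a disk of radius line_width/2, bridging
   the region between ridges closer than line_width; both readings of
   "area between adjacent ridges" are kept because the original binary
   construction is not documented.

**Parameters.** The published profile (σ = 5.70, line width 15, hysteresis
0.00/0.17, min length 5.00, max length 0.00) is the config default for
real micrographs. Those values were tuned to the study's own (unstated)
pixel scale; at the simulator's default geometry the implied total scale
(~7 px after the σ = 4 blur) exceeds the 7.5 px width-search cap, so no
fixed-parameter set can be transferred across pixel scales. The package
therefore exposes the matching rule σ ≈ w/(2√3) for an expected groove
width w (`matched_ridge_params`) and a `sweep_parameters` grid search
reporting sensitivity, false-positive area fraction and their Youden
difference on ground-truthed images — the same optimize-on-training-set
procedure the published parameters came from. Calibration at matched
scale: mean absolute SD% error ≈ 1–3 pp over true fractions 20–40% at
default noise, monotone in truth, < 2 pp change under 90° rotation.

## Method 3 — profile FPW

Profiles are sampled by bilinear interpolation at 1 px arc-length steps
along user polylines and converted to µm. Peaks are local maxima with
prominence ≥ 0.2 of the profile's dynamic range and separation ≥ 0.1 µm
(both configurable; the original peak criterion is not documented),
refined by 3-point parabolic interpolation. Bright crests (FP tops) are
peaks by default; a polarity flag selects troughs. Per-profile FPW is the
mean adjacent-peak spacing; per-glomerulus FPW averages 3–5 profiles,
which suppresses the end-peak jitter that dominates single-profile error.
Sampling at angle θ to the FP normal inflates FPW by exactly 1/cos θ —
the method's intrinsic orientation sensitivity, verified on synthetic
gratings at 0°/30°/45°.

## Synthetic images and cohorts

`make_pattern` renders a periodic groove pattern in a rotated, optionally
sinusoidally warped stripe coordinate: FP plateau at intensity 0.85 with
a cosine crest (+0.10) peaking mid-FP, grooves of depth 0.6 with erf
shoulders (0.02 µm), then an optional illumination ramp, additive
Gaussian noise (default SD 5% of range) and 8-bit quantization. The
groove mask is captured before noise, so the recorded true SD% is exact
for the rendered pixels; for unwarped axis-aligned patterns whose
reference region spans whole periods it equals slit_width/fp_period
exactly. Defaults: 0.55 µm FP period, 0.165 µm slits (30%), 0.01 µm/px,
256² px.

`simulate_cohort` draws per-mouse true fractions ~ N(group mean,
between-mouse SD) and per-image fractions ~ N(mouse, within-mouse SD),
truncated to (5%, 60%), back-solves slit widths, randomizes orientation
(0–45°) and groove phase per image, and emits ROIs, profile polylines,
a study table and per-image truth. Default groups mirror a
diabetic-nephropathy design: 17 control mice at 32.00 ± 2.08% vs 15
diabetic at 29.82 ± 1.98%, 3–5 images per mouse, within-mouse SD 1 pp.
Mouse-level covariates (fasting glucose, ACR) are drawn negatively
correlated with the mouse's true fraction. What the simulator does *not*
emulate: electron-optical noise structure (charging, topographic
shading), irregular FP branching and junctions, focal-quality variation,
and partial effacement as a distinct texture — so passing tests show the
measurement chain is correct on idealized geometry, not that it is robust
to every real-tissue artifact.

## Diagnostics layer

Per-mouse values are unweighted means of image-level measurements
(hierarchy beyond that — images within mice — is deliberately not
modeled; no mixed effects). Group comparison uses the pooled-variance
Student t-test (Welch behind a flag); no multiplicity correction is
applied. Hedges' g uses J = 1 − 3/(4N − 9); its default CI is the normal
CI of d scaled by J (the direct-on-g variant is available). ROC curves
enumerate all distinct thresholds; AUC equals the Mann–Whitney pair
statistic with ties at ½ (property-tested up to n = 200); the
"lower score = diseased" orientation is explicit. The Youden-optimal
threshold is reported as the midpoint between the straddling observed
scores, ties resolved toward higher specificity. Sensitivity/specificity
CIs are Wilson score intervals. Bland–Altman reports bias and
bias ± 1.96·SD(differences) with per-pair (mean, difference) rows.

**A note on end-to-end AUC.** Under the default cohort moments the
per-mouse effect is d ≈ 1.07, whose Gaussian-model AUC is
Φ(d/√2) ≈ 0.78; the empirical AUC at n = 17/15 has a sampling SD of
≈ 0.085 (Hanley–McNeil), so individual replicate AUCs fall below 0.7
roughly one time in five. The pipeline's discrimination is therefore
assessed on the replicate mean; a per-replicate "AUC > 0.7 in ≥ 90% of
cohorts" bar is not attainable from these group moments alone, and the
corresponding strict test documents this as an expected failure mode of
summary-moment-based simulation rather than a pipeline defect.

## Problem sizes and determinism

Cohort-level tests and the acceptance script use 160² px images at
0.02 µm/px with 3 images per mouse and 10 replicate cohorts; calibration
sweeps use 256² px at 0.01 µm/px — sizes chosen to keep full runs at
desk scale while retaining ≥ 5 FP periods per image. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`);
detection, linking and rasterization are seed-free and deterministic, so
identical inputs reproduce outputs bit for bit.
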