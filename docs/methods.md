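# Methods

This note documents the models, numerical choices, and limitations behind
`redoxmap`. It is written for a reader who wants to know what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## Intensity calibration

Two-photon signal scales nonlinearly with excitation power and detector
gain. We model the response as separable power laws,

    I = concentration · P^a · G^b · c_day,

and fit (a, b, log c_day) by least squares in log space to fluorescein
measurements spanning ≥3 distinct powers and gains. Physically a ≈ 2
(two-photon absorption) and b reflects the PMT dynode chain; both are
*fitted* rather than fixed because real detection chains deviate from the
textbook exponents. The per-day scale c_day absorbs day-to-day laser and
alignment drift. Normalized images are in fluorescein-equivalent μM, and
any ratio of normalized channels (e.g. the ORR) is invariant to the
acquisition settings — a property tested by construction. Detector
saturation and spectral bleed-through are out of scope.

## IHC binarization and masks

Pimonidazole: red channel at 755 nm excitation, positive strictly above
L_P. HIF-1α: the red×green product at 950 nm, positive strictly above
L_H; the product suppresses background that appears in only one channel.
Thresholds are *inputs* (in practice averaged from manually set values
over a subset of images); the code deliberately does not auto-estimate
them. Strict inequalities make binarization idempotent and monotone in
the threshold. Validity masks combine an intensity floor (≥ low_signal)
with exclude/include polygons; pixels count as inside a polygon when
their centre is strictly interior (even-odd rule, centres on the boundary
are outside). Coordinates are 0-based (row, col) with pixel centres at
integer positions; point coordinates are (x, y) = (col, row).

## Landmark registration

Two corresponding point pairs define a line segment in each frame; the
similarity transform is closed-form: scale = length ratio, rotation =
angle difference, translation aligns the first endpoints. The rotation
pivot is the first fixed landmark (any pivot gives the same mapping; one
is fixed for reproducible parameters). The translation is rounded to
whole pixels after scale and rotation, respecting the discrete grid, so
the post-rounding endpoint residual is at most √2/2 px. Binary maps are
resampled nearest-neighbour (binarization survives exactly); continuous
maps bilinearly. Scale is not rounded. Round-trip (forward then inverse)
nearest-neighbour warping erodes blob boundaries by up to ~1 px; the
Jaccard overlap stays ≥0.98 on average for structures at the regional
scale (tens of pixels), but can drop to ~0.95 for 20 px blobs under
extreme scale changes (0.8×) — a resampling fact, not an estimation
error, since the transform itself is recovered to machine precision.

## Regional (100 μm disk) analysis

The disk kernel is a pillbox whose rim weights are the *analytic* area of
intersection between each pixel square and the disk (computed from the
circle-quadrant area function, not supersampling). The averaging kernel
sums to 1; the summation kernel is the raw coverage map (averaging ×
πr²). Regional averages divide the summation-kernel convolution of each
masked layer by the convolution of the mask itself — this single rule
handles masked-out pixels and image borders without padding heuristics,
and the denominator (the "region size") uses the same fractional-coverage
kernel for self-consistency. Convolution is FFT-based and matches a
literal per-pixel weighted loop to <1e-8 (tested on 20 random 64×64
stacks). 100 μm approximates the oxygen diffusion limit; at the native
1.140625 μm/px sampling the radius is 87.67 px. Kernels below half a
pixel radius are rejected (the disk no longer covers its own centre);
0.5 px degenerates to the single-pixel identity kernel. The regional ORR
averages per-pixel ORR values (not a ratio of averaged intensities),
matching the stack-then-average order of the pipeline.

## Phasor FLIM

Per pixel, G and S are cosine/sine moments of the decay histogram at
ω = 2π·f_rep (harmonic 1; the repetition rate, not the observation
window). Times are bin centres; there is no instrument-response
deconvolution — a delta-function IRF is assumed, and a small
circle-offset tolerance (5e-3) absorbs discretization. Pixels with fewer
than 15 photons are dropped and G/S are median-filtered once with a 3×3
window before line fitting (shot-noise suppression). The two-species
model enters through a simple OLS line S = mG + c over the pixel cloud
(or over ROI means for group-level fits); its universal-circle
intersections give τ = S/(ωG) for the free and bound species, and each
pixel's α₂ is its orthogonal chord projection, clamped to [0, 1], with
τ_m = α₁τ₁ + α₂τ₂. An automated adequacy report (R² plus the fraction of
pixels far from the line) replaces visual inspection of the phasor cloud.

**Truncated-window bias.** The acquisition window is 256 × 0.0390625 ns =
10 ns, but an 80 MHz laser repeats every 12.5 ns; photons in the last
2.5 ns are unrecorded. Short lifetimes are unaffected (e^(−10/0.4) ≈ 0),
but the τ = 2.5 ns bound species loses ~2% of its photons, displacing its
phasor slightly off the universal circle. The net effect, verified
analytically and by simulation, is a ~3% low bias in recovered τ₂ and a
≤ +0.027 bias in α₂ near α₂ = 0.8; τ₁ and low/mid fractions are accurate
to <1%. Decay cubes sampled over the *full* period (320 bins) reproduce
the analytic single-exponential phasor to ~5e-5 on the circle residual,
which is how the analytic-limit check is run.

## Histograms, cutoffs, conditional distributions

All histograms are normalized to percent of counted pixels (sums to 100
exactly); out-of-range values are excluded and reported, or optionally
clipped into the end bins. The trivariate histogram stores per-bin counts
plus the mean of a third variable; its count-weighted mean equals the
global masked mean to 1e-9 (conservation). Cutoffs: median (default for
the zero-skewed regional stain fractions), mean, and Otsu (256-bin
maximum between-class variance; used for ORR splits). Values exactly at a
cutoff belong to neither class and are reported. Default binning: 50 bins
for ORR on [0, 1]; 25 per axis for regional percentages — the source
workflow does not pin bin widths, so these are configurable.

## Group statistics

χ² homogeneity operates on raw counts (percent scaling would invalidate
the sampling model); bins with expected counts <5 are pooled into their
smaller adjacent neighbour, recorded in the result, with df = k−1 after
pooling. Type-I error is calibrated: 5% ± 3 binomial SE at α = 0.05 over
1000 null simulations. OLS regression and the ANCOVA slope comparison
(group × covariate interaction F-test, overall and pairwise) delegate to
scipy/statsmodels; noise-free degenerate fits (zero residual in both
models) report p = 1 — no detectable slope difference. Holm–Bonferroni
uses the standard step-down rule; α = 0.05 throughout. Nested and
repeated-measures ANOVA are intentionally not reimplemented; the package
exports tidy tables instead.

## Synthetic sections: what they emulate

Spatial structure comes from thresholded Gaussian random fields (white
noise smoothed by a Gaussian kernel; periodic FFT boundary). Default
study conditions: 512×512 px at 1.140625 μm/px (whole-section analyses
use larger frames at the same sampling, emulating stitched mosaics);
correlation length 200 μm for stained foci (the inter-vessel scale over
which hypoxic territories form — the source data give no quantitative
covariance, so this is a generator parameter, not a data claim); two
subpopulations occupying exact in-tissue area fractions, 2.4%
pimo+/HIF+ (ORR 0.3) and 3.8% pimo−/HIF+ (ORR 0.7), against a 0.40
background — matching the printed group-level stain fractions of the
study system. Distinct focus types keep ≥100 μm clearance (hypoxic and
ROS/reoxygenation foci arise from opposite ends of the vascular supply).
Each focus's redox zone extends one diffusion length (100 μm) beyond its
stained boundary, so the metabolic signature survives 100 μm disk
averaging: every pixel inside a focus then has its full disk inside the
altered-redox zone. Within-region jitter is a zero-mean cellular-scale
(10 μm) field with σ = 0.02. Intensities satisfy
FAD/(NADH+FAD) = ORR exactly before noise; all noise is Poisson on
expected photon counts (budget 5000/px for intensity, configurable for
FLIM); decays are periodic two-exponential mixtures normalized to unit
window sum, so α₂ is an intensity fraction and total counts conserve the
photon budget. Everything is deterministic per seed via independent
`SeedSequence` streams.

The implanted-subpopulation check classifies regions by majority stain
coverage (fraction > 1/2) and compares their mean regional ORR against
stain-free regions (no stained pixel under the disk, ε = 1e-6 for FFT
round-off). This estimator reads the focus interiors — where the disk
average equals the implanted value — rather than the partially covered
fringe, and recovers the implanted 0.30 offset to within ~0.01 across
seeds. Otsu- or median-based selections include fringe pixels and
understate the contrast by design of the disk average, not by error.

What the generator does *not* emulate: histology texture, vascular
networks, stitching artifacts, stain bleed-through, detector saturation,
or IRF width. Passing tests therefore demonstrate correctness of the
*computation* under the stated statistical structure, not robustness to
every property of real tissue images.

## Problem sizes in the validation suite

The test suite and acceptance script scale inputs for desk-class
hardware, as a design choice: whole-section runs use 1536² px
(~1.75 mm)², FLIM recovery uses 48² px at 10⁴ photons/px (≥10⁶ photons
total, a 3×3 median filter and 15-photon floor as in the ROI workflow),
oracle comparisons use 20 random 64² stacks, and registration recovery
uses 100 random transforms with scale 0.8–1.25, rotation ±π, translation
±50 px. The statistical calibration uses 1000 null simulations of
two 400-count samples over 8 bins.
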