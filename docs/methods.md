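# Methods

## Frames, coordinates and units

A B-scan is a 2-D array of backscatter intensities in dB; row index is
axial depth (increasing downward), column index is lateral position.
Indices are 0-based. The default geometry matches the acquisition
protocol: a 5 × 5 mm scan with 256 A-lines (lateral pitch 5000/256 ≈
19.5 µm) and an in-tissue axial pixel size of 4.4 µm (enamel refractive
index 1.63; the axial pitch is already an in-tissue distance, so no
further index scaling is applied). Cropped regions of interest are
typically 225 × 100 pixels (≈ 4.4 × 0.44 mm). dB↔linear conversion uses
the power convention, `linear = 10^(dB/10)`: OCT intensity frames are
power-like, and linear-domain averaging of A-lines is what a spreadsheet
reproduction of the computation does.

## Segmentation

Background (air) is removed with a global threshold: pixels **at or
below** 5 dB become 0, which doubles as the background marker. A genuine
0 dB tissue pixel is therefore indistinguishable from background by
construction — a documented limitation of marker-in-band encoding. The
enamel surface in each A-scan is the first non-zero pixel; columns with no
tissue are excluded from every per-column average (they carry no A-line).

Zone labels come from the calibrated colormap (sound 10–16, Ie 16–28,
Ia 28–60 dB). Intervals are half-open `[lo, hi)` with Ia closed at the
top; two cases the printed ranges leave open are resolved as follows:
values above 60 dB are specular glare and are clamped into Ia (with a
logged count), and values between the 5 dB background threshold and the
10 dB sound floor are labeled sound, the only non-lesion tissue class. No
speckle filtering precedes segmentation: smoothing shifts zone boundaries
and biases the very intensities being classified.

Zone limits are per-A-line pixel counts from the surface row to the
deepest pixel of each zone, inclusive. With the lesion morphology this
produces, the Ia limit always sits at or above the Ie limit (the Ia zone
may be sandwiched inside Ie); this ordering is enforced as a test
invariant on clean simulated frames.

## Depth quantification

Two readings of the same limits:

* **Curved surface.** `D = mean(Δ) · Ps_axial · cos α`, where α is the
  median of the absolute per-pixel tangent angles of the surface. The
  cosine **multiplies** the axial run — it projects the axial pixel count
  onto the surface normal — which is the reading consistent with curved
  and aligned results being almost identical for nearly flat surfaces
  (cos α → 1). Tangent angles are estimated by least-squares lines over a
  centered 7-pixel window of the surface polyline in physical (µm)
  coordinates; the window size is a parameter. The median (not the mean)
  is used because the discrete surface produces a few grossly wrong
  per-pixel normals and the median ignores them. Angles enter the median
  as absolute values: the angle between the surface normal and the axial
  axis is naturally non-negative, and a signed median would cancel to zero
  on any symmetric surface, silently disabling the correction.
* **Aligned surface.** Every A-line is shifted up so all surfaces sit at
  the highest (smallest-index) surface row; vacated bottom rows are filled
  with the background marker. Integer shifts preserve per-column zone
  counts exactly, so for a flat surface the two readings coincide exactly.

The curvature index is the surface polyline arc length divided by its
lateral span (1.0 for a flat surface). Discretization of surface rows to
integers inflates it slightly (≈ +0.2–0.4 % at gentle slopes), which is
why geometry tests compare against quadrature with a 0.005 absolute
tolerance.

The average A-line profile averages linear intensities per depth row over
non-background pixels and converts back to dB; rows with no tissue are
NaN. Integrated reflectivity sums linear intensity from the surface down
to a caller-chosen depth (converted to whole pixels, at least one). The
integration bound is deliberately a parameter — the natural default is the
frame's own Ie lesion bottom (DlIe), which the `quantify` workflow can
supply — because no single bound suits all lesion stages.

The **manual oracle** re-implements the aligned-depth measurement the way
a spreadsheet user would (walk cells, classify by thresholds, count,
average, multiply by pixel size) with no code shared with the pipeline.
It is alignment-based only, so its curved and aligned outputs coincide.

## SEM segmentation and colormap calibration

SEM micrographs are normalized to their maximum and background-removed
with multi-level Otsu using **3 classes** (background / darker tissue /
brighter tissue — "multi-level" without a stated count; 3 is the smallest
count that separates background from a bimodal tissue). The demineralized
area (Ia ∪ Ie plus cracks) is the binarized top-hat residual of a
grayscale opening with a disk of 10 px diameter (radius-5 structuring
element); the residual is thresholded by Otsu on its positive values, or
kept wholesale when it is single-valued. The Ia zone is found by a
census over **non-overlapping** 10 × 10 tiles (a per-tile count reading of
"more than 25 pixels per kernel"): the target intensity interval is the
second-highest bin of a 10-bin histogram of tissue intensities (the
highest bin is the dominant sound population). The Ie zone is strong
Sobel edges — Otsu-binarized edge magnitude with connected components
under 30 px removed — intersected with the demineralized mask.
Composition precedence is Ia > Ie > sound > background, and per-column
interface rows are the last Ia and last Ie rows.

Calibration assumes registration is given. The OCT frame is resampled to
the SEM grid by nearest-neighbour replication. ROC curves are one-vs-rest:
Ia against all other tissue, Ie against sound only (Ia pixels sit above
the Ie band and would contaminate the negative class). The threshold sweep
is the union of a 0.1 dB grid and the observed values, so the trapezoid
AUC equals the Mann–Whitney pairwise-concordance statistic exactly while
the operating threshold lies on the grid whenever it falls in a gap;
distance ties at the nearest point are broken by the middle tied
threshold. Agreement percentages use the SEM zone area as denominator
(the SEM is the reference), and interface agreement uses a ±1 resampled
pixel band — exact row equality across modalities would make the reported
near-perfect interface agreement unreachable. Colormap selection maximizes
the mean of the two zone agreements, with interface agreement and then
candidate order as tie-breakers.

## Simulation

The mathematical A-scan is
`I1(z) = a·z·e^(−2µt1·z·S) + b·z·e^(−2µt2·z·S)`, with
`I(z) = I1(z)·(1 + M·1[z1 ≤ z ≤ z2])`. The z-factor uses the depth grid's
units (µm) consistently. Defaults: S = 0.125; a = 1, b = 1500,
µt1 = 0.034 µm⁻¹, µt2 = 0.2 µm⁻¹, M = 2 — chosen so the noiseless dB
profile spans the whole colormap: a ≈ 37 dB surface peak (Ia), decay
through the Ie band, and an 8–12 dB sound tail at the 440 µm bottom of a
100-sample grid starting one pixel below z = 0 (the model vanishes at
z = 0 exactly). Non-positive linear intensities map to the background
marker rather than −∞ dB.

Verification batches fix S = 0.125 and sweep M ∈ [1.5, 3.5],
z1 ∈ [120, 170] µm, z2 ∈ [240, 380] µm uniformly (seeded); the ranges
keep the Ie band inside the frame and give mean depths spanning roughly
115–160 µm (DIa) and 240–380 µm (DIe). Surface kinds cycle round-robin:
flat; cosine; a smoothed-random-walk stand-in for a profile taken from a
real B-scan; and piecewise-linear "freehand" control points. Batch
surfaces are gently curved (curvature index ≲ 1.02, median tangent angle
under ~12°), the regime in which curved and aligned depths are nearly
identical; steeper cosines reproducing the 1.07–1.09 curvature-index range
of real premolar samples are exercised separately in the geometry tests,
where the amplitude is solved by root-finding against quadrature.

Speckle: the residual of a 3 × 3 median or 5 × 5 edge-padded Wiener filter
can be extracted from a donor frame and re-injected; for fully
self-contained runs the default is a seeded Gaussian dB field (σ = 1.5 dB,
multiplicative in linear intensity, i.e. speckle-like) on tissue plus
sub-threshold uniform clutter (0–4.5 dB) in air. What this generator does
**not** emulate: coherent point-spread correlations (real speckle is
spatially correlated), angular-scattering loss on curved surfaces, depth
dependence of the noise, and genuinely sub-threshold surface signal. In
particular, air clutter never exceeds the 5 dB background threshold, so
surface detection on simulated frames is exact; passing tests therefore
demonstrate correctness of the measurement chain, not robustness of
surface detection to heavy surface noise. With injected speckle the
deepest-pixel zone limits are biased a few pixels deeper than the
noiseless truth (occasional deep outliers cross a zone floor), which is
why ground-truth recovery is asserted on noiseless frames only, while
algorithm-vs-oracle comparisons (both paths see the same noisy frame) hold
with or without speckle.

## Verification statistics

Trendline R² is the coefficient of determination of the OLS line of y on
x (equal to squared Pearson r in simple regression); it is undefined for
fewer than 3 points or zero x-variance, and batch summaries record NaN in
that case rather than failing. Batch processing skips and flags failing
frames instead of aborting. The acceptance script uses 23- and 12-frame
batches at 225 A-lines — the pipeline processes a frame in well under a
second, so these sizes run essentially instantly while matching the
verification design.

## Known limitations

* Registration of OCT/SEM pairs must be supplied; there is no automatic
  multimodal registration, and no confidence intervals on AUC.
* The background marker conflates 0 dB tissue with air.
* Strongly curved surfaces (beyond the slightly-curved regime) would need
  angular rescanning hardware and are out of scope; the cos α correction
  assumes one representative median angle per frame.
* 3-D C-scan volumes, proprietary binary formats and deep-learning
  extensions are out of scope.
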