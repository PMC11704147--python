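# Methods

`octavasc` implements a label-free OCT-angiography (OCT-A) analysis chain
for detecting persistent microvascular dilation in mouse cortex after
low-intensity focused ultrasound (FUS), exercised end to end on synthetic
3D vascular phantoms with exact ground truth. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Angiogram model

Flow contrast is the inter-frame amplitude decorrelation of repeated
B-scans. With N repeats and M spectral bands,

    D = 1 − (1/(N−1)) (1/M) Σₙ Σₘ Aₘₙ Aₘ,ₙ₊₁ / ((Aₘₙ² + Aₘ,ₙ₊₁²)/2),

so D ∈ [0, 1], D = 0 for static speckle and D → 1 for fully decorrelated
(flowing) voxels. Zero-amplitude pairs are defined as D = 0 rather than
0/0. D is invariant to global amplitude scaling and, for N = 2, to frame
order.

Frames are first registered by phase correlation with 1/100-pixel
upsampling. When only amplitude images exist (no raw spectral
interferograms), the split-spectrum decomposition is synthesized by
Gaussian windows on the positive half of each frame's axial Fourier
spectrum; the inverse transform of a one-sided band is an analytic signal
whose magnitude is the band's amplitude envelope — a reduced-axial-
resolution image, as a true sub-band reconstruction would give. Defaults:
N = 4 repeats, M = 4 bands, 50 % overlap; none of these are reported by
typical system descriptions, so they are exposed as parameters.

## Surface referencing

The cortical surface is neither flat nor perpendicular to the beam, so all
depths are referenced to a fitted surface plane. Detection: axial Gaussian
smoothing, then a global threshold (Otsu computed after clipping the
volume at its 90th percentile — clipping suppresses the bright vessel
class so the two-class split falls between dark above-surface voxels and
tissue), then the first supra-threshold index per A-line, median-filtered,
with gaps filled by 2D median interpolation; an error is raised if more
than half the columns have no surface. De-tilting fits a least-squares
plane and resamples every A-line (linear interpolation) so the plane maps
to a constant index; depth thereafter means "µm below the cortical
surface" with half-open bins [lo, hi). Axial binning covers 0–400 µm;
25-µm analysis bins aggregate to 50-µm reporting bins.

## Segmentation and branch graph

Segmentation operates on en-face maximum projections. Two white top-hat
channels are thresholded and unioned: a fine 6.7-µm window for capillary-
scale background suppression and a coarse 60-µm window that retains
vessels wider than the fine element (a single 6.7-µm top-hat suppresses
the interior of any vessel much wider than the window). Thresholding is
Otsu with a guard floor of 0.3 × the image's 99.9th percentile: on sparse
scenes a plain Otsu collapses into the speckle bulk, and because the floor
is relative, branch counts are invariant under intensity rescaling.
Objects smaller than a 5-µm disk are removed; pinholes smaller than 5 px
are filled.

The mask is skeletonized and converted into a branch graph. Adjacent
junction pixels are merged into one topological node (junction cliques);
end spurs shorter than the 10-µm prune length are deleted at graph level
and degree-2 nodes are dissolved by concatenating their incident paths, so
a pruned spur re-merges the branch it interrupted. Branches are
junction-to-junction or junction-to-end paths; fragments shorter than the
prune length are dropped as unmeasurable.

Classes follow the baseline diameter with half-open edges: "<15" (d < 15),
"15-20" (15 ≤ d < 20), ">20" (d ≥ 20); branches measuring below the 5-µm
inclusion floor (the lateral-resolution limit) are excluded entirely.

## Diametry

A branch's diameter is the mean full width at half maximum
(FWHM = 2√(2 ln 2) σ) of Gaussian-plus-offset fits to intensity profiles
sampled perpendicular to the smoothed centerline: 5-µm section spacing
(~15 sections on the smallest measurable branches), line length
max(4 × width estimate, 20 µm), bilinear sampling at 1-µm steps.

Two numerical points matter:

* **Projector choice.** Profiles are read from a narrow *mean* projection
  centred at the branch's own depth (half-window max(0.75 d, 6 µm)), not
  from the global max projection. A max projection takes, at each lateral
  offset, the maximum of many speckle draws; the center of a wide vessel
  offers more draws near its peak than the flanks, so extreme-value
  statistics sharpen wide profiles (≈ −5 % at 15–20 µm — enough to leak
  arterioles into the capillary class). The mean projector is
  width-unbiased, averages speckle, and excludes crossing vessels at other
  depths. Branch depth is attributed first (median axial argmax along the
  centerline).
* **Sampling-kernel correction.** Reading a profile off a 2-µm grid
  through bilinear interpolation convolves it with a kernel of known
  variance (≈ Δ²/12 for gridding plus ≈ Δ²/12 for interpolation, plus the
  1-µm step's Δ²/12). This variance is subtracted from the fitted σ in
  quadrature. It is a discretization correction with no free parameter —
  not a PSF deconvolution, which the pipeline deliberately does not do:
  diameters are reported as measured FWHM, and sub-resolution widths are
  handled by the 5-µm floor instead.

A fit is accepted iff R² ≥ 0.5, amplitude > 0, the center lies in the
middle half of the line, and the FWHM is at most ¾ of the line length (a
width comparable to the sampling window is untrustworthy). A branch needs
at least 3 accepted sections and ≥ 50 % acceptance; otherwise it is
flagged unmeasurable. On noiseless Gaussians the estimator is unbiased to
< 1 % across σ ∈ [1.5, 25] µm.

## Longitudinal tracking

Timepoints (pre, 1 min post dose 1, 10 min post dose 1, 10 min post dose
2) are co-registered by phase correlation (translation only — a
head-fixed cranial window drifts but does not rotate); a correlation
confidence below 0.05 falls back to the identity shift with a warning.
Branch matching is geometric: greedy one-to-one assignment maximizing the
fraction of baseline centerline points within tolerance of a candidate's
centerline (minimum 50 % overlap), with the tolerance widened to a quarter
of the baseline width (floored at 5 µm) because the medial axis of a wide
vessel jitters with mask-edge noise. Matching is diameter-blind so dilated
vessels keep their identity, except that a pair differing by more than a
factor 2 is rejected as a crossing-vessel confusion. A second pass lets a
leftover baseline fragment share an already-claimed later branch, since
the baseline skeleton can fragment more finely than a later one.

Normalized diameter = diameter(t) / diameter(pre); class labels are frozen
at baseline so a dilating 14-µm vessel does not migrate classes
mid-study. The unit of analysis is the animal: branch ratios are averaged
per animal, then group statistics run on per-animal means. Branches
unmatched at one timepoint are analyzed where present (a complete-case
mode exists).

## Statistics

* Paired two-tailed Student's t on per-animal means, computed from first
  principles (t = mean difference over its standard error, n−1 df);
  zero-variance differences report NA.
* Two-way ANOVA (condition × timepoint, with interaction) on per-animal
  normalized diameters via OLS, followed by Fisher's LSD in its classical
  form: unadjusted pairwise t tests using the pooled residual mean square
  and residual df. LSD is deliberately unadjusted; no further
  multiple-testing correction is applied.
* Mann–Whitney–Wilcoxon on depth-binned branch diameter distributions
  (branches, not animals, as units), exact for combined n ≤ 20 and
  normal-approximated with tie correction otherwise; bins with fewer than
  3 branches on a side report counts but an NA p value.
* The summary table mixes conventions deliberately: the baseline-diameter
  column summarizes across branches (hence large SDs for pooled classes),
  while normalized columns summarize across animals.

## Synthetic phantom

The phantom emulates a 600 × 600 × 400 µm cortical block at 2-µm isotropic
pitch (a reduced desk-scale version of a 1 × 1 mm field): a tilted surface
(default 2°), dark space above, weakly decorrelating tissue (level 0.12),
and tubular vessels rendered with a radially Gaussian decorrelation
profile whose FWHM equals the true diameter (peak 0.6), *added* onto the
tissue floor so a lateral cut is exactly Gaussian-plus-offset. Speckle is
multiplicative unit-mean lognormal (CV 0.2, a configurable stand-in for
Rayleigh-like speckle); multiple-scattering "tails" decay exponentially
below each vessel (strength 0.3, 30-µm decay) and never exceed the parent
intensity.

Per animal: 24 capillary-class, 3 arteriole-class and 3 large vessels with
gently curved centerlines 90–260 µm long, stratified in depth (large
vessels weighted toward the surface). Capillary truth diameters are drawn
from a lognormal calibrated so the measurable [5, 15) µm window has mean
6.2 µm and SD 1.3 µm: those moments describe a *post-inclusion-floor*
population, and no untruncated lognormal reproduces them after the floor
(truncation alone raises a mean-6.2 parent to ≈ 6.56). The price is a
floor-dominated shape rather than a clean mode at 6–8 µm; the 5-µm-binned
histogram still peaks in the 5–10 µm bin with a long tail past 40 µm.

Dilation studies scale each branch's diameter by its class × timepoint
factor times an animal-level perturbation (SD = inter-animal SD of the
effect; 1 W/cm²: 1.17/1.23/1.27 ± 0.03 on the capillary class, 10 W/cm²:
1.27/1.30/1.32 ± 0.08, sham: 1.0 ± 0.01 — the group trajectories of the
two dose conditions), with geometry held fixed, fresh speckle per
acquisition, and ≤ 5 µm rigid lateral drift between timepoints. Seeds
split per animal and stage through `SeedSequence([root, animal, stage])`,
so adding animals never perturbs earlier ones; same seed ⇒ byte-identical
volumes.

A branch-table-level fast path (`simulate_track_table`) skips imaging for
statistical calibration. Its measurement error is split into a
branch-persistent component (CV 0.04 — geometry-linked biases that repeat
at every timepoint and cancel in normalized diameters, as in the imaging
pipeline) and an independent per-measurement component (CV 0.03); with all
error independent, the ratio-mean bias (≈ CV²) would inflate the paired-t
type-I rate.

### What the phantom does not emulate

No bifurcation-order realism or connected trees — branches are independent
tubes, so junctions arise only from incidental crossings. No flow-velocity
or RBC-flux contrast, no acoustic field, no pulsatility, no non-rigid
tissue motion, no real OCT PSF (resolution effects enter only through the
voxel grid). Passing tests therefore show that the *measurement chain*
recovers known geometry and effects under speckle, tilt, drift and
projection tails — not that it would survive every artifact of in-vivo
data.

## Validation outcomes the package computes

`tests/test_acceptance.py` re-derives, from full simulated studies: the
17 % and 27 % capillary dilation recoveries (±3 / ±4 points), null
preservation on unaffected classes and sham (±0.03), the 6.2 ± 0.5 µm
baseline capillary mean, analytic FWHM identities, decorrelation
identities, agreement of every statistical routine with independent
references or enumeration, paired-t type-I calibration (5 % ± 2.5 % over
200 sham studies), ≥ 90 % vessel-level tracking across all four
timepoints, and sub-µm registration recovery.
`scripts/acceptance.py` recomputes the two headline numbers (group percent
dilation at 1 min post dose 1; baseline capillary mean) from scratch at a
caller-chosen seed.

## Known limitations

Branch fragments below 3 accepted cross-sections are discarded, biasing
against very short inter-junction segments. Depth attribution uses the
axial intensity argmax and can be pulled deeper by projection tails (no
tail correction is attempted). Arterioles near the 15-µm class edge can
migrate classes through measurement noise, slightly inflating the
capillary-class mean. The matching second pass can attach two baseline
fragments to one later branch, duplicating that branch's diameter in two
tracks. Mann–Whitney depth comparisons count a vessel once per depth bin
it appears in.
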