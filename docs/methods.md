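# Methods

This note documents the models, parameter choices and numerical decisions
behind `octavg`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic validation does and does
not establish.

## Coordinate and scale conventions

All images are 0-based `(row, col)` arrays with row 0 at top; boxes are
half-open `[r0, r1) × [c0, c1)`. The native en-face sampling is 30.4
px/degree (304 px over 10°). Physical scale uses a nominal 291 µm/degree
for a 24 mm eye, scaled linearly by `axial_length_mm / 24` (a simple
Bennett-style magnification correction; more elaborate schemes exist, but
for the metrics here only the linear factor matters and it is explicit and
overridable). Defaults give 9.57 µm/px, and 1.595 µm/px after the 6×
upsampling used by quantification.

## Synthetic scene generator

The generator emulates the anatomy the pipeline targets: near-parallel
capillaries at mean centre-to-centre spacing `true_icd_um` (default 38 µm,
the middle of the histologic 30–40 µm range; parallel geometry then implies
a length density of ~26–28 mm⁻¹ and an area coverage of ~24 % at 9 µm
diameter — both in the physiologic range), with per-vessel spacing jitter
(default 10 %), gentle sinusoidal tortuosity (5 µm amplitude over a 300 µm
wavelength) and sparse perpendicular anastomoses (Poisson, 0.1 expected
links per adjacent pair). Centrelines are rasterised at quarter-pixel
steps; the central vessel is anchored on a pixel centre so that
axis-aligned, jitter-free scenes rasterise at exact integer spacing. The
noise-free image convolves the centreline map with a Gaussian cross-section
of FWHM `true_diameter_um` (9 µm — sub-pixel at native sampling, which is
why a hard-disk profile would be unrepresentable) and normalises to [0, 1].

Ground-truth density is measured on the rasterised centreline map with the
same step-length metric used throughout (1 per orthogonal step, √2 per
diagonal, diagonal shortcuts across staircase corners suppressed). This is
deliberate: 8-connected rasterisation of an oblique continuous curve
overestimates its arc length by up to ~8 %, so defining truth on the raster
keeps "truth" and "measurement" on the same footing — which is also how
skeleton-based density is defined on real data.

Acquisition noise is phenomenological, not a physical decorrelation model
(no public noise characterisation exists for the device output): per-frame
multiplicative speckle `Normal(1, 0.3)` clipped at zero, additive
background `Normal(0, 0.05)`, and with probability 0.01 per row a
motion-artifact line (whole row brightened or attenuated; a config flag
extends this to columns or both axes). Magnitudes were calibrated once,
qualitatively — single frames visibly noisy and fragmented, 10-frame
averages smooth — and are config-exposed. Frames are misaligned by rigid
transforms drawn uniformly within ±3 px and ±1°; frame 0 is the
untransformed reference. All randomness derives from
`SeedSequence([seed, stream, frame_index])`, so identical configurations
reproduce bit-identically and every frame has an independent sub-stream.

One consequence of clipping intensities to [0, 1]: the expectation of a
noisy frame is *not* the clean render at bright pixels (speckle above 1 is
clipped, biasing the mean down by up to ~0.12 at intensity 1). Averaging
many frames therefore converges to the clipped expectation; tests of the
law-of-large-numbers behaviour restrict to pixels below 0.4 where the clip
is inactive.

## Registration

Same-device, same-session scans justify a rigid model (translation +
rotation, no scale). Estimation minimises the phase-correlation residual
over a coarse (0.5°) then fine (0.1°) angle grid with a final parabolic
refinement, and reads the subpixel translation off upsampled phase
correlation at the best angle; images are Hann-windowed so borders and
rotation fill do not dominate the spectrum. On synthetic stacks at speckle
0.3 the residual against the generating transforms is ~0.05 px and ~0.05°,
comfortably inside the binding contract of 0.5 px / 0.2°.

Resampling is bicubic. Out-of-field pixels are marked invalid rather than
zero-filled, and validity is additionally eroded by the 2-px bicubic
support so that no "valid" pixel is contaminated by constant fill; any ROI
whose contributing frames contain an invalid pixel is excluded outright,
so averaging is never biased by border fill. The reference frame is chosen
automatically as the frame maximising (intensity IQR) − (fraction of
rows/columns whose mean deviates > 3 SD), a stated, reproducible proxy for
"highest contrast, least motion artifact"; ties break to the lowest index.
Non-rigid refinement is out of scope, but `register_stack` exposes a
`post_hook` so a deformable stage can be chained after the rigid one, and
`transfer_transforms` supports estimating on a high-contrast stack (e.g. a
deeper slab with large vessels) and applying to a low-contrast one.

## ROI geometry

The disc margin is delineated manually (clicked points, CSV) and fitted
with a direct least-squares ellipse (scikit-image's estimator), normalised
to `a ≥ b` with the RMS point residual reported. Five 60×60 px ROIs are
placed along radial directions (for a right eye: superior 90°,
superotemporal 45°, temporal 0°, inferotemporal −45°, inferior −90°;
mirrored horizontally for a left eye) at a centre distance of
(boundary radius + 1° + half box side), i.e. one degree of clearance
between the disc margin and the ROI's near edge. The phrase "centred ~1°
from the margin" is genuinely ambiguous between edge- and
centre-clearance; edge-clearance was chosen (it keeps the ROI clear of the
peripapillary annulus) and per-label manual pixel offsets absorb the "~"
— they also stand in for the manual dodging of major vessels and of
arterial capillary-free zones, which is not automated. Boxes extending
off-image are flagged excluded, not silently dropped. Vessel orientation
within each ROI is radial by construction and overridable — the synthetic
full-field pipeline overrides it with the scene's global orientation,
since the generator draws one parallel family rather than a radial fan
(a knowingly non-emulated feature of real anatomy).

The ICD sampling box is 0.1×1° (3×30 px), centred in the ROI, long axis
perpendicular to the vessel orientation, interpreted at native (not
upsampled) resolution; its ~2-capillary-diameter width averages away any
perpendicular crossings. Oblique boxes sample by bilinear interpolation in
1-px steps.

## Quantification

Per ROI and frame count n (reference first, then acquisition order):

1. **Average** the first n registered frames pixelwise over the ROI box.
2. **Binarise**: 6× bicubic upsample (60→360 px), linear contrast stretch
   mapping the 1st/99th percentiles to 0/1, adaptive threshold against a
   51-px Gaussian-weighted local mean with zero offset (the window is the
   nearest odd size to the nominal 50 px). The stretch percentiles,
   window, and offset are unknowable choices of the original operators;
   they are config-exposed and validation tests recovery of known truth
   rather than operator agreement. A constant ROI binarises to empty
   foreground with a warning.
3. **Skeletonise** (topology-preserving thinning). Endpoints are skeleton
   pixels with ≤ 1 eight-neighbour (isolated pixels count); branch pixels
   have ≥ 3 and are clustered 8-connectedly so a thick junction counts
   once; segments are the connected components left after deleting branch
   pixels. Skeleton length uses geometric steps (1 / √2) with staircase
   diagonal shortcuts suppressed — "pixel count" length is available as a
   config switch but geometric length is the default since density is
   reported in physical units.
4. **SNR**: the vessel mask is built once per ROI from the 10-frame
   average (skeleton dilated with a disk of the nearest odd pixel diameter
   to 15 µm → 9 px at defaults) and applied to the upsampled average at
   every n; population SDs (sample SDs differ by < 0.1 % at these pixel
   counts). SNR is invariant to the linear stretch, so it is computed on
   the unstretched resample. Endpoint/segment metrics use per-n
   skeletonisation (the per-n skeletons are what fragmentation is measured
   on); only the SNR mask is frozen at n = 10.
5. **ICD**: min–max-normalised profile, peaks with prominence ≥ 0.1 and
   separation ≥ 2 px, ICD = mean successive peak distance × µm/px. Fewer
   than two peaks flags the ROI unmeasurable — never silently zero.

## Statistics

Metric tables pivot to subjects × frame-counts per (metric, region), with
listwise deletion of subjects having any excluded cell. The one-way
repeated-measures ANOVA uses the standard subject/condition/error
decomposition; the Greenhouse–Geisser epsilon comes from the
double-centred sample covariance (trace form), clamped to
[1/(k−1), 1], with ε = 1 exactly at two levels; F is tested on
((k−1)ε, (n−1)(k−1)ε) degrees of freedom. The implementation is validated
to 1e−8 against an independently coded loop/eigenvalue oracle and against
`pingouin.rm_anova`.

Post hoc testing is paired two-sided t-tests on the nine *sequential*
pairs with Bonferroni m = 9 (all-pairs, m = 45, is available behind a
flag); a zero-variance pair gets p ∈ {0, 1} by whether the means differ
and is flagged. The optimal frame count is the smallest n such that every
sequential comparison from (n, n+1) onward is non-significant: 1 if
nothing is significant, 10 if the last pair is. Percent differences
(reference → averaged) default to the percent difference of
across-subject means; mean-of-per-subject-ratios is a config switch, as
the two are not distinguishable from published summaries. The normative
comparison reports each case value's empirical quantile among ≥ 5 controls
and flags values below the box-plot lower whisker (lowest control datum
inside Q1 − 1.5 IQR) and below the control minimum.

## What the synthetic validation shows — and what it does not

On synthetic cohorts the pipeline reproduces the qualitative frame-count
behaviour expected of averaging: SNR rises monotonically (on average) and
saturates; endpoints drop by roughly half from n = 1 to n = 10; segments
fuse and lengthen; ICD is frame-count-invariant with an optimal count of
1; density is comparatively stable. Registration, density and ICD recover
ground truth within their stated tolerances (0.5 px / 0.2°, 10 %, 10 %).

The synthetic noise is not device noise. In particular, real single-frame
angiograms *lose* vessel segments to decorrelation dropout, which is why
measured density rises ~11 % with averaging on patient data; the synthetic
speckle model adds spurious foreground rather than deleting vessels, so
synthetic density stays flat or drifts slightly negative, and the
synthetic SNR gain (~25–30 %) is smaller than the ~44 % reported on real
eyes. Matching the *direction and ordering* of effects, with exact
recovery of known geometry, is what these simulations establish; absolute
effect sizes on patient data are not derivable from them. Likewise the
generator draws one parallel capillary family per field rather than a
radial fan, has no large vessels, no capillary-free zones and no deep
plexus, so ROI-placement edge cases driven by those structures are
exercised only through the manual-offset/exclusion machinery.

## Problem sizes

The default test suite and the acceptance script use scaled-down cohorts
chosen as sufficient for their assertions: 20-seed trend ensembles on
80×80 px fields, 6-subject full-field (304×304) pipeline runs, 22×10
matrices for the statistics (1000 replicates for the type-I check). All
seeds are fixed; everything regenerates from code at run time.
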