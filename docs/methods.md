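# Methods

This note documents the models, parameters and numerical choices behind
octstent, and what the synthetic validation does and does not show.

## Image model and coordinate conventions

A pullback is an ordered stack of cross-sectional greyscale frames
(intensities 0–255) with two lengths attached: the in-plane pixel size
(μm/px, default 13) and the inter-frame spacing (μm, default 100).
Pixel indices are 0-based. Polar resampling uses bilinear
interpolation on rays from the catheter axis; θ is in degrees in
[0, 360), counter-clockwise from +x with y pointing up (decreasing image
row), one bin per degree by default (n_theta = 360, so the 50° gap
threshold spans 50 bins). Lengths are μm internally; areas are
reported in mm² and volumes in mm³.

The polar origin is the centroid of the detected catheter mask, falling
back to the image centre when no catheter is found. The catheter is
detected on the cross-frame mean image: moving structures average out
while the catheter, fixed in the frame, survives as the brightest
region; the mask is the connected component above the 0.99 intensity
quantile that contains the global maximum. This works when the catheter
occupies well under 1% of the frame, which holds for typical geometries.

## Lumen border detection

1. Otsu binarization, morphological opening (disk, radius 3 px), and
   removal of connected components below 30 px². The opening radius
   matches the scale of salt-and-pepper speckle; the area threshold is
   small enough to keep thin wall sections.
2. Per A-scan, the border candidate is the smallest r with non-zero
   Sobel response along r. For a crisp 0→1 transition between rows
   b−1 and b the 3-tap Sobel first responds at b−1 while the sub-pixel
   edge sits at b−0.5, so 0.5 px is added — without this the detected
   radius is biased low by half a pixel, which already matters at the
   1% level for a 1.5 mm lumen sampled at 13 μm/px.
3. Tracking: candidates farther than ±5 px (half of the 10-px validity
   width) from the previous frame's border are discarded; the first
   frame is accepted as-is.
4. Gap filling: circular runs of missing bins ≤ 50° are closed by
   circular linear interpolation and the contour is smoothed with a
   circular moving average spanning 5% of the bins. Gaps > 50° are
   filled from the previous contour, the heavier 10% span is applied to
   blend the seam, and the frame is flagged as containing a bifurcation
   ostium. Interpolation precedes smoothing; the small-gap span (5%)
   is a free choice kept below the wide-gap span, which is fixed at 10%.
   Missing bins are explicit NaNs, never radius 0.

Lumen area is the shoelace area of the 360-vertex polygon (the polygon
chord error at 1°/bin is < 0.01%); the centroid is the polygon (area)
centroid. Volume is Σ area × spacing.

## Strut detection

Struts are found by their bloom-plus-shadow signature on the unweighted
polar frame. For each run of pixels strictly above the frame's 90th
intensity percentile, the run peak is connected to the 30th following
pixel below the frame median — counting low pixels, not offset rows,
with zero padding past the scan end (a config switch selects the simpler
fixed-offset reading) — and the run is kept when the slope is strictly
below −1.5 intensity/px. The strictness of both comparisons is
deliberate and pinned by tests (a slope of exactly −1.5 is rejected).

The discriminative power of this test comes from depth attenuation: in a
wall-only A-scan the signal decays gradually, so the 30th below-median
pixel is far from the peak and the slope is shallow; behind a metallic
strut the shadow makes it immediate. Two suppression stages follow:

- **Triangular window** centred on the frame's lumen border (apex 1,
  linear to 0 at ±40 px ≈ 0.5 mm, chosen to exceed plausible
  malapposition distances): candidate pixels whose windowed intensity
  does not exceed the percentile threshold are culled, removing
  far-field structures such as the outer wall. A relative trim keeping
  pixels above 0.8 of the run peak isolates the saturated bloom from
  the contiguous decaying wall signal; without it the centroid is
  dragged several pixels outward. Detection-then-windowing is the
  default order; the reverse is available as a config switch but makes
  the slope statistics degenerate on the window's zeroed support.
- **Cross-frame confirmation**: a candidate must have a neighbour within
  θ ≤ 10° and r ≤ 15 px on at least one of the ±5 surrounding frames
  (union of neighbourhoods, not track gating); stack ends use the
  neighbours that exist. This removes single-frame artefacts such as
  guide-wire reflections.

Surviving pixels are merged 8-connectively with θ wrap-around; the
intensity-weighted centre of mass (circular mean in θ) gives the strut
position, and LOA = centroid radius − border radius at that θ (positive
outside the border).

## Point clouds and registration

Frames are stacked orthogonal to a straight pullback axis at
z = frame × spacing, each frame translated so its lumen centroid lies on
the axis. Recentring removes catheter wobble but also any true vessel
curvature — appropriate for straight-tube phantoms and switchable off
for in vivo pullbacks.

ICP is point-to-point: nearest neighbours via a k-d tree, closed-form
SVD (Kabsch) update, iterated until the RMS distance changes by less
than 10⁻³ μm or 100 iterations. No outlier trimming is applied by
default (distance distributions are reported raw). The sweep
initialization aligns barycentres, pre-rotates about z through the
barycentre in 1° steps over 0–360°, and keeps the result with the
smallest sum of squared distances — necessary because a tubular stent
is nearly rotation-symmetric and single-start ICP reliably finds local
minima under large axial rotations. Distances are computed moving →
fixed (OCT cloud → reference); "radial" is the difference of the two
matched points' distances from the z axis, isolating strut-to-axis error
from axial/angular mismatch.

## Validation metrics

Similarity indexes are computed from pixel confusion counts in percent;
an index with a zero denominator is NaN, never 0. For lumen masks the
comparison uses filled regions (the area inside the contour): true
negatives over 1-px border curves are ill-defined, and a border-band
variant is available (`contour_to_mask(..., border_band=n)`). The
strut-count specificity (1 − FP/n_strut)·100 is unbounded below and
reported as-is. Strut matching is greedy nearest-neighbour with a
150 μm gate (≈ strut width plus localization error; the gate is a free
parameter). Bland–Altman uses arithmetic differences with
mean ± 1.96·sample SD, plus a percentage-difference variant used for
paired areas. Percentiles follow the Hazen (midpoint) plotting
position — the convention under which the repeated-pullback volume
quartiles (358.51 / 360.41 / 365.56 mm³ from seven scans) reproduce
exactly; the corresponding struts-per-frame quartiles reproduce to
±0.02 because the tabulated means are rounded to 2 d.p.

## The synthetic phantom

The generator renders, in Cartesian coordinates: a dark lumen; a wall
whose intensity starts at 180 grey levels at the border and decays
exponentially with depth (attenuation length 500 μm) toward a dim
floor — the minimal contrast model that gives wall A-scans the gradual
decay the slope test discriminates against; struts as saturated disks
(radius 2 px) whose radial wedge behind them is attenuated ×0.1 (the
trail shadow); a constant-intensity catheter disk fixed across frames; a
fixed overlay pixel pattern at a sentinel intensity; optional
bifurcation ostia as angular wall gaps over a frame interval; and
additive Gaussian noise (σ = 8 grey levels) clipped to [0, 255], all
behind one seed (same seed ⇒ bit-identical stacks). Default geometry:
540 frames, 100 μm spacing, 13 μm/px, 512² frames. The default stent
layout is helical (rings of 10 struts advancing 3°/frame), matching real
stent geometry and keeping any one pixel strut-free in most frames.

What the phantom does **not** model: physical speckle statistics,
tissue layering, bioresorbable (shadow-less polymer) struts, vessel
curvature, cardiac-motion artefacts, or eccentric catheter wobble.
Passing synthetic tests therefore demonstrates the correctness of the
algorithmic chain and its noise robustness at the stated contrast, not
clinical-grade performance on in vivo pullbacks.

## Validation problem sizes

The acceptance script and end-to-end tests use: a noise-free 100-frame
cylinder (R = 1.5 mm, 512² frames) for analytic area/volume recovery; a
40-frame noisy stented pullback (400 rendered struts) for detection
rates; 12-frame stacks with 60° and 30° ostia for the gap rule; a
500-point helical cloud rotated 120° and translated (300, −200, 150) μm
for registration; and 10⁴ Monte-Carlo pairs for the Bland–Altman check.

## Known limitations

- The first frame's border is accepted from the Sobel stage without a
  validity region; a heavily corrupted first frame can mis-seed tracking
  for several frames.
- Strut detection assumes metallic struts; polymer scaffolds cast no
  shadow and are not detected.
- The straight-centerline assumption makes the 3D reconstruction of a
  curved vessel a straightened representation; registration metrics to
  an undistorted reference then mix true error with curvature.
- Greedy strut matching is not globally optimal for pathological
  configurations of near-equidistant struts (the tests pin equality
  with exhaustive assignment only for separated configurations).
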