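# Methods

## Model of the image

The pipeline assumes bright-field micrographs of Alexander-stained
pollen: dark grains on a light, roughly uniform background, acquired
with contrast set so that viable (dark purple) and non-viable (pale
turquoise) grains are visually separable. Channel semantics follow the
stain chemistry — malachite green (all pollen walls) absorbs in the red
channel, acid fuchsin (viable protoplasm) in the green channel — so the
red channel yields the total-grain count and the green channel the
viable-grain count. The raw channel planes are used directly; no
color-space transform or stain deconvolution is applied, and no
contrast adjustment is performed inside the pipeline (an optional
linear-rescale hook exists but is off by default, since contrast is
assumed to be set at acquisition).

## Segmentation

**Thresholding.** The default method is isodata on the 256-bin
histogram. The implementation scans thresholds upward from the darkest
occupied bin and returns the first *T* at which the half-up-rounded
class-mean average round((μ_≤T + μ_>T)/2) no longer exceeds *T*; since
that update map is non-decreasing in *T*, this is the smallest integer
fixed point *T* = round((μ_≤T + μ_>T)/2). Choosing the smallest fixed
point is deliberate: when dark grains occupy a tiny fraction of the
pixels, the histogram is dominated by the background mode and larger
fixed points degenerate into a split of the background noise, while the
smallest one still separates grains from background. Otsu and a fixed
user threshold are available as alternatives. Binarization uses
dark-on-light polarity: foreground = intensity ≤ *T* (inclusive).

**Degenerate channels.** A constant channel raises an error (the
threshold is undefined). A noisy but grain-free channel would otherwise
be split down the middle of its noise distribution, so the pipeline
applies a bimodality guard: if the mean intensities below and above the
automatic threshold differ by less than `min_contrast` (default 25
intensity units), the channel is reported as containing no detectable
particles. The default palette puts grains ≥ 40 units below background,
so any real detection clears the guard by a wide margin; a fixed
threshold bypasses it.

**Morphology.** Dilate (k iterations) → fill holes → erode (k
iterations), with k = 1 and a 3×3 square structuring element by
default, mirroring common ImageJ binary-operation conventions.
Foreground is 8-connected; hole filling treats background as
4-connected so diagonal gaps do not leak. Erosion uses border padding
so edge-touching particles are not eaten from the image boundary.
Edge-touching particles are retained by default (`exclude_edges` flag
available).

**Watershed.** The Euclidean distance transform of the solid mask is
computed; its regional maxima are the "ultimate eroded points" that
seed the watershed of the negated distance map, restricted to the
foreground, with one-pixel watershed lines assigned to background so
split particles are disjoint. Maxima closer than `maxima_merge_radius`
(default 4 px) are merged to keep mildly elliptical grains from being
split in two. Splitting never merges: every connected component
receives at least one label. The watershed can be disabled for
sensitivity analysis.

## Particle filtering

Particles are measured with connected-region properties: area = pixel
count, perimeter via the weighted boundary-step estimator (less biased
for small rasterized particles than naive edge counting), circularity =
min(1, 4πA/P²) so a perfect disk scores 1, centroid in pixel
coordinates. Defaults: red channel keeps areas 60–800 px², green
100–800 px², both channels circularity 0.40–1.00, all bounds inclusive
(the published ranges say "between"; endpoint membership is declared
here for determinism). The higher green floor exists because small
acid-fuchsin-stained "balloon" structures — protoplasm released through
intine rupture during staining — appear only in the green channel at
areas below ~100 px² and would otherwise inflate viable counts.
Circularity is defined as 4πA/P²; a min/max-diameter ratio is a
conceivable alternative reading of "calculated from diameter data", but
the isoperimetric form is the standard particle-analysis descriptor and
is used throughout.

## Viability statistics

- APV_img (%) = 100·G/R, where G and R are the green- and red-channel
  counts. R = 0 raises an undefined-viability error (distinct from
  zero viability). Values above 100% indicate a segmentation fault and
  are reported uncapped with a warning rather than clamped, so faults
  surface instead of hiding.
- MPV_img (%) = 100·(dark-stained grains)/(all grains), for manual
  reference counts.
- Sample APV (%) = 100·ΣG/ΣR pooled over a sample's images. This
  count-weighted ratio always lies between the per-image extremes but
  differs from their mean whenever images contribute unequal grain
  numbers.
- Rating bins: very high (APV > 90), high (75, 90], medium (50, 75],
  low [25, 50], very low [0, 25). Boundary membership is assigned to
  the lower category except that exactly 25 rates as low; no value in
  the packaged reference table sits exactly on a boundary, so any
  consistent rule reproduces all 111 printed labels — this one is
  declared for determinism.
- PSI_img (%) = share of grains with area strictly over a threshold
  (default 118 px², the mean of the smallest viable-grain area across a
  calibration image set; "over" is implemented as a strict inequality,
  declared since ties are not otherwise specified). PSI is implemented
  for completeness; viable and non-viable size distributions overlap
  across genotypes, so APV is the recommended estimator.

## Agreement statistics

OLS of automatic on manual counts with R² = 1 − SS_res/SS_tot;
Bland–Altman mean difference of (automatic − manual) with limits of
agreement mean ± 1.96 × sample SD (n−1 denominator, standard
Bland–Altman multiplier); and a two-sided two-sample t-test on
viability percentages. The Welch (unequal-variance) variant is the
default since equality of variances is rarely defensible for
percentage data near the boundaries; the pooled-variance variant is
available, and the two coincide on balanced equal-variance data.

## Synthetic scenes

The generator emulates the acquisition conditions the pipeline targets:
1024×768 rasters with ~130 grains by default (20–200 in the validation
sweeps), additive Gaussian noise with SD 5 clipped to [0, 255], and
optional JPEG re-encoding to emulate the acquisition file format.
Grains are ellipses with eccentricity up to 0.6 (real grains are
visibly non-circular, and ellipses exercise the circularity filter and
the watershed non-trivially) whose equivalent radii are drawn uniformly
— viable 8–14 px (areas ≈ 200–620 px²), non-viable 6.5–12 px (areas ≈
130–450 px²) — so both classes sit inside the 60–800 px² counting
window, the distributions overlap (which is what defeats PSI), and
non-viable grains are slightly smaller on average, as observed in real
samples.

Default palette (RGB): viable (70, 60, 120), non-viable (90, 225, 230),
background (235, 235, 235), artifacts (235, 120, 235). Construction
validates the contrast margins the segmentation invariants rely on:
grains ≥ 40 units below background in red, viable grains ≥ 40 below in
green, non-viable within 20 of background green, artifacts dark only in
green. The non-viable red intensity is placed near the viable one so
each channel's histogram is bimodal (grains vs background), which is
the regime the isodata threshold assumes.

Placement is rejection sampling with 1000 bounded retries and an
explicit failure rather than silent under-filling. Non-touching grains
keep ≥ 6 px between bounding circles — more than twice the default
dilation — so solidification cannot fuse separate grains. A
`touching_fraction` of the grains is instead attached to a random
earlier grain with a boundary overlap of 10–30% of the smaller
equivalent radius, using the exact directional radius of each rotated
ellipse so contact is guaranteed. Artifacts (40–99 px² disks, with the
rasterization capped a few pixels below the 100 px² green floor so
subpixel placement cannot push a blob into the countable range) are
free-standing: they avoid grains and each other so that counting errors
are attributable to the pipeline, not to generator-made composites.

What the generator does **not** model: optical blur, vignetting,
out-of-focus halos, pollen texture and apertures, debris other than the
green-channel balloons, clumps of more than pairwise contact, and
uneven illumination. Passing the synthetic suites therefore
demonstrates the correctness of the algorithmic chain (thresholding,
morphology, watershed, filters, statistics) under controlled contrast —
not robustness to every real-world acquisition artifact, which is why
the agreement module for comparison against manual counts exists.

## Problem sizes in the validation suites

The test suite checks exact recovery on 50 non-touching 1024×768
scenes of 20–200 grains, ≤ 5% per-channel relative error on 20 scenes
with 30% touching grains (plus strict error inflation when the
watershed is disabled), and APV recovery within 2 percentage points
with R² ≥ 0.99 on 20 samples of ≥ 520 grains spanning 10–99% true
viability. `scripts/acceptance.py` re-derives the same quantities at
12 / 8 / 8-sample scale, which reproduces the same zero-error behaviour
in well under a minute on one CPU.

## Known limitations

- Global thresholding assumes roughly uniform illumination; strongly
  vignetted images would need upstream flat-field correction.
- The watershed splits pairwise contacts reliably but can under-split
  dense clumps of many mutually touching grains.
- Counts are pixel-area based; the px² filter bounds assume the
  magnification used at acquisition and must be re-tuned for other
  optics or species (all bounds are exposed in the configuration).
- APV treats every green-channel survivor as viable; systematic stain
  failures (e.g. under-staining of viable protoplasm) bias it low in a
  way no image analysis can detect.
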