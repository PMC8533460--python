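# Methods

This note records the models behind each pipeline stage, the defaults that
matter, and the choices made where the design was genuinely open.

## Coordinate and unit conventions

All public interfaces speak physical nanometres. The origin of an image is
the *center* of its top-left pixel; `x` runs along columns, `y` along rows;
pixel `(row, col)` sits at `(col·px, row·py)`. Pixels appear only inside
algorithms. Inter-stage tables are plain CSV, transforms and summaries are
JSON, images are single-page 16-bit grayscale TIFF with the pixel size in
the resolution tags.

## Registration

The overlay model is the 2-D affine transform `y = A·x + t` from ESEM
(source) into TIRF (target) coordinates. Three-point alignment with
translation, rotation and per-axis scaling is, with three point pairs,
exactly determined by the full affine (six constraints, six degrees of
freedom), so the solver estimates the full affine — which subsumes those
components — by linear least squares on the fiducial pairs (`lstsq` on the
design matrix `[x, y, 1]`); with exactly three non-collinear pairs the fit
interpolates them (fiducial registration error, FRE, ≈ 0). The
decomposition reported is rotation-after-scale/shear:
`A = [[sx·cosθ, −sy·sin(θ+h)], [sx·sinθ, sy·cos(θ+h)]]`; a shear magnitude
above 0.05 rad triggers a warning because the physical model expects none.
Whether the original alignment software applies scaling before or after
rotation is not documented; the affine solve is independent of that choice
and only the decomposition convention (stated above) depends on it.

Degeneracy tolerances: fiducial sources are rejected as collinear when
their planar spread (product of the two singular values of the centred
point set, halved) is below `1e−6 × span²`; a linear part with
`|det| ≤ 1e−12` is singular. Correlation happens in the TIRF frame because
the nanodomain FWHM — which sets each assignment radius — is defined there.

Image resampling inverse-maps each target pixel center and interpolates the
source bilinearly; out-of-field pixels receive a flagged fill value (NaN by
default).

## TIRF spot analysis

Detection: the image is smoothed with a Gaussian (σ = 1 px); local maxima
of the smoothed image above `median + k × (1.4826·MAD)` with `k = 5` are
kept, where the MAD is taken on the *raw* image — smoothing shrinks the
noise floor, and a threshold scaled to the smoothed noise admits rare
smoothed-noise maxima. No detection threshold was published for the
original interactive analysis; `k` is an explicit parameter. Maxima closer
than `min_separation_nm = 300` (about the smallest frequent nanodomain
FWHM) merge into the brighter one, so one domain is never split. Centers
are refined to subpixel precision by an isotropic 2-D Gaussian fit in a
9×9 px window; saturated maxima (dtype maximum) are flagged.

FWHM: two orthogonal (0° and 90°) line profiles through the refined center,
sampled at the pixel pitch by cubic-spline interpolation. Bilinear sampling
was rejected: it biases the FWHM of subpixel-centred diffraction-sized
spots by up to +3% at half-pixel phase, while cubic interpolation keeps the
noiseless calibration error below 1% across the 300–550 nm range. Per
profile, the background is the median of the outer 20% of samples on each
tail (robust to neighbouring spots, unlike a global background), the
half-maximum level is `background + 0.5·(peak − background)`, and the two
crossings are located by linear interpolation between the bracketing
samples walking outward from the peak; re-crossings further out flag the
profile as multi-peaked. The *peak level* is estimated by a 1-D
Gaussian+offset fit to the whole profile rather than the raw maximum: the
maximum of a noisy profile is selection-biased upward, which at the default
fixture's signal-to-noise (~7 at the spot peak) shrinks the measured FWHM
by 3–8%. The fit is guarded — when its peak departs from the raw maximum by
more than `max(4% of amplitude, 4 noise SD)` the profile is not
Gaussian-shaped and the raw maximum is used, which keeps non-Gaussian
profiles (e.g. triangular test peaks) exact. A spot's FWHM is the mean of
its two profile FWHMs; any profile failure (peak at the profile edge,
truncation at the image border) flags the spot and removes it from the
distributions. By construction the measure is invariant to affine intensity
rescaling.

## ESEM particle analysis

Segmentation: optional 3×3 median prefilter (off by default — the synthetic
noise is mild and the filter triples the cost on large fields), a global
threshold, 8-connected component labelling, intensity-weighted centroids.
The default threshold is Otsu with two safeguards for extreme class
imbalance, each announced by a warning: if a pass marks more than half the
field as foreground, Otsu is re-run on the above-threshold pixels (plain
Otsu splits the background noise when particles cover ≲0.5% of the field);
and if the final split separates the classes by fewer than five robust
background SDs — i.e. it is cutting through noise — the threshold is raised
to the background noise floor (median + 5 robust SD). An absolute override
is available for pathological histograms. Components touching the border
are flagged `edge`; components whose equivalent diameter falls outside
[10, 150] nm are flagged `undersize` (noise specks; the pre-enhancement
1.4 nm gold is invisible) or `oversize` (debris or merged blobs) and
excluded from statistics. Touching particles are *not* split — no splitting
rule was published, and a flagged merged blob is a transparent failure
where a watershed guess would be a silent one.

Sizing: equivalent diameter `d = 2·√(area/π)` exactly, with the area in
nm². The size summary is the mean and Student-t 95% CI half-width over
`ok`-flagged particles.

## Correlation

Particles (default: `ok`-flagged only) are mapped through the solved
transform and assigned exclusively: a particle is a candidate for a spot
when its distance to the spot center is at most `0.5·FWHM·radius_factor`
(`radius_factor = 1`), goes to its nearest candidate spot, ties to the
lower spot id. "Spatially correlated" had no operational definition in the
source workflow; half the spot's own measured FWHM scales the acceptance
disk with each domain's size, which matches the intent of scoring an
overlay by eye, and exclusive assignment matches per-domain tallies in
which each particle is counted once. Spots without a valid FWHM are
excluded (logged); unassigned particles are background. The identity
`assigned + background = total` holds exactly.

## Distribution statistics

Histograms are equal-width over the data range (numpy convention:
left-closed right-open, last bin closed), 20 bins for FWHM and 12 for
counts. Integer-valued data whose span fits inside the requested bin count
get unit-width bins centred on the integers, so count histograms have no
fractional empty bins. The 3-parameter Gaussian
`f(x) = a·exp(−0.5·((x−x₀)/b)²)` is fitted to (bin center, frequency)
pairs by unweighted nonlinear least squares (`curve_fit`, b constrained
positive, initialised at the modal bin with b₀ = the sample SD) — a curve
through the histogram, matching the original plots, not a maximum-
likelihood density fit; whether the original fits weighted bins is
unstated, so unweighted is the declared default. Normality is gated by the
standard Shapiro–Wilk test (the sample must have 3–5000 values and nonzero
variance; pass = p > 0.05). Box summaries use linear interpolation between
closest order statistics for the 10/25/50/75/90 percentiles (the plotting-
package convention is unstated; this common spreadsheet convention is
declared and testable), with points beyond the 10th/90th percentiles
listed as outliers.

## Synthetic data generator

The generator emulates the study conditions; its defaults are the
conditions the tests and acceptance checks run under.

* **Field and sampling.** 20×20 µm field, TIRF at 60 nm/px (the documented
  camera geometry), ESEM at 3 nm/px. The ESEM pixel size was never
  published; 3 nm/px makes a 38 nm particle span ~12.7 px, comfortably
  segmentable.
* **Nanodomains.** 50 domains by default (100 in the count-recovery
  fixtures), centers uniform with a 1.2 µm minimum separation (a separation
  below the profile scale would merge neighbouring spots by construction),
  FWHM ~ Normal(400, 80²) nm resampled above 120 nm — unimodal and peaking
  inside the reported 300–500 nm interval. Spots render as 2-D Gaussians
  with σ = FWHM/2.3548, peak 50 photons over a 5-photon baseline, Poisson
  shot noise plus Gaussian read noise (SD 2 counts).
* **Per-domain counts.** Left-truncated (≥1) negative binomial with
  dispersion 2; only a mean of five and a 2–23 range were reported, and
  this family reproduces both the mean and the heavy right tail (and tends
  to a truncated Poisson at large dispersion). The *untruncated* mean is
  calibrated numerically (Brent root-finding) so the truncated mean equals
  `count_mean` exactly; sampling is exact inverse-CDF. A truncated-at-1
  distribution cannot have mean ≤ 1, so configuration requires
  `count_mean > 1`.
* **Particles.** Diameters ~ Normal(38, 11.5²) nm, floored at 5 nm. Only
  the mean (38 nm) and its 95% CI (±1.6 nm) were reported, not an SD or n;
  the default SD is the one implied by that CI at n = 200
  (`1.6·√200 / t₀.₉₇₅,₁₉₉ ≈ 11.5`). In-domain particles are uniform in the
  disk of radius FWHM/2 around the domain center, with a hard-core
  constraint (best-candidate sampling; center separation at least the sum
  of radii + 6 nm where the disk allows): gold-enhanced particles are solid
  spheres and cannot interpenetrate, and independent placement produces
  unphysical overlapping disks that any split-free segmentation merges.
  Background particles (1 /µm², uniform over the field) model the label
  observed outside nanodomains; at this density their overlaps are
  negligible and they are placed independently. Particle ESEM positions
  are the exact inverse-transform of their TIRF positions.
* **ESEM rendering.** Uniform background (level 100) with disks of
  contrast 400 (bright-on-dark by default; the dark-particle polarity is
  configurable because overlays are often shown in complementary colors),
  1-px antialiased edges, Gaussian noise of 5% of the disk contrast.
* **Transform truth.** Rotation 2°, scales (1.03, 0.97), translation
  (150, −80) nm — a modest misalignment representative of re-seating a
  coverslip on a second instrument. Fiducials are four points inset from
  the field corners, exact under the transform.
* **Determinism.** One `numpy` Generator seeded from the config: identical
  config ⇒ bit-identical images and tables.

What the generator does *not* emulate: a physical optics PSF
(Richards–Wolf), detector MTF, spatially varying background or
illumination, membrane curvature, clustered background label, or
time/3-D dimensions. Passing tests therefore demonstrate correctness of
the measurement chain under the stated statistical structure, not
robustness to every real-world artefact.

## Problem sizes used by the checks

The particle-sizing check segments 200 particles on a ~4.3×4.3 µm field
(~2 Mpx); count recovery runs the full pipeline on a 100-domain,
20×20 µm pair (ESEM ~44 Mpx); the FWHM-distribution check measures ~500
spots on a 45×45 µm TIRF-only field. These sizes keep every check
statistically meaningful (Monte-Carlo SEs well inside the stated
tolerances) at interactive runtimes.

## Known limitations

* Merged gold particles are flagged, never split; in dense label the count
  per domain is a lower bound.
* The FWHM peak-level estimator assumes quasi-Gaussian spots; strongly
  flat-topped or double-peaked domains fall back to the raw maximum and
  may carry a `multi-peak` flag.
* The assignment rule is geometric; it does not model label displacement
  by the antibody linker (~10–20 nm), which is small against the ~200 nm
  acceptance radii.
* Automatic thresholding assumes particles are a minority of the field;
  fields with >50% label coverage need the absolute threshold override.
* The registration model is affine; nonrigid sample deformation between
  modalities is out of scope.
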