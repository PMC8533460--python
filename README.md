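# nanoclem

Correlative TIRFM / environmental-SEM quantification of plasma-membrane
nanodomains and their immunogold label.

## The problem

Plant plasma-membrane proteins — here the tobacco auxin efflux carrier
NtPIN3b — cluster in sub-micrometre nanodomains. Total internal reflection
fluorescence microscopy (TIRFM) of membrane ghosts resolves the nanodomains
as diffraction-limited spots but cannot count the molecules inside them;
environmental scanning electron microscopy (A-ESEM) of the same ghost
resolves individual gold-enhanced immunolabel particles (~38 nm) but carries
no fluorescence context. Overlaying the two modalities lets each fluorescent
nanodomain be annotated with the number of gold particles — hence labelled
protein copies — it contains.

`nanoclem` turns that correlative workflow into an automated, tested
pipeline:

1. **registration** — solve the affine transform `y = A x + t` mapping
   ESEM coordinates into the TIRF frame from ≥3 matched fiducial points
   (least squares; exact for 3 points), and report its decomposition into
   rotation θ, per-axis scales (s_x, s_y) and shear.
2. **spot analysis** — detect nanodomains in the TIRF image (smoothed local
   maxima above a `median + k·MAD` threshold, subpixel 2-D Gaussian
   refinement) and measure each spot's FWHM as the mean of two orthogonal
   intensity-profile half-max widths.
3. **particle analysis** — segment gold particles in the ESEM image (Otsu
   threshold with imbalance safeguards, 8-connected components) and size
   each one by its equivalent diameter `d = 2·√(area/π)`.
4. **correlation** — map particle centroids into the TIRF frame and assign
   each to the nearest nanodomain whose acceptance disk
   (radius `0.5·FWHM·radius_factor`) contains it; unassigned particles are
   background.
5. **statistics** — frequency histograms (20 bins for FWHM, 12 for counts),
   a 3-parameter Gaussian fit `f(x) = a·exp(−0.5·((x−x₀)/b)²)` to the
   histogram, a Shapiro–Wilk normality gate, and 10/25/50/75/90-percentile
   box summaries.

A synthetic-data module generates paired TIRF/ESEM images with known ground
truth (domain centers and FWHMs, per-domain particle counts from a
left-truncated negative binomial with mean 5, particle diameters around
38 nm, a known affine transform, Poisson/Gaussian noise), so every stage is
verifiable without any experimental download.

## Worked example

```sh
nanoclem run-all --seed 1 --out demo
```

simulates the default study conditions (50 nanodomains in a 20×20 µm field,
TIRF at 60 nm/px, ESEM at 3 nm/px) and runs the full pipeline on the pair.
Output:

```
50 nanodomains, 611 particles (205 assigned, 406 background); mean count 4.10, range (1, 18)
```

Reading: 50 fluorescent spots were detected and measured; 611 segmented gold
particles were mapped through the fiducial-solved transform; 205 fell inside
a nanodomain's half-FWHM disk, averaging 4.10 particles per nanodomain
(the generator's truth mean for this seed is 4.70), while 406 lay outside
any nanodomain — the synthetic field deliberately contains background label
(1 particle/µm² over 400 µm²), as the real membranes do. `demo/run/summary.json` holds the registration
residual (FRE), the Gaussian-fit parameters for the FWHM and count
distributions, and the box summaries; `demo/run/*.csv` hold the per-spot,
per-particle and per-domain tables.

Individual stages are available as `simulate`, `register`, `detect-spots`,
`detect-particles`, `correlate` and `stats` subcommands, and as library
functions (`nanoclem.solve_transform`, `nanoclem.detect_and_measure`,
`nanoclem.segment_particles`, `nanoclem.assign_particles`, ...).

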