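# Methods

## The measurement model

The package estimates the DNA content of a GFP-delimited kinetochore domain
by photometric calibration. Integrated DAPI fluorescence is assumed
proportional to the amount of DNA in the emitting object, with the
proportionality constant fixed per imaging session by internal standards —
bacteriophage particles of known genome size (λ 48 kb, P1 90 kb, T4 168 kb)
present in the same field of view. The chain is:

    net intensity I = Σ(ROI) − Σ(shifted ROI)          (background subtraction)
    standards:     I = β₀ + β₁·kb + ε,  ε ~ N(0, σ²)   (OLS, intensity on kb)
    unknown:       kb̂ = (I − β₀)/β₁                     (inverse prediction)

The regression is deliberately oriented with intensity as the response and
DNA amount as the predictor — matching how the standard curve is plotted —
so unknowns are converted by inverting the fitted line rather than by
regressing kb on intensity. The intercept is estimated, not forced through
the origin: background subtraction can leave a small systematic offset, and
an estimated intercept absorbs it.

### Uncertainty of the inverse prediction

The default 95 % interval uses the delta method for a single new
observation:

    Var(kb̂) ≈ [σ² + Var(β₀) + kb̂²·Var(β₁) + 2·kb̂·Cov(β₀,β₁)] / β₁²

with a t quantile on n−2 degrees of freedom. Over 1,000 Monte-Carlo
standard-curve replicates (3 points per phage class, homoscedastic noise)
the empirical coverage is ~95 %, which the acceptance script recomputes.
Fieller bounds are available (`predict_dna(..., method="fieller")`) for
noisy or shallow fits; when the slope is not statistically distinguishable
from zero the Fieller interval is correctly unbounded.

### Background protocol

The background for an ROI is the sum over a same-shape copy of the ROI
translated toward one of the eight compass directions. The translation
distance along a moved axis is the ROI's bounding-box extent plus
`shift_px` (default 8, admissible 5–10), i.e. `shift_px` is the *edge
clearance* between the original and background footprints. A raw 5–10 px
centre shift would leave the background copy overlapping any object wider
than the shift — for extended kinetochore envelopes most of the object's
own flux would be counted as background — whereas the manual protocol this
codifies implicitly cleared the object before annotating background. The
candidate with the least overlap with known foreground (all detected
objects in both channels) wins; ties go to the lowest sum, then to the
fixed order N, NE, E, SE, S, SW, W, NW. Candidates that would leave the
image are discarded; if all eight are discarded an error is raised. Nets
are never clamped: negative nets are emitted with a `negative-net` flag so
cohort statistics stay unbiased.

### Phage photometry and class assignment

Spots are detected on the full-stack DAPI sum projection: threshold at
median + 5·MAD (when MAD = 0, as on noiseless synthetic planes, the
threshold falls back to median + 1 % of the dynamic range), 8-connected
components, area within [4, 400] px, border-touching components dropped,
ROI = component dilated by 2 px. Detected DAPI spots whose centroid lies on
GFP foreground are kinetochores, not phages, and are excluded from the
standard set. Each phage is measured on the single plane maximizing
in-region intensity (ties to the lower index) — the protocol's "single
planes where phages were observed".

Classes are assigned by deterministic 1-D 3-means on net intensity
(centers seeded at the 1/6, 3/6, 5/6 quantiles), clusters ordered
ascending → λ, P1, T4. A QC gate requires adjacent cluster-mean ratios to
match 90/48 and 168/90 within ±25 %; offending clusters are flagged
unassigned, and an empty cluster is an error because a usable field must
contain all three standards. When a ground-truth manifest is available
(simulations), assignment can instead be done by nearest manifest position;
this oracle mode exists for testing and is never the default.

### Kinetochore envelope

Around each seed (auto-detected GFP spot or manifest position) a
31 × 31 px window is cropped over the full z-extent. The GFP sum projection
of the window is thresholded at 50 % of (local max − local median); the
connected component containing the seed locates the kinetochore. Because
the half-maximum contour of a Gaussian blob encloses only ~50 % of its
flux, the component is then grown to an aperture of `aperture_nsigma`
(default 3.5) Gaussian-equivalent sigmas, inferred from the component's
equivalent radius (σ ≈ r_eq/1.177). At 3.5σ the aperture holds 99.8 % of a
2-D Gaussian's mass, making the envelope photometrically comparable to the
near-total phage ROIs; the threshold fraction and aperture are both
config-exposed. The DAPI measurement is made on a sum projection over the
planes where the component's GFP exceeds its plane-wise background
estimate, padded by `z_pad` (default 2) planes per side to keep the axial
tails. The envelope is 2-D, matching the measured quantity (a projected
sum); a component touching the window border yields an
`envelope-truncated` flag.

Records carrying QC flags (negative net, truncated envelope, background
overlap) are excluded from the headline cohort summary by default but are
always written to the records table.

## The simulator

The synthetic-data generator emulates the acquisition conditions the
protocol describes: 1,024 × 1,024 px planes (tests and the acceptance
script use 512 × 512 to keep runtimes in seconds; the geometry is
otherwise identical), 21 planes at a 200 nm step, 65 nm xy pixels (the
conventional value for a 100×/1.4 NA CCD system; the protocol does not
state pixel pitch), 16-bit counts with gain 1.

* **Objects.** Phages are point sources rendered with the PSF sigma
  (σ_xy = 100 nm); kinetochores are Gaussian blobs (σ_xy = 250 nm,
  σ_z = 300 nm) present in both channels; an optional chromatin mass is a
  large DAPI-only blob kept ≥ 1.5 µm from kinetochores, emulating the
  chromosome body the kinetochores stretch away from.
* **Rendering** integrates a separable anisotropic Gaussian over each voxel
  (differences of normal CDFs per axis), so expected integrated DAPI is
  *exactly* `brightness_per_kb × true_kb × at_bias_factor(class)` before
  noise, photon conservation holds to window truncation (< 10⁻⁸ at the
  ±6σ support used), and noiseless fields are additive over objects by
  construction.
* **Axial idealization.** The images are "as-if-deconvolved": there is no
  out-of-focus haze, and point sources are axially confined to their focal
  plane (sub-step axial sigma of 30 nm, positions snapped to plane
  centers). This models what deconvolution does to a point emitter and
  keeps the protocol's single-plane phage photometry commensurate with the
  sum-projection kinetochore photometry; extended objects keep the 300 nm
  axial sigma and fractional z positions.
* **Noise.** Poisson on (signal + background), then additive Gaussian read
  noise, then clipping to [0, 2^bits − 1]. Per-voxel variance equals the
  mean for the Poisson-only model (verified by Monte-Carlo). Fixed seeds
  give bit-identical fields.
* **Photon budget.** Defaults — 200 photons/kb, DAPI background
  5 photons/voxel, 15,000 GFP photons per kinetochore over background 2,
  read noise 2 — are a realistic deconvolved-widefield budget chosen so the
  dimmest kinetochore in the modeled 28–147 kb range has integrated
  SNR ≳ 15, comfortably inside the SNR ≥ 10 regime the recovery analyses
  assume. The protocol states no photon counts; these are package choices.
* **AT bias.** DAPI prefers AT-rich DNA, so equal kilobases of phage and
  vertebrate chromatin need not fluoresce equally. `at_bias_factor` scales
  the expected photons/kb per object class; it is a *modeled systematic*,
  applied in the manifest's expected values and propagated untouched by the
  pipeline — setting the kinetochore factor to 0.8 shifts recovered
  estimates low by ~20 %, quantifying the caveat rather than correcting it.
* **Placement** is rejection sampling with objects kept 2·3σ_xy from the
  borders and pairwise separated by the sum of 3σ supports plus a 30 px
  margin (room for background ROIs); failure after bounded retries raises
  "field too crowded", and expected intensities that would saturate > 1 %
  of an object's voxels raise a saturation error.

### What the simulation does not capture

Real fields contain out-of-focus haze, deconvolution artifacts, spectral
bleed-through, uneven illumination, touching or aggregated phages,
irregular (non-Gaussian) stretched-chromatin shapes, and trailing
pericentromeric chromatin entering the envelope — the likely source of the
wide spread in real cohorts. Passing recovery tests therefore demonstrate
that the *measurement chain* is unbiased and correctly calibrated under the
stated imaging model, not that real-image estimates carry 2–5 % accuracy;
on real data the dominant errors are the biological/optical ones above.

## Numerical and design choices

* OLS via statsmodels; an independent closed-form normal-equation solution
  is the test oracle. Perfect fits define R² = 1 (the centered ratio is
  0/0). Outlier flagging in `fit_diagnostics` uses externally studentized
  residuals, since internally standardized residuals are bounded by
  (n−1)/√n and cannot reach the conventional cutoff of 3 on small standard
  sets.
* 1-D k-means is fully deterministic (quantile init, ≤ 100 iterations,
  fixed tie-breaking), so repeated runs agree bit-for-bit.
* Sum projections are exact pixel-wise sums (conservation asserted in
  tests); maximum projections are tagged and rejected by every
  quantification path.
* ROIs are stored as full-plane boolean masks, serialized as run-length
  encodings in the records table.
* Cohort runs of the test-suite and acceptance script use 8 fields of
  512 × 512 × 21 voxels with 9 phages + 5 kinetochores each (40
  kinetochores total, matching the ≥ 40-centromere cohort size the
  protocol reports), which keeps the full stochastic recovery analysis
  under a minute on one CPU.

## Known limitations

* The envelope is an aperture, not a matched filter: at very low GFP SNR
  the half-max component becomes noise-dominated and the inferred aperture
  radius unstable.
* The inverse-prediction interval assumes homoscedastic Gaussian residuals
  on the standard curve; shot-noise-limited standards are mildly
  heteroscedastic (variance ∝ intensity).
* Background is a same-area translated ROI, per the protocol; no local
  background surface is fit, so a sloped haze gradient biases nets.
* Overlapping kinetochores closer than the aperture diameter are not
  deblended; the simulator's placement constraints avoid creating them.
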