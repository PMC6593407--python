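# Methods

This note documents the models behind `sporeloc`, the defaults that matter,
and the choices made where the underlying procedure left the design open.
Units are nanometres and minutes throughout; images are indexed
`[row, col]` with pixel centres at integer coordinates, and the optical
axis is `z`, so an image is the projection onto the `(x, y)` plane.

## Synthetic forespore scenes

**Geometry.** A forespore is a sphere of diameter 600 nm (the scale used by
the free-diffusion null model) or, optionally, a hemispherical cap abutting
a flat septum — real forespores abut a septum, and both variants are
provided because neither is privileged by the measurement itself. The
tether anchor (the DivIVA/RacA pole site) is placed on the +x axis, i.e.
in the image plane, so a tether offset survives projection; a tethered
locus sits at a normal-jittered distance from the anchor along the inward
normal, a free locus is uniform in the volume (`r = R·U^{1/3}` with an
isotropic direction).

**Optics.** The PSF is an isotropic 2D Gaussian per channel with
σ ≈ 0.21·λ/NA at NA 1.4: 65 nm for the blue-emitting membrane stain
(TMA-DPH, ~430 nm) and 90 nm for mCherry (~610 nm). Pixel size defaults to
65 nm/px (a 6.45-µm camera pixel at 100×). These are conventions chosen
from standard diffraction arithmetic, not measured values.

**Membrane rendering.** The default `silhouette_ring` render draws the
projected outline — a thin annulus at the true silhouette radius — and
convolves it with the PSF. The physically exact line-of-sight projection
of an isolated 600-nm stained shell (`projected_shell`, provided as an
option) is *below the diffraction limit*: it blurs into a blob whose
intensity maximum lies ~40–100 nm inside the true membrane radius, and a
7-sample window fit lands further inside still, so the line-scan
measurement is undefined on it (there is no membrane peak beyond a
near-membrane focus at all). Real forespore membranes do not look like
isolated vesicles: they sit in a septum/cell-envelope context in which a
line scan crosses a locally sheet-like membrane whose intensity profile
peaks *at* the membrane. The ring render reproduces that local geometry
while keeping the spherical silhouette that the placement models and null
models use. Consequence for interpretation: passing recovery tests show
the measurement chain is accurate when the membrane crossing is locally
resolvable, as in the real images; they do not claim that an isolated
600-nm vesicle could be measured this way.

**Photometry and noise.** The locus channel is a single PSF-shaped spot
normalised to `photon_budget` expected photons (default 5000); the
membrane channel carries `membrane_photon_budget` photons (default 40×)
distributed over the outline. Noise is Poisson shot noise on expected
counts plus additive Gaussian read noise (sd 2) over a flat background
(100 counts) — CCD physics. `shot_noise=False` gives exact noiseless
renders for oracle tests. A single top-level seed drives everything;
multi-cell simulations spawn one `SeedSequence` substream per cell, so
output is bit-reproducible.

**Time-lapse generator.** Per cell, YFP rises linearly
(`reporter_rise_rate`, default 50 counts/min) from the septation time
(normal, 60 ± 15 min, truncated at 0) and CFP from septation +
translocation time (per-genotype normal; 11 ± 3 min emulates a wild-type
motor); frames every 2 min with additive Gaussian noise (sd 5). A
`yfp_miss_prob` fraction of cells never develops YFP although CFP still
appears, emulating the CFP-only mis-capture class. The generator does not
model reporter maturation delay, photobleaching, or cell-to-cell rise-rate
variation; recovered Δt means are therefore unbiased by construction, and
recovery tests validate the detection/arithmetic chain, not those
biological confounders.

## Detection rules

* Smoothing is one pass of a 3×3 neighbourhood mean with edge replication.
  It is applied for identification only (forespore ROIs, focus candidates);
  line scans are extracted from the raw channels, because the extra box
  blur costs ~5 nm of membrane-localisation accuracy and the subpixel fits
  do not need it.
* Forespores: Otsu threshold on the smoothed membrane channel, floored at
  median + 5×robust-sd so a mostly-background histogram cannot flood the
  mask; a 3×3 morphological closing bridges shot-noise gaps; connected
  components are circle-fit (centroid + mean radial distance) and kept if
  the fitted diameter lies in 250–1200 nm.
* Foci: local maxima above background mean + 2×background sd inside each
  ROI, with the statistics taken from the *raw* image outside all ROIs
  (smoothed noise is spatially correlated and would false-trigger the 2×
  rule constantly). Position refined by a 3×3 quadratic fit. An ROI is
  accepted only when it contains exactly one candidate; zero or several
  candidates reject the ROI rather than erroring.
* Reporter onsets: first frame whose excess over background reaches
  2×noise-sd, is strictly positive, and persists for 3 frames (runs cut
  off by the end of the trace count). The persistence requirement exists
  because a bare first-crossing rule false-triggers on ~2.3% of pre-onset
  frames under Gaussian noise — over a typical 40-frame pre-onset stretch
  most cells would get a spurious early onset. A rising reporter satisfies
  it immediately; noise blips do not. `min_consecutive=1` restores the
  bare rule.

## The line-scan distance statistic

The scan runs from 4 px behind the focus, through it, to 5 px past the
nearest point of the fitted outline, sampled at 1-px steps by bilinear
interpolation (no perpendicular averaging). Each channel's peak is fit
over the 7 samples around it with `y = A·exp(−(x−a)²/2b²)`, initialised at
(A = peak value, a = peak index, b = 1 px). The formula has no offset
term, so the mean of the two outermost window samples is subtracted first
(switchable); a raised local baseline cannot otherwise be accommodated.
Membrane-peak selection: local maxima must clear a prominence of 5% of the
profile range; the candidate nearest the focus centre wins, searching
beyond the focus with a 2-sample backlash (a membrane peak fractionally
behind a coincident focus still qualifies); plateaus resolve to the lower
index, distance ties to the brighter peak. Fits that do not converge or
with b > 5 px are rejected and logged, not propagated.

**Curvature correction.** The intensity peak of a curved membrane ridge of
radius R blurred by a Gaussian PSF of width σ sits σ²/2R inside the true
radius (the blurred-ring profile is ∝ I₀(rR/σ²)·e^{−(r²+R²)/2σ²}; at
R = 300 nm, σ = 65 nm the shift is ~7.5 nm). The measurement therefore
shifts the fitted membrane centre outward by σ²/2R, using the ROI
circle-fit radius for R. Without the correction the 600-nm scenario has an
irreducible ≈ −9 nm bias that no estimator of the image peak can remove;
with it the residual bias is ≈ −3 nm. The correction is parameter-free,
uses only observable quantities, and is switchable
(`curvature_correction=False`).

Accuracy under the defaults (seeded simulations in the test suite):
subpixel centre error < 0.1 px noiseless and < 0.3 px median at peak SNR 5;
measured mean distance within ~3 nm of truth for tethered populations and
monotone in the true tether distance over 0–200 nm.

## Free-diffusion null models

Closed forms for the mean apparent distance of a uniform locus at
forespore radius R:

| variant | geometry | E[d] | at R = 300 |
|---|---|---|---|
| `ball_projected_to_silhouette` | uniform ball, radial distance to the silhouette circle in projection | R(1 − 3π/16) | 123.3 nm |
| `ball_projected_1d` | uniform ball projected onto the scan axis | R(1 − 3/8) | 187.5 nm |
| `disk_1d` | projected image treated as a uniform disk, 1D scan | R(1 − 4/(3π)) | 172.7 nm |

`full_imaging_pipeline` has no closed form: each sampled position is
rendered and measured with the actual pipeline, which makes it the correct
null when comparing *measured* distance distributions (the geometric 1D
variants answer the back-of-envelope question "how far would a free locus
appear?").

**Calibration.** The expected free-diffusion figure for a 600-nm forespore
is ~174 nm; among the candidates only `disk_1d` is consistent with it —
172.68 nm exactly, and 174 = 300 × 0.58 is the same coefficient
(1 − 4/(3π) = 0.5756) rounded to two digits. `disk_1d` is therefore the
calibrated default. Note the two-digit rounding (±1.5 nm) exceeds the
Monte Carlo standard error at n ≥ 10⁵ (±0.25 nm), so agreement with the
printed figure is expected only to that rounding, not to MC precision.

Observed-vs-null comparison reports the mean difference, a z-score of the
observed mean under the null at the observed n, and the Monte Carlo
quantile of the observed mean among null means resampled at the observed
n — a calibration-free summary appropriate when the comparison is a
qualitative tether-vs-free call.

## Kinetics and population arithmetic

Δt is computed only for complete events (YFP then CFP); YFP-only cells are
censored and excluded from Δt means (no survival correction — the original
assay used none), CFP-before-YFP or CFP-only cells form the excluded
mis-capture class. Per-field CFP⁺/YFP⁺ fractions are averaged per
timepoint with the sd across fields; fields with zero YFP⁺ forespores are
excluded with a warning. Efficiency of transport = mutant/wild-type
fraction at a reference timepoint (a parameter, not hard-coded; 225 min
and 180 min are the conventional choices), with the deficit optionally
expressed as a fold change against a reference deficit. Sporulation
efficiency = post-heat-kill colonies × dilution over the reference
condition's CFU at the normalisation stage (resuspension by default),
averaged over dilutions with 30–300 colonies (inclusive; the standard
countable-plate convention), sd across dilutions; an all-zero
post-heat-kill count is reported as efficiency 0 rather than an error.

## Problem sizes and numerical conventions

Monte Carlo null means use 10⁵–10⁶ samples (geometric variants are
vectorised; standard errors ≤ 0.25 nm at 10⁵). Parameter-recovery
simulations use 100–400 cells per condition — enough that the 95%
confidence band of a recovered mean (± ~6 nm for distances, ± one frame
for Δt) is decided by the science, not the sample. Gaussian fits use
`scipy.optimize.curve_fit` (TRF, bounds A ≥ 0, a within the window,
b > 0); a flat window returns a non-converged fit rather than raising.
Degenerate inputs error early with named reasons; measurement-level
rejections (no membrane peak, wide fit) are flagged per cell and excluded
from summaries, with counts logged.

## Known limitations

* The ring render is a deliberate idealisation of membrane locality; no
  attempt is made to model the full septum/mother-cell scene, 3D stacks,
  or photobleaching.
* No axial (z) information: all distances are 2D-projected apparent
  distances, as in the assay being modelled.
* The onset rule models a detection threshold, not reporter maturation;
  absolute onset times are arbitrary to within the maturation delay,
  which cancels in Δt.
* Real-data robustness (uneven illumination, touching cells, drift) is out
  of scope; the detection stages are built for, and validated on, the
  synthetic scenes described here.
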