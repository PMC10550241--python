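# Methods

This note records the models implemented in `ptmtrack`, the parameter
choices that matter, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinate and unit conventions

Positions are micrometres; row = y, column = x; pixel indices are 0-based.
A sub-pixel position belongs to pixel `floor(position / pixel_size)`, i.e.
pixel *j* covers the half-open interval [j, j+1) pixels and its centre sits
at j + 0.5.  Masks, spawn sites and track-to-mask assignment all use this
one convention; mixing centre-at-integer and floor conventions shifts rim
pixels by half a pixel and measurably biases mask-conditioned statistics.
Frame indices are integers; the frame interval is given in seconds
(default 86.68 ms, the effective per-channel rate of an alternating
two-channel acquisition at ~23 Hz).

## Trajectory model

Single-nucleosome motion is modelled as 2-D fractional Brownian motion
with ensemble law `E[MSD(t)] = K t^α` (each coordinate contributes K/2).
Increments are synthesized by Davies–Harte circulant embedding of the
fractional-Gaussian-noise covariance, which is exact in distribution (a
Cholesky factorization backs it up should an embedding fail to be
nonnegative definite; for α ≤ 1, i.e. Hurst ≤ 1/2, the embedding is valid).
The MSD-exponent correctness is asserted by a log-log slope property test
over α ∈ {0.3, 0.5, 1.0}.

A trajectory's (K, α) is decided by where it spawns: tracks starting in an
enriched territory use the inside parameters (ownership is read off the
pixelized territory map, so ground-truth labels agree exactly with the
mask-assignment rule).  Tracks are *not* confined to their territory by
default.  This is deliberate: the randomized-mask control works because
the real mask and its translated copies select tracks from one population
with the same residence-time statistics — any mask preferentially retains
slower tracks for ≥ 10 consecutive frames, and the contrast ΔK is meant to
cancel exactly that bias.  If inside tracks are hard-confined, the real
mask captures them without any selection while the null mask still selects
among free tracks, and homogeneous cells acquire a structural ΔK > 0
(about +9% under the default conditions — we measured it).  A
`confine_inside=True` option retains the reflective-boundary model for
users who want hard territories, with that caveat.  Tracks reflect at the
nucleus boundary (approximate mirror in normalized elliptical coordinates,
with a one-pixel safety margin so positions stay inside the pixelized
nuclear mask).

Static localization error is iid Gaussian per coordinate (default
σ = 30 nm), raising every TA-MSD value by ≈ 4σ².  Motion blur (dynamic
error) is off by default; `motion_blur_samples > 1` simulates on a finer
grid and averages positions within each frame, for exercising the
error-cancelling resampling estimator.

## Scene geometry and rendering

Nuclei are ellipses filling 84% of the image span.  Territories are
non-overlapping disks, radius ~ N(0.56 μm, 0.18 μm) clipped at 2 px —
median cross-section ≈ 1 μm² with a wide spread, matching the scale
reported for PTM-enriched chromatin territories.  Disk centres keep a 3-px
clearance so that distinct sites remain resolvable after the cleanup
dilation.  Half the territories are enriched in each Fab channel.  The
default cell has 24 territories (≈ 7% nuclear coverage) and 1000 tracks
spawned uniformly over the nucleus, giving per-cell inside-segment counts
(tens to low hundreds) comparable to per-cell track statistics in live-cell
single-nucleosome experiments.

Rendering is intentionally minimal: flat nuclear background, flat
territory foreground, Gaussian-approximated shot noise with
sd = `noise_scale · sqrt(intensity)` (defaults 100/400/1.0, i.e. contrast
15× the foreground noise sd), optionally convolved with a Gaussian PSF
(`psf_sigma_px`, default 0 — the downstream analysis only thresholds and
averages intensities, and a blur skirt systematically widens adaptive-
threshold masks).  No photophysics, axial motion, or registration drift.

Territory intensity traces are smooth latent Gaussian processes (one
shared Gaussian filter, σ = 2 time steps ≈ 6 min at the 3-min cadence,
standardized to unit variance) with iid measurement noise.  The two Fab
channels are coupled so that the *observed* traces have population Pearson
correlation exactly equal to `trace_coupling`; the latent coupling is
inflated by `1 + noise_sd²/amplitude²`, and couplings unreachable at the
requested noise level raise an error.

## Segmentation and null masks

Binarization follows the local adaptive threshold
`I_LT = a⟨I_n⟩ + b σ_I + g` (21×21 window; a = 0.94, b = 0.6, g = 0.05) on
the min–max-normalized nuclear image; pixels outside the nucleus contribute
zero to the window statistics and are always background; the comparison is
strict (ties have measure zero for continuous intensities).  Cleanup
removes 8-connected components of area < 10 px and dilates survivors by
one pixel using the 4-connected (diamond) footprint — the unit Euclidean
ball on the grid.  We use the diamond rather than a 3×3 square because, at
the ~1 μm² site scale, raw detection on clean scenes is already pixel-
accurate and the dilation ring is the dominant mask/ground-truth mismatch;
the square's corner overshoot alone caps the achievable Jaccard below 0.7,
while the diamond keeps pooled Jaccard at 0.70–0.77 across noise levels
down to 3× contrast.

Randomized null masks translate every component rigidly by an independent
integer vector uniform in [−max_shift, max_shift]² (default 20).  Draws
that would push a component out of the image are redrawn up to 100 times,
then the last candidate is kept clipped and counted in the result metadata.
Component areas and shapes are preserved exactly up to overlap of shifted
components (property-tested by shape signatures).

## Mask-conditioned diffusion statistics

Tracks are truncated to their first 10 frames before TA-MSD computation so
all tracks probe the same time span (suppressing the aging/selection bias
of long-lived tracks), ensemble averages are unweighted with SEM across
tracks, and fits use ordinary least squares on the first five points of
log₁₀ MSD vs log₁₀ t.

Static-error offset estimation offers three routes:

* `two_point` — linear extrapolation of the first two lags to lag zero,
  floored at 0.  Exact for linear MSDs; for a power law it over-subtracts
  by `K Δt^α (2 − 2^α)` (comparable to 4σ² itself under the default
  conditions), so it serves as a quick diagnostic, not the pipeline
  default.
* `power_law` — SEM-weighted fit of `K t^α + c`.  Unbiased but, on the
  nine truncated lags, the curvature/offset degeneracy makes it noisy.
* `resampling` (default) — α from the even/odd-subsampling functional
  ratio (see below) restricted to frame lags ≤ 10, then a linear
  SEM-weighted fit of (K, c) on the full-length ensemble curve given that
  α.  This is stable because the functional ratio is offset-free by
  construction and (K, c) enter linearly.

In per-cell real-vs-random comparisons the offset is estimated **once per
cell from all tracks** and shared by both fits: σ is a property of the
imaging, not of the mask, and sharing it cancels most of its estimation
error in ΔK and Δα.  The randomized ensemble pools segments across the 10
randomizations into a single fit (matching the convention of counting
"total tracks across randomizations") rather than averaging 10 separate
fits.  Cells with fewer than 25 segments on either side are excluded with
a logged reason.

The resampling estimator builds even- and odd-position subsampled copies
of every track (both are used, doubling the 2Δt ensemble), forms translated
functionals `v(n) = MSD(n) − MSD(1)` with the lag *n* indexed in frames for
both frame times, and averages `log2[v₂(n)/v₁(n)]` over lags where both
functionals are positive.  Any lag-independent error term — static noise,
and to leading order motion blur — cancels in the translation; the
identity is exact for power-law MSDs (unit-tested with analytic curves).
When several independent datasets are supplied, the reported spread is the
sample SD of per-dataset α values.

## Region tracking and correlation

Region linking is greedy nearest-neighbour centroid matching (closest pairs
first, one-to-one per frame pair) with a 10-px adjacent-frame gate and
3-px / 2-frame gap closing — deliberately simple plumbing standing in for a
full LAP tracker, adequate for slowly moving territories.  Member pixels at
each time point are the mask component at the linked centroid intersected
with the 5-pixel Chebyshev neighbourhood of the centroid ("within 5 pixels
in any direction").  Channel images are rescaled per nuclear frame before
averaging; the default maps the 2.5/97.5 percentiles to −1/+1
(`quantile_anchor`), with the mean-centred variant (`fig1`) also available
— the two differ by a shift unless the intensity distribution is symmetric.
Missing time points are linearly interpolated and flagged; the interpolated
fraction is reported per track.

Peak/trough calling uses prominence 0.15, width 2 and separation 10 on
tracks of ≥ 30 points, discarding events within 10 points of either end.
Event alignment reports the mean and a 1.96·SEM 95% CI per offset; with a
single event the CI is reported as missing, not zero.  The event-alignment
window defaults to ±10 steps (configurable; the appropriate width depends
on the cadence).

Lagged cross-correlation computes each track's Pearson r over the
overlapping samples only (no padding); positive lag means the second
channel is delayed.  Tracks are weighted by the number of overlapping
points at that lag (track length − |lag|), zero-variance overlaps are
excluded and counted, and errors are the SD over 1000 bootstrap resamples
of tracks with replacement.  Since resampling acts at the track level, the
per-track correlation tables are computed once and reused across replicates.

## Spatial correlation

Images are mean-subtracted over the caller-supplied analysis mask, zeroed
elsewhere, and cross-correlated with the full linear surface (FFT method).
Radial profiles average over rings of width 2 px — ring *k* collects radii
in (2(k−1), 2k] with the r = 0 entry being the zero-shift value itself —
and are normalized by the zero-shift value only (no variance
normalization).  Masking of nucleus/nucleoli is the caller's
responsibility; the analysis mask is an input.

## Stoichiometry

Counts follow the parameter chain exactly: per-site numbers scale the
per-cell abundances by the site volume fraction (default 1/200 of a
200 μm³ nucleus); Ser5ph sites multiply initiated RNAP2 (1e5/cell) by 52
heptads; H3 tail sites multiply nucleosomes (6e7/cell) by two tails.  With
a 2% acetylation fraction the marked-tail count is 2.4e6 per cell; accounts
quoting ~4.4e6 for the same inputs do not follow from this arithmetic, and
the calculator always reports the formula value.  The bound fraction
divides nuclear Fab (half of 1e6 loaded) by the Ser5ph site count, giving
9.6%.  All outputs are exact floats; rounding is presentation-side.

## Rouse reference chains

The polymer benchmark integrates overdamped bead-spring chains
(Euler–Maruyama, dt = 0.02 reduced units, kT = ζ = k = 1) started from
exact equilibrium (iid Gaussian bonds).  With 32 beads the fastest mode
relaxes in ζ/4k = 0.25 and the Rouse time is ≈ 104, so middle-monomer
positions are sampled every 2.0 time units: the five fitted lags (2–10)
sit decisively inside the t^1/2 window while the centre-of-mass diffusion
term (4kTt/Nζ) remains a small correction.  Six hundred chains through the
pipeline's truncation/EA-TA-MSD/5-point fit reproduce α = 0.5 within a few
hundredths.

## Problem sizes used by the test-suite benchmarks

Parameter recovery uses 1000 tracks of 30 frames per (K, α) condition;
the selection-bias study uses 20 cells × 1000 tracks per condition with 10
mask randomizations per cell; correlation recovery uses 300 tracks × 100
points; segmentation recovery pools three 256² confocal-scale scenes
(0.096 μm pixels) per noise level.  These sizes put Monte-Carlo error
comfortably below the tolerances being asserted while keeping the full
suite around two minutes.

## Known limitations

* The generator emulates the *observables* (K, α contrast, trace coupling,
  territory geometry) and not mechanisms: no tethering, crowding,
  condensate physics, photophysics, 3-D motion, or registration drift.
  Passing tests demonstrate the statistical machinery is correct and
  unbiased under the stated model, not that real chromatin satisfies it.
* fBm is self-similar; real nucleosome motion may show regime changes
  outside the fitted five-lag window.
* The greedy region linker is not a global assignment optimizer; heavily
  crossing territories would need a proper LAP tracker upstream.
* Randomized masks are constrained to the image, not to the nucleus; with
  territories concentrated centrally this slightly widens the null's
  spatial support.
* The two published rescaling conventions (mean-centred vs quantile-
  anchored) are both provided but are not identical; region-trace
  extraction defaults to quantile anchoring.
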