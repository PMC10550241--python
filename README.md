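# ptmtrack

Analysis pipeline for live-cell chromatin imaging experiments that relate
histone-modification–enriched subnuclear territories to single-nucleosome
mobility.  It is aimed at labs doing Fab-based live endogenous modification
labeling (e.g. H3K27ac and RNAP2-Ser5ph Fab channels plus a HaloTag-H2B
channel) combined with single-molecule tracking, and at anyone who needs the
individual pieces: local adaptive segmentation of enriched territories,
morphology-preserving randomized null masks, mask-conditioned
anomalous-diffusion statistics, or minutes-scale intensity-trace
correlation.

## What it computes

**Territory segmentation.** A nuclear image is min-max normalized and
binarized with a local adaptive threshold per pixel,
`I_LT = a⟨I_n⟩ + b σ_I + g` over a 21×21 window (defaults a = 0.94,
b = 0.6, g = 0.05), followed by a 10-pixel size filter and a 1-pixel
dilation.  A null mask with identical morphology is built by rigidly
translating every connected component by an independent uniform integer
vector in [−20, 20]².

**Single-nucleosome statistics.**  For each track the time-averaged mean
squared displacement (TA-MSD)

    msd(nΔt) = 1/(N−n) Σ_j |r[(j+n)Δt] − r[jΔt]|²

is ensemble-averaged over all tracks assigned to a mask (positions are
classified by their containing pixel; tracks are split at border crossings
and only runs of ≥ 10 consecutive frames are kept, after truncation of each
track to its first 10 frames).  The ensemble curve is fitted on log-log
axes over its first five lags to the anomalous-diffusion law

    MSD(t_lag) ≅ K_α · t_lag^α ,

after subtracting a static-localization-error offset (≈ 4σ² for 2-D tracks).
Per cell, the fits inside the real mask and inside pooled randomized masks
are subtracted to give ΔK and Δα — the randomized control carries the same
residence-time selection bias as the real mask, so the difference isolates
the mobility contrast.  A subsampling estimator (even/odd frames, frame
time 2Δt) recovers α free of static and dynamic localization errors via
`v(t_lag, 2Δt) = 2^α v(t_lag, Δt)` for translated MSD functionals `v`.

**Territory dynamics.**  Segmented territories are linked through time by
greedy centroid matching (10 px link, 3 px / 2-frame gap closing), their
three-channel mean rescaled intensities extracted (quantile anchoring of
−1/+1 to the 2.5/97.5 percentiles per nuclear image), peaks and troughs
called (prominence 0.15, width 2, separation 10), signals aligned at
events, and channel pairs cross-correlated per track with length-weighted
averaging and track-level bootstrap errors (1000 resamples).

**Synthetic scenes.**  Every stage is testable without raw microscopy data:
the generator builds elliptical nuclei with non-overlapping disk-like
enriched territories (~1 μm² median cross-section), subdiffusive 2-D
fractional-Brownian-motion nucleosome tracks (defaults K = 0.03 μm²/sᵅ,
α = 0.5, 86.68 ms frame time, 130 nm pixels, 30 nm localization error)
whose (K, α) depend on the spawn territory, rendered channel stacks with
shot noise, and coupled minutes-cadence intensity traces with a prescribed
inter-channel Pearson correlation.  An overdamped Rouse bead-spring chain
provides an independent polymer-physics reference whose middle-monomer
MSD exponent is 1/2 at intermediate times.

**Stoichiometry.**  Deterministic calculators reproduce the back-of-envelope
molecular budget of an average territory (~1/200 of a ~200 μm³ nucleus):
nucleosome, H3K27ac-site and initiated-RNAP2 counts per site, per-cell Fab
binding-site budgets, the Fab bound fraction, and the dye degree of
labeling DOL = (ε_Fab/ε_dye)/(A280/Adye − CF).

## Worked example

Simulate a cell whose nucleosomes diffuse 15% faster inside enriched
territories, then measure that contrast against the randomized-mask null:

```python
from ptmtrack import (SceneConfig, generate_scene, MaskSeries,
                      compare_real_vs_random, resampled_alpha)

cfg = SceneConfig(K_inside=0.0345, K_outside=0.03, seed=42)
scene = generate_scene(cfg, render_images=False)
masks = MaskSeries.static(scene.combined_region_mask,
                          cfg.n_frames, cfg.pixel_size)
comp = compare_real_vs_random(scene.trajectories, masks,
                              scene.nucleus_mask, n_random=10, seed=0)
print(comp.fit_real.K_alpha, comp.fit_random.K_alpha, comp.pct_delta_K)
```

prints (one cell; the per-cell scatter is a few percent, so population
statements average ~20 cells):

```
real mask:       K = 0.0309 um^2/s^a, alpha = 0.496 (76 segments)
randomized mask: K = 0.0283 um^2/s^a, alpha = 0.472 (635 segments)
pct delta K = +9.0%  delta alpha = +0.024
resampled alpha (error-free): 0.482
```

The real-mask ensemble is faster than the morphology-matched null (ΔK > 0,
true contrast +15%, this cell measures +9%), the diffusion *type* is
unchanged (Δα ≈ 0), and the subsampling estimator returns the ground-truth
exponent 0.5 to within a few percent despite the 30 nm localization error.

A command-line interface mirrors the library:
`ptmtrack simulate|mask|regions|events|xcorr|spt|spatial|stoich|run`
(see `ptmtrack --help`).

## Layout

- `src/ptmtrack/synthetic.py` — scene/trajectory/trace generators, Rouse chains
- `src/ptmtrack/masks.py` — local adaptive binarization, cleanup, randomized nulls
- `src/ptmtrack/regions.py` — region linking, traces, events, cross-correlation
- `src/ptmtrack/spt.py` — TA-MSD, anomalous fits, ΔK/Δα, resampling estimator
- `src/ptmtrack/spatial.py` — spatial auto/cross-correlation, radial profiles
- `src/ptmtrack/stoichiometry.py` — composition / binding-site / DOL calculators
- `src/ptmtrack/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
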