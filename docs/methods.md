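# Methods

## The measurement

A microbubble flowing through a vessel crosses the imaging plane on a nearly
straight path at 1–6 cm/s; a microbubble entering a glomerulus swirls slowly
(sub-cm/s) inside a capillary bundle of ~150–300 µm. Both are far below the
resolution of the ~0.5 mm point-spread function of a 3 MHz convex probe, but
localization microscopy recovers them: each bubble is a point emitter whose
center can be estimated to a fraction of a pixel, and linking localizations
over frames yields per-bubble tracks whose *kinematics* — not their raw image
footprint — identify the underlying structure.

The discriminating statistic is the normalized distance
ND = path length / chord. A straight transit gives ND = 1; a track that loops
inside a bundle gives ND ≫ 1, diverging as the track closes on itself. ND is
aggregated (per-cell maximum) on a super-resolved grid, smoothed, and cells
above the 90th percentile of the visited cells are segmented into connected
components: the glomerulus candidates. Counts are normalized by ROI area
(cm⁻²). Secondary metrics (dispersity, normalized and absolute speed)
characterize the same separation on the track population directly.

## Processing chain and numerical choices

**Blocks.** Loops are processed in blocks of 200 frames; a trailing partial
block is kept when it holds ≥ 100 frames (dropping it would discard up to
5 s at 40 Hz). Tracks never span block boundaries.

**Slow/fast split.** An order-2 Butterworth bandpass (0.5–5.5 Hz), run
forward–backward (`sosfiltfilt`) over the time axis so it adds no group
delay. A fast bubble's transit through a pixel is an impulse-like event with
energy in the band; a quasi-stationary glomerular bubble is mostly DC and is
suppressed. The fast population is localized on the filtered stack, the slow
population on the raw stack.

**Localization.** Gaussian pre-smoothing at the PSF scale, strict regional
maxima above a threshold, and intensity-weighted centroid refinement in a
(2⌈2σ⌉+1)² window with the window minimum subtracted as local background.
On noiseless blobs this is accurate to < 0.1 px RMSE. Four threshold modes:
absolute; top-N brightest maxima per frame (the usual ULM toolbox
parameterization, N ≈ expected concurrent bubbles); k·σ above the noise with
σ estimated from the high-frequency residual (frame minus its smoothing —
bubbles are smooth at the PSF scale, so the residual is nearly pure noise
even when blobs crowd the frame); and a per-frame intensity percentile
(library default, 99.5). The percentile mode degrades on crowded bolus-phase
frames — the top percentile of pixels concentrates in the few brightest
blobs — so the bolus configuration (`PipelineConfig.bolus()`) uses the
noise-adaptive mode with k = 8.

**Tracking.** Per consecutive frame pair, minimum-total-distance bipartite
assignment (Hungarian via `linear_sum_assignment`) with links beyond the
population's radius forbidden (slow 2 px/frame, fast 10 px/frame; at 0.2 mm
and 40 Hz these bound 1.6 and 8 cm/s). A missed detection terminates the
track — no gap closing, which keeps every metric defined on consecutive
frames. Tracks shorter than 5 frames are dropped. Two consistency filters
follow: a slow track duplicating a fast track (≥ 50 % of its points within
1 px in the same frames) is dropped, and a fast track whose mean step is
below the speed cutoff (default 1 cm/s) is dropped as residual filter
ringing rather than a transit.

**ND grid.** Track trajectories (consecutive localizations connected by line
rasterization, as ULM density maps accumulate tracks) are painted onto a
grid at pixel_spacing/8; each visited cell keeps the maximum ND over
touching tracks (a mean would dilute a swirl crossed by one straight
transit). ND is capped at 100 when the chord falls below one grid cell,
preserving "large ND = swirling" without infinities. Rasterizing isolated
points instead of trajectories would under-represent fast tracks (whose
steps span ~30 grid cells) by an order of magnitude and distort the
percentile threshold.

**Segmentation.** The grid is smoothed with a Gaussian; the threshold is the
90th percentile over *visited* cells (over all cells it is typically 0 and
degenerates), applied strictly (>). 8-connected components smaller than
0.005 mm² are dropped; centroids are the detected centers; a center is
assigned to the ROI containing it. The library default smoothing is 0.1 mm
(the glomerulus scale); the bolus configuration uses 0.05 mm — half the
bundle radius — because heavier smoothing dilutes weakly-covered bundles
below the percentile cut.

**Statistics.** Summaries are mean ± sample SD [min–max], displayed with
half-away-from-zero rounding. The omnibus test is the classical one-way
ANOVA decomposition; post-hoc contrasts are Tukey–Kramer (studentized range
with pooled within-group MS, valid for unequal n, via `scipy.stats
.tukey_hsd`); Shapiro–Wilk is reported as a normality gate and never blocks
the pipeline. The packaged per-lesion density table is compared as three
independent groups: 6 tumors, 6 pseudotumors, and the 12 adjacent-cortex
values pooled — the grouping under which the published F statistic (16.21)
reproduces exactly. The published cortex-vs-pseudotumor post-hoc p (0.6018)
is not recoverable from the per-lesion table under Tukey–Kramer (the group
means differ by 0.08, giving p ≈ 1.0); it is documented, not asserted. A few
printed aggregates are internally inconsistent with their own per-lesion
rows (pseudotumor mean diameter, the tumor eGFR quoted in prose, the
pseudotumor loop-duration range); the fixtures store the per-row values and
those aggregates are excluded from checks.

## The synthetic CEUS simulator

The simulator emulates what the analysis needs from a bolus-phase renal
acquisition and nothing more:

- **Geometry/calibration**: 20 × 10 mm field, 0.2 mm isotropic pixels,
  40 Hz, 20 s (800 frames) — within the clinical ranges (32–56 Hz, 10–40 s).
- **Vessels**: straight centerlines with finite lumen width (0.3 mm); each
  bubble rides a parallel line at a constant random offset, advancing at
  exactly the configured speed (2–6 cm/s, the renal cortical range), so
  repeated transits paint a band as real vessels do on ULM maps. The
  two-ROI phantom uses 7 such vessels per ROI, an interlobular-artery-like
  bed.
- **Glomeruli**: radius 0.15 mm; each bubble orbits at a random radius in
  [0.3, 1.0]·R with random direction, 0.3 cm/s tangential speed, small
  radial jitter, clipped to stay inside R (confinement is exact by
  construction). Arrivals are Poisson at 0.5 bubbles/s per glomerulus with a
  2 s lifetime; the published data constrain the concentration only
  qualitatively, and these rates give each bundle several transits per
  acquisition, as the method presumes.
- **Rendering**: each bubble is an isotropic Gaussian blob (σ = 0.3 mm, the
  diffraction scale) of unit amplitude, plus i.i.d. Gaussian noise
  (σ = 0.05). A fixed seed yields bit-identical stacks and ground truth.

Not modelled: tissue speckle and clutter, nonlinear bubble acoustics, beam
geometry, attenuation, out-of-plane motion, breathing. Passing recovery
tests on these phantoms therefore demonstrates the correctness and
calibration of the *analysis chain* — localization accuracy, tracking
identity, metric analytics, detection counting — not robustness to clutter
or motion, which clinical data add on top.

## Phantom recovery experiment

Ten phantoms (true cortex density 26 glomeruli/cm², lesion 0) are analyzed
with the bolus configuration. Recovered cortex density averages within a few
percent of truth (individual seeds scatter roughly ±20 %, occasionally
over-segmenting a bundle) and exceeds the lesion's in every seed; the lesion
retains a small artifactual residue (~1/cm², from occasional high-ND track
fragments), qualitatively mirroring the artifact counts clinical tumors
show. This direction-of-effect experiment is the acceptance surface for the
imaging pipeline: the published per-patient values cannot be recomputed
because no cine loops are deposited.

## Known limitations

- The dispersity definition reads "number of times a track goes in the same
  direction … divided by the number of points": same-direction *pairs* are
  counted and the denominator is the original point count. Counting
  direction *changes* instead preserves the group ordering; the choice is
  flagged, not silent.
- The normalization constant of "normalized speed" is not defined in the
  published description; the 99th percentile of acquisition track speeds is
  used (robust to a single outlier, pins the fastest flows near 1).
- The exact duplicate-removal rule between the slow and fast passes
  ("double post-processing classification") is described only in
  unavailable supplementary material; the 50 %-coincidence rule stands in.
- Detection counts include swirl-like artifacts by construction (the
  percentile threshold always selects the top decile of visited cells);
  distinguishing true glomeruli from artifacts is out of scope, as in the
  clinical analysis.
- No motion correction: the chain assumes breath-hold acquisitions.
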