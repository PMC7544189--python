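# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `protrudyn`. It is written for a reader who wants to know
*why* each stage behaves the way it does, and what passing the test suite
does and does not demonstrate about real recordings.

## Imaging model and preprocessing

Input is a calibrated single-channel time-lapse `(t, z, y, x)` or, after
projection, `(t, y, x)`. The analysis targets membrane-marker recordings of
dendrite segments: one frame every 5 s for 10 min (121 frames), 0.06 µm/px,
segments of roughly 65–75 µm.

**Maximum z-projection.** Each pixel takes the maximum over z. Applied only
when a z axis is present; a projected stack passes through unchanged.

**Drift correction.** Rigid translation only, estimated per frame against a
reference (frame 0 by default) by cross-correlation in the Fourier domain
with sub-pixel refinement. Dendrite stage drift is overwhelmingly
translational on the 10-min scale, so no rotation or deformation model is
fitted. Integer shifts are undone exactly (array roll); sub-pixel shifts use
linear interpolation with nearest-edge padding. A featureless (constant)
frame produces a warning and an assumed zero shift.

**Gaussian low-pass.** σ = 2 px with reflective boundaries (total intensity
conserved to ≪ 0.1 %). The "kernel size 2" of interactive image-analysis
tools is read as the Gaussian σ, the common convention.

**Triangle threshold.** A 256-bin histogram over the frame's min–max range;
a chord runs from the histogram peak to the last non-empty bin on the
longer-tail side; the threshold is the bin maximising perpendicular distance
to the chord, mapped back to intensity units at the tail-side bin edge (this
edge convention makes thresholding exactly consistent under intensity
inversion, and exactly scale-equivariant). The threshold is computed **per
frame** by default because photobleaching shifts the histogram over 121
frames; a single global threshold is available and the choice is recorded in
the output provenance. Degenerate (constant) frames raise an error.

**Silhouettes and outlines.** mask = frame ≥ level; the largest 8-connected
component is kept (the dendrite with its protrusions); outline = mask minus
its erosion; outlines are painted into an RGB overlay with a hue drawn
linearly from a red→violet time colormap. Frames with an empty mask are
flagged and excluded from counting. A focal-loss heuristic (frame mean
dropping below 50 % of the first frame) flags frames but never excludes
them — exclusion decisions stay with the analyst.

## Shaft/protrusion separation and length measurement

The shaft is recovered by **morphological opening** with a disc of radius
⌈w/(2·px)⌉ where `w = max_protrusion_width_um`. The parameter is the
protrusion's *apparent* width in the binary mask, not its physical width:
the PSF plus the low-pass widen a ~0.3 µm process to well over 1 µm at the
triangle threshold (which sits close to the background mode). The default is
1.6 µm; if the opening erases the whole mask the error message says to lower
it. The largest remaining component is the shaft; its centerline is the
longest geodesic path through the skeleton, its length (µm) is the segment
length used for densities, and its half-width is the median distance
transform along the centerline.

Protrusion candidates are 8-connected components of `mask − shaft` that
touch the shaft. Within a component, a multi-source geodesic distance
(diagonal steps cost √2) is computed from the shaft-adjacent pixels; the
length is the distance to the farthest pixel and the reported skeleton path
is the corresponding shortest path. Two corrections matter:

* **Base-incursion correction.** The opening's dilation step creeps up the
  blurred base fillet of each protrusion, so the recovered shaft boundary
  sits above the true shaft edge at each junction. The measured length is
  corrected by `(distance of base from centerline − median shaft
  half-width)`. With this correction, PSF-induced dilation at the base and
  at the tip cancel to first order and noiseless renderings are measured to
  within ~0.1 µm (validated against ground truth in the acceptance suite).
* **End caps.** Components whose base projects onto an endpoint of the
  centerline are residuals of the shaft's rounded end (the opening erodes
  the cap); they are discarded, since a process at the cut end of the
  analysed segment is not measurable.

Lengths are gated to the inclusive interval **[0.4, 10] µm**. Components
touching the image border are kept but flagged (their length is a lower
bound). Detection is per frame with no temporal smoothing; time is handled
by the tracker.

## Tracking and event classification

Greedy nearest-base linking along the (frame-0) centerline coordinate:
candidate (track, instance) pairs within `linkage_radius_um` (default
1.0 µm) are matched in order of increasing distance with deterministic tie
breaks; unmatched instances found new tracks; a track missing for more than
`max_gap_frames` (default 1 frame = 5 s) is terminated, shorter dropouts are
bridged by linear interpolation. Tracks spanning fewer than
`min_track_frames` (default 2) are discarded as detection blips: no
protrusion of interest lives for a single 5-s interval.

Classification relative to the recording window:
present at frame 0 and the last frame → *stable*; absent at 0, present at
the end → *formed*; present at 0, absent at the end → *eliminated*; absent
at both → *labile*. These categories are mutually exclusive per track — a
labile protrusion is **not** additionally counted as one formation plus one
elimination, which keeps the turnover sum un-inflated. Independently, a
track is *motile* if any consecutive-frame length change reaches
`motility_threshold_um` (default 0.25 µm ≈ 4 px) while the track persists;
birth and death transitions do not count. Both the motile-track count (used
in the metrics) and the per-track extension/retraction event counts are
reported.

The event log satisfies `N_end = N0 − E + F` by construction; the identity
is asserted at aggregation and a violation is reported as an internal error.

## Metrics

All percentages are normalised by N0 and computed per segment, then averaged
across cells (mean of ratios, matching cell-level summaries). The additive
identity Δmovement = turnover + motility is exact per segment and survives
group averaging. Density uses the traced centerline length of the shaft,
and N0 as the count. Segments with N0 = 0 are undefined and raised as
errors so that callers can exclude and log them. Values are rounded to one
decimal only at reporting time.

## Statistics

The normality gate applies Shapiro–Wilk per group across all four groups of
the 2×2 design (genotype ∈ {WT, KO} × plasmid ∈ {EGFP, PANX1-EGFP}); any
rejection at α = 0.05 routes the whole metric to the nonparametric branch.
Parametric branch: two-way ANOVA (main effects + interaction, type-II sums
of squares) with pairwise t tests; nonparametric branch: Kruskal–Wallis
omnibus with pairwise two-sided rank-sum tests. Four planned comparisons are
made — every group against WT-EGFP, plus KO-EGFP vs KO-PANX1-EGFP — so the
Bonferroni multiplier is 4 (not the 6 of all pairs).

Effect sizes are differences of group means with **BCa bootstrap** 95 %
intervals: both groups resampled independently (default 5000 resamples),
bias correction z₀ from the fraction of resampled statistics below the
point estimate (with mid-rank handling of ties and clipping at 1/(2·n_boot)
to keep the normal quantile finite), acceleration from a leave-one-out
jackknife across both groups. A plain bias-corrected and a plain percentile
interval are available via `method=`. With zero variance in both groups the
interval collapses to the point estimate with a warning. All bootstrap paths
require a seed and record it. On simulated normal data (n = 15 per group,
1000 resamples) the measured coverage of the 95 % interval is ≈ 92.5–93.7 %
depending on the Monte-Carlo stream — the documented small-sample
under-coverage of BCa, on the order of 2 percentage points at this n;
scipy's independent BCa implementation shows identical coverage on the same
data, and the conservative (order-statistic) quantile convention changes it
by < 0.1 point. The validation suite estimates coverage with 4000
replications so that Monte-Carlo error (~0.4 percentage points) is small
against the target band.

## The synthetic generator

`simdendrite` emulates the targeted acquisition: 0.06 µm/px, 5 s frame
interval, 121 frames, a straight horizontal shaft (default 70 µm long,
1.5 µm wide) with protrusions rendered as straight lines normal to the
shaft — only length and presence are quantified downstream, so curvature is
not modelled. Defaults describe a moderately dynamic segment; the event
structure is:

* **Initial population**: `n_initial_protrusions` (default 15) present at
  frame 0, with lengths uniform in `length_sampling_range_um` (default
  1–4 µm, matching the ~2 µm mean of real protrusions; the full
  [0.4, 10] µm interval remains the admissible envelope and the detection
  gate). The default initial density is kept below the biological value so
  that neighbouring protrusions remain individually resolvable after PSF
  blurring; base positions sit on a jittered grid with a guaranteed minimum
  spacing (default 2 µm, jitter bounded so adjacent bases stay > 0.7 ×
  spacing apart — inside the linker's matching radius nothing ambiguous can
  happen).
* **Eliminations**: an exact count of initial protrusions disappears at a
  uniform frame.
* **Formations and labile events** arrive as homogeneous Poisson processes
  (`formation_rate_per_min`, `lability_rate_per_min`); exact-count overrides
  exist for parameter-recovery experiments. Labile lifetimes are uniform in
  `labile_lifetime_range_min` (default 1–3 min, the typical short-lived
  range). Events leave at least `min_visible_frames` (default 6 frames =
  30 s) of presence: a "protrusion" alive for a single frame interval is not
  an observable event for any observer, human or algorithmic.
* **Motility**: a configured fraction of the protrusions persisting to the
  end performs a ±`motility_step_um` (default 0.5 µm) random walk on length
  with per-frame move probability 0.15, reflecting at the sampling band —
  a walk onto the 0.4 µm gate would make an alive protrusion undetectable
  by definition, conflating motility with elimination.

Rendering: binary geometry → Gaussian PSF (σ default 0.15 µm) → peak
normalisation to `signal_level` over `background_level` → Poisson shot noise
plus Gaussian read noise (standard confocal approximation). The canvas
auto-sizes to the schedule unless an explicit field of view is given, in
which case geometry leaving the frame raises an error naming the track.
Schedule and noise use independent streams derived from one seed, so
identical `(config, seed)` give byte-identical stacks.

**What the simulations do not capture**: curved and branching dendrites,
protrusion curvature and spine-head morphology, uneven illumination and
photobleaching, z-dependent blur (rendering is 2-D, post-projection),
crossing structures from neighbouring cells, and genuinely ambiguous
protrusions below ~0.6 µm. Passing the recovery tests therefore shows the
chain is correct and well-calibrated under clean geometry and realistic
noise — not that it matches human tracing on arbitrary real data.

## Problem sizes used in validation

Validation experiments are scaled to remain quick while keeping the
acquisition parameters (pixel size, frame interval, SNR) at their target
values: recovery simulations use 45 µm segments over 61 frames (5 min) with
N0 = 15, F = 3, E = 2, L = 2 across 10 seeds; detection-accuracy fixtures
use 30 µm noiseless renderings with true lengths pinned across 0.7–9.3 µm;
bootstrap coverage uses 4000 replications at n = 15 per group with 1000
resamples; the type-I experiment uses 200 null datasets.

## Known limitations

* The shaft model assumes one dominant, roughly straight process; heavily
  branched dendrites would need per-branch masking upstream.
* Two protrusions closer than the linkage radius cannot be disambiguated by
  base position alone.
* Border-touching protrusions carry only a lower length bound (flagged).
* Cells excluded in practice for blebbing or focal loss cannot be detected
  reliably from intensity alone; the pipeline accepts an exclusion decision
  from the analyst and only flags suspicious frames.
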