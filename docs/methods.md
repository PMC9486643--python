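# Methods

This note documents the models, estimators and numerical choices
behind each analysis stage, the assumptions of the synthetic-data
generators, and the limits of what synthetic validation shows about
real microscopy data.

## Conventions and calibration

Pixel coordinates are 0-based, origin top-left, x rightward (the
direction of colony expansion in all edge analyses), y downward.
Times are minutes, lengths μm, areas μm², volumes μm³.  Defaults
follow a confocal setup scanning 1024 px over an 890 μm field
(0.869 μm/px), 10-min frame intervals, and 3.87 μm z-steps; all three
are explicit parameters everywhere.  Calibration travels in ImageJ-style
TIFF tags and a sidecar JSON; the sidecar wins on conflict because
third-party tools routinely strip TIFF tags.  Readers reject invalid
inputs (missing calibration, dangling pedigree links, non-monotone
track frames) rather than repairing them: silent repair of annotation
errors would propagate into the statistics.

## Initial doubling time

**Model.**  During early surface colonisation, ROI fluorescence is
taken as proportional to cell density, and growth is exponential:
*I(t) = I₀·2^(t/T)* with doubling time *T*.  As the field fills, the
curve saturates into a sigmoid.

**Estimator.**  The slope of log₂ *I(t)* in a sliding centred OLS
window (default 5 frames) has units doublings/min; the maximum over
windows, *g*, gives *T = 1/g*.  On an exact exponential this is
unbiased for every window position and length, and the estimate is
invariant to positive rescaling of the curve (so normalising to the
curve maximum, done for presentation, does not affect it).

**Numerical choices.**

* *Plateau exclusion*: windows containing any point above 0.9 of the
  curve maximum are excluded.  Logistic saturation biases the log-slope
  downward only, so exclusion cannot inflate the growth estimate; it
  simply removes windows that would never attain the maximum anyway,
  and protects against spurious slopes from plateau noise.
* *Background*: the default subtracts nothing.  Subtracting an
  estimate of the signal's own starting level distorts the early-time
  log-slope severely (log(I − I₀) diverges at t₀), which is exactly the
  regime the estimator relies on.  For real curves riding on an
  autofluorescent-agar baseline, `background="auto"` subtracts the
  minimum of the first three frames; this is appropriate when the
  first frames are baseline-only, i.e. growth has not yet produced
  signal.
* *No-growth*: a flat curve (max slope ≤ 10⁻⁹ doublings/min) raises a
  dedicated error instead of returning a huge doubling time.

On a noise-free logistic started at 10⁻³ of carrying capacity with
T = 258 min (4.3 h), the estimator returns 258.3 min; the +0.1 % bias
is the logistic correction (1 − I/K) over the earliest window.

## Edge expansion

Each frame is binarised with Otsu's threshold, recomputed per frame
because photobleaching and biomass accumulation drift the histogram
over multi-hour movies.  Connected components below `min_object_px`
(default 10 px, 8-connectivity) are removed so isolated hot pixels
cannot masquerade as the right-most edge — without this filter a
single bright noise pixel anywhere right of the front corrupts the
max-x statistic.  The right-most foreground x, converted to μm, forms
the edge trace; frames at or beyond x ≥ width − 2 px mark the front's
arrival at the far border, and later frames are excluded (the arrival
frame is kept — it is still a genuine observation).  The expansion
rate is the OLS slope of edge position against time over valid frames
(minimum 3).  Volumetric stacks are max-projected along z first.

Pixel quantisation bounds the error: the measured edge is
⌊x/0.869⌋ px, a uniform error of at most one pixel, which OLS averages
away — noise-free recovery is within 1 % for rates 0.5–5 μm/min at
30+ frames, and 0.1 % at 60 frames.

## Landmark motion

Tracks are truncated to the shortest track's length (earliest frames
kept) so pooled statistics compare a common observation window.  Step
sizes are per-interval Euclidean displacements; an |Δx| variant
isolates the radial component.  Per-track x/y components are the
max − min range of each coordinate (range of motion, not net
start-to-end displacement).  Distance to the edge uses the edge trace
of the same movie: *d(t) = edge_x(t) − x(t)*, and the OLS slope of
*d(t) − d(t₀)* classifies the track — |slope| ≤ 0.1 μm/min counts as
keeping pace, positive slopes as falling behind, negative as catching
up.  The 0.1 μm/min band is a design choice: the three categories are
qualitative, and the band is an order of magnitude below the wild-type
edge rate while absorbing tracking jitter.  Landmark positions are
consumed as given (manual or synthetic); no automated feature tracking
is attempted.

## Division pedigrees

A division interval is defined between the *first appearances* of a
parent's and a daughter's z-rings, so both daughters of one node
contribute one interval each ("division events").  Generation depth is
recorded so root→daughter intervals can be excluded via
`min_generation=2`: a root's true appearance may precede the start of
observation (left-censoring).  The default keeps all edges.  Sampling
quantises intervals to the frame grid; rounding to the nearest frame
bounds the per-interval bias by dt/2 (5 min at 10-min sampling), which
with ≥152 events keeps the recovered mean within dt/2 + 2·SE of truth.

## Morphometrics

**Footprint.**  Otsu segmentation of a reflected-light macro image,
keeping only the largest connected component (a colony is one object;
plate debris is not).  Area = pixel count × pixel size².

**Surface and volume.**  Z-stacks are segmented slice by slice (Otsu
per slice, because depth-dependent attenuation shifts the histogram
with depth).  Slices whose histogram is effectively single-class — a
deep slice entirely inside the biomass, or an apex slice entirely
above it — have nothing for Otsu to split, and a per-slice threshold
would cut through pure noise and erode ~1 z-step of surface; such
slices (≥98 % of pixels on one side of a whole-stack Otsu threshold)
are instead classified against that global threshold.  For each (y,x)
column the top surface is (max foreground z index + 1)·z_step above
the agar reference plane (z = 0 of the supplied stack; reference-plane
detection is deliberately out of scope, cropping is the caller's
responsibility).  The default volume fills each column from the
reference to its top surface — the biofilm as the solid under its top
surface, internal voids included; `mode="segmented-voxels"` counts
only segmented voxels instead.  Attributing a full z-step to the top
voxel overestimates each column by ~z_step/2 on average; ratios
between stacks sharing a z-step largely cancel this bias.

**Thickness ratio.** volume(late)/volume(early) for two stacks with
identical calibration.

**Internal flow.**  Per-interval Euclidean step / interval length;
per-track means are averaged so each landmark counts once regardless
of length.  The assay's native interval is 18 min.

## Group statistics

Dunnett's many-to-one procedure (via the multivariate-t distribution
of the comparison statistics) tests every mutant against the single
control per metric at α = 0.05.  No across-metric correction is
applied — each metric is an independent family.  Panels in which all
values are identical (zero variance) are reported as not significant
with a warning rather than erroring, so degenerate synthetic replicates
cannot kill a batch run; non-finite p-values from near-zero pooled
variance are treated the same way.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its spec including the seed, and
returns ground truth alongside the rendering.  Noise is additive
Gaussian, clipped at zero, applied after the geometry — the simplest
model that stresses Otsu thresholding.  Specifically:

* Fronts are hard steps (a pixel is foreground iff its x-position in
  μm is ≤ the true edge), advancing at exactly constant speed; this
  makes the segmentation oracle exact.  Real fronts are ragged,
  partially transparent, and accelerate.
* Growth-curve stacks are spatially uniform at the logistic value, so
  the ROI mean equals the curve exactly; real fields have spatial
  texture and the three-ROI protocol exists precisely to average it.
* Division intervals are Normal, truncated at one frame interval
  (mean ± SD is the level of detail available for the real
  distributions; no lognormal tail is modelled), and z-ring events are
  table rows — fluorescent spot rendering and detection are out of
  scope, matching the manual-annotation workflow.
* Volume stacks have noise but no depth attenuation, scattering or
  point-spread blur, so per-slice segmentation is easier than on real
  confocal data.
* Tracks follow drift / isotropic-Gaussian / mixture step models with
  no tracking error.

Passing recovery tests therefore demonstrates that the *estimators*
are correct and well-conditioned at realistic parameter values and
sampling; it does not validate segmentation against optical artefacts
of real microscopy.

**Generator conditions used in validation.**  Front recovery uses 60
frames at 10-min intervals, noise σ = 5 on a 10→100 background→
foreground contrast, image width sized so the front stays in-frame for
the whole movie (the far-border truncation path is exercised
separately).  Pedigrees use 11 roots × 4 generations = 154 edges
(matching the ≥152-events scale of a full strain dataset).  Volume
pairs use 48×48-column ramp height maps spanning 120–180 μm — a
realistic mature-biofilm thickness — at the 3.87 μm z-step, so the
half-voxel surface bias (~1.9 μm/column) stays well below the measured
fold-changes.  Flow uses 24 tracks over 15 h at 18-min intervals.
Doubling-time recovery uses a 280-frame noise-free logistic started at
10⁻³ of capacity.  These sizes run in seconds on one CPU.

## Known limitations

* Curved-front geometry is not modelled; fields are assumed oriented
  so radial growth is the x-axis.
* The edge is a single scalar per frame; multi-lobed fronts report
  only their right-most extreme.
* Volume estimation assumes the agar plane is z = 0 of the supplied
  stack and that attenuation does not extinguish the top surface.
* The doubling-time estimator assumes intensity ∝ cell density; it
  reports proxy doublings, not absolute counts.
* The pipeline's YAML config references files, not acquisition
  metadata; consistency of dt and pixel size across replicates is the
  caller's responsibility except where checked (thickness pairs).
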