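# Methods

`morphospec` profiles cellular morphodynamics from segmented time-lapse
movies in five stages: cell segmentation, cell-edge tracking, edge-attached
sampling windows, Hilbert–Huang spectral decomposition of the resulting
sector × time activity maps, and statistical region merging (SRM) of the
spectral features into motion regimens, optionally related to a windowed
biosensor signal by lagged cross-correlation.  This note records the models,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic tests do and do not establish.

## Segmentation

Frames are prefiltered with a Gaussian approximating the point-spread
function (`psf_sigma`, default 1.5 px) and thresholded at the first valley
of the smoothed intensity histogram after the lowest-intensity mode (the
background).  The histogram (default 128 bins) is smoothed with a spline;
modes must reach 5% of the peak and be separated by a valley dropping below
half the lower mode, which suppresses spurious smoothing wiggles; the
threshold is placed at the midpoint of the valley floor, since the floor
between well-separated modes is wide and flat and its argmin is noise.  A
unimodal histogram raises an error directing the user to
`threshold_override`.  Post-processing fills intracellular holes up to
`max_hole_area` (default 100 px², 8-connected), applies a morphological
closure (default radius 3 px) and keeps the largest 4-connected component,
so the mask always has exactly one foreground component.

## Edge tracking

The mask boundary is extracted with marching squares and resampled to one
node per boundary pixel.  The raw outline staircases at the pixel scale,
inflating arclength by ~4% and making tangents noisy; a circular Gaussian
smoothing of the node polygon (σ = 1 px) removes the quantization without
measurably shrinking features larger than a few pixels.  A periodic cubic
B-spline through the smoothed nodes provides sub-pixel positions, tangents
and an arclength parameterization.

Consecutive contours are divided into segments between their crossing
points.  Within each segment the correspondence minimizes total squared
displacement plus ω times the lateral strain (the squared ratios of node
spacings), subject to the constraint that displacement vectors never cross.
The unit-balancing factor ω = w·SUMA/SUMB is evaluated once at a
closest-point initialization (w is the user trade-off, default 1).  Because
the objective couples only adjacent nodes, the constrained minimization is
solved *exactly* on a discretized grid of candidate target parameters
(`grid_density` per node, default 4) by dynamic programming; the solution
is verified against exhaustive enumeration in the test suite.  Segments
longer than `n_max` nodes (default 50, valid range 10–100) are down-sampled
for the solve and the correspondence up-sampled with monotone
piecewise-cubic interpolation, which preserves the ordering constraint.
Contour pairs without crossings (including identical and concentric
contours) are handled as one periodic segment anchored at the target point
closest to the first source node.

Projecting each displacement onto the outward boundary normal (sign fixed
by probing the mask 0.5 px along the candidate directions) gives the signed
normal velocity, protrusion positive, in μm/min.  Nodes are reset every
time step; no continuous multi-frame marker paths are built.

Accuracy is bounded by rasterization: the true gap between the rasterized
outlines of two frames wobbles by about ±0.3 px around its nominal value,
so single-node velocities carry that error and ~10-pixel sector averages
carry roughly ±8% of a one-pixel step; the map-wide mean is accurate to a
few percent.  With congruent rasterization (integer-pixel translation) the
mapper's own error is below 0.1 px/frame.

## Sampling windows and activity maps

Both windowing methods build on the Euclidean distance transform of the
cell edge.  The *discrete* method assigns every cell pixel its distance to
the nearest boundary pixel and the arclength position of that boundary
pixel, then bins (distance, arclength) into bands and slices; within each
band the windows partition the band's pixels exactly.  A pixel whose
nearest boundary pixel is the origin itself (arclength 0) wraps to the last
slice; the slice axis is circular.  The *sub-pixel* method extracts
isocontours of the distance transform at the band levels by linear
interpolation, places slice start positions at arclengths along a master
contour (default: the edge), and ascends the interpolated
distance-transform gradient from each start with step 0.5 px until the
ascent crosses the deepest band isovalue (stall tolerance 1e-3 flags
distance-transform ridges).  Windows are the polygon pieces bounded by
adjacent isocontours and slice curves; pieces adjacent to a stalled curve
or within one pixel of the image border are excluded and logged.

Defaults follow the ~3 μm sector width and 3 μm band depth that match the
spatial autocorrelation of cell-edge motion.  Window propagation keeps the
band distances fixed and supports four origin/slice policies; the default
(`constant_slice_count`) preserves the slice count and rescales slice
widths with the edge length.  Velocity maps have N_t − 1 columns (one per
frame pair); biosensor maps N_t; regimen analysis aligns activity column t
with velocity column t, which introduces a half-frame (dt/2) offset into
measured motion–signal lags, well below the dt resolution of the lag axis.

## Hilbert–Huang spectra

Each activity-map row (temporal axis) and column (spatial axis) is sifted
into intrinsic mode functions: cubic-spline envelopes through maxima and
minima (the two nearest extrema mirrored about each series end), envelope
mean subtracted until a Cauchy-type criterion SD < 0.2 is met and the
extrema/zero-crossing counts balance, at most 100 sifts.  The component
count is fixed at six per axis so spectra are comparable across cells;
series that exhaust earlier pad with zero components, flagged in the
validity masks.  Completeness (ΣIMF + residual = input) holds to machine
precision by construction and is asserted to 1e-9 in the tests.

Instantaneous frequency is the central-difference derivative of the
unwrapped analytic-signal phase over 2π (scipy's Hilbert transform), and
amplitude the analytic magnitude; the first and last samples are marked
invalid.  The spatial axis follows the closed cell boundary and is treated
as periodic by default: each column is decomposed on a three-period
extension and the central period kept, avoiding artificial boundary
extrema (an `open` mode is available).  Spatial frequencies are reported in
cycles/sector, convertible via the sector width.  Negative instantaneous
frequencies — possible at weak-amplitude samples — are kept in the stored
fields but excluded from distribution summaries by default.

Per-IMF maps can be reconstructed on the grid, and their cumulative time
integral gives per-sector displacement series seeded at the first true
edge, which visualize what each IMF order contributes to the motion.

## Spectral profiling

Cells or subcellular regions are profiled by the pooled distributions of
instantaneous frequency and amplitude per IMF order and compared with the
two-sample Kolmogorov–Smirnov statistic D = sup|CDF₁ − CDF₂| (own CDF-sweep
implementation, verified exhaustively against a brute-force oracle on small
integer samples; asymptotic p-value).  Central frequencies are per-sector
medians (robust to spectral tails), summarized across sectors as mean ±
standard error.  Population heatmaps are pairwise D matrices, orderable by
mean absolute velocity.

The mapping-error robustness simulation perturbs a velocity map with
uniform noise on ±rate·Δ(s), where Δ(s) is the per-sector RMS inter-frame
velocity step — the scale of the worst topology-preserving mapping error, a
vector landing on a neighboring virtual marker (pluggable via `scale_fn`).
Re-decomposing the perturbed map and tracing the K-S distance of the IMF
frequency distributions against the original over rates 1%–100% yields a
monotone robustness curve.

## Statistical region merging

The feature vector φ(s,t) stacks the six temporal and six spatial
instantaneous frequencies, each weighted by its squared amplitude relative
to A_max — the maximum amplitude of the sector along time (temporal
channels) or of the time point along sectors (spatial channels).  The
normalizer is taken jointly over all IMF orders, so the quadratic weight
measures the relative energy of each component against the strongest
oscillation present; a per-order variant is available
(`normalizer='per_imf'`), but it erases the contrast between tone-carrying
and noise-carrying components of equal relative amplitude.

Before merging, channels are clipped to their physical frequency range
(zero to the Nyquist frequency of the axis) and mapped linearly onto
[0, R_max] (default 256).  Using the fixed physical range rather than the
per-map data range makes maps comparable across cells and keeps
heavy-tailed instantaneous-frequency outliers from compressing the scale —
with a data-range rescale, channels that carry only noise inflate to the
full range and violate the premise of the statistical merge bound.  The
field is then median-filtered over a persistence window (default 3 sectors
× 15 frames ≈ 9 μm × 2.5 min, circular along sectors): motion regimens
persist over minutes, and without the filter sample-level spectral noise
scrambles the ascending-dissimilarity merge schedule, letting
cross-boundary merges nucleate while regions are still small and the bound
is permissive.  The filter bounds the temporal localization of regimen
boundaries at roughly half the window.

Two adjacent regions (4-connected, circular along sectors, open along
time) merge when every channel's mean difference is below
√(T²(R₁)+T²(R₂)), with

    T(R) = √( R_max² · 2^−(Q+3) / |R| · [min(|R|, R_max)·ln(|R|+1) + ln(6·N_t·N_s)] ).

The structure of the bound follows the region-merging literature (size
penalty, region-count entropy, grid-size term); its overall unitless
constant is a calibration: it is fixed so that on maps of a few thousand
grid cells the delicacy range Q ∈ [0, 8] spans the full coarse-to-fine
regime — one or two regimens at Q = 0, shattered near-singleton regions at
Q = 8 — with the knee of the explained-variance curve near Q = 3, the
operating point used for regimen extraction.  Edges are processed in
ascending max-channel dissimilarity with deterministic lexicographic
tie-breaks, and the scan is iterated to a fixpoint (no pair of adjacent
regions still satisfies the criterion), so the partition is independent of
incidental schedule truncation.  Missing feature entries are imputed with
per-channel medians before clustering and reported.

The Q scan reports, per Q, the fraction of feature variance explained by
the partition (1 − SSW/SST averaged over channels) and the number of
regions; the knee estimate is the Q with the largest single-step gain.

## Motion–signal coupling

Per-regimen activity summaries group the windowed biosensor samples by
regimen label.  Cross-correlation uses Pearson correlation of
mean-subtracted series at integer-frame lags with pairwise-complete
samples and no prewhitening (the simplest defensible estimator; exposed for
replacement).  `xcorr(v, a)` correlates v(t) with a(t+lag), so a
positive-lag peak means the activity follows the motion; `regimen_xcorr`
reports curves on the mirrored axis conventional in edge-motion/signaling
studies, where *delayed* activity peaks at a *negative* lag.  Per-sector
curves are computed over maximal runs of at least 20 frames carrying the
regimen label and averaged without re-normalization.  The per-lag
significance bounds ±1.96/√n_eff are pointwise and heuristic (no
autocorrelation correction); the curve-level significance test applies a
Šidák correction over the number of lags, without which about half of all
white-noise curves would be flagged.  The full width at half maximum of the
dominant significant lobe is measured on the averaged curve with linear
interpolation between lag samples.

## Synthetic data

The generator produces three fixtures with closed-form truth: (i) a
deforming star-convex blob whose boundary radius is a sum of
raised-cosine-windowed sinusoidal modes, with analytic normal velocity
dρ/dt (exact up to a (∂θρ/ρ)² geometric correction, negligible for the
gentle deformations used), rasterized masks and foreground/background
images with i.i.d. Gaussian noise; (ii) an activity channel equal to
baseline + gain·v(θ, t − lag) within a band of the instantaneous edge,
emulating a biosensor coupled to motion with a known delay; (iii) planted
block-sinusoid sector × time maps for spectral and clustering tests.
Default conditions mirror a typical fibroblast time-lapse: 10 s frames,
0.3 μm pixels, ~14–15 μm cell radius, mode amplitudes 1–2 μm at 0.004–0.02
Hz, map noise 0.4 μm/min against 2 μm/min tones (SNR 5), a 50 s activity
delay.  Broadband (multi-mode, incommensurate-frequency) motion is used for
coupling fixtures because a single tone makes the lag ambiguous modulo its
period.

What the phantoms do not emulate: textured cell interiors, photobleaching
and uneven illumination, Poisson noise, non-star-convex shapes (no analytic
normal velocity there), biosensor photophysics, and the shape complexity of
real motile cells.  Passing tests therefore establish the correctness of
the computational chain under controlled conditions, not biological effect
sizes; headline distribution thresholds from real cell populations are not
reproducible from synthetic data and are not asserted anywhere.

## Problem sizes

The test suite and the acceptance script run on 96–128 px movies of 12–100
frames, 64 × 120 planted maps, and populations of 5–6 synthetic cells —
sizes at which every stage's contract (completeness, exactness of the DP,
partition recovery, lag recovery) is already fully exercised; all
quantities scale to larger inputs without algorithmic change
(the DP is O(n·G²) per segment with capped n, SRM is near-linear in grid
cells via union-find).
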