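# Methods

## Motion model and tracker

Cell displacement per frame along each axis is modelled as
Δx(t) = μₓ(t) + σₓ(t)·w(t), with w(t) zero-mean, unit-variance white noise
(Gaussian by default; uniform and Laplace alternatives are provided for
robustness checks), axes independent. Drift μ and volatility σ are the
expected value and standard deviation of the displacement. Assuming local
ergodicity, both are estimated per track from the most recent
T displacements: μ̂ is the window sample mean and σ̂² the mean squared
deviation from that window mean (population form, ddof = 0). The window
default is **T = 10 frames** — short enough to follow drift changes over a
few cell diameters of travel, long enough that the variance estimate has ~9
effective degrees of freedom.

Frame-to-frame linking minimizes total cost over one-to-one matchings
(Munkres algorithm via `scipy.optimize.linear_sum_assignment`), where the
cost of a candidate link is the inverse of the bivariate Gaussian density of
its displacement under the track's current (μ̂, σ̂²). Numerical choices:

- **σ-floor 0.5 px** (half a pixel) before evaluating the density, so a
  locally stationary cell cannot produce an infinite density.
- **Cold start** (fewer than one displacement): μ = 0, σ = 2 px, a population
  prior of the order of one cell radius per frame.
- **Gate**: a link is rejected when its cost exceeds the inverse density at a
  per-axis Mahalanobis distance of **4**; unmatched detections seed new
  tracks, unmatched tracks terminate (no gap closing). The textbook 3σ gate
  is too aggressive here: with T = 10 the variance estimate fluctuates like
  χ²₉/9, and an apparent 3σ excursion under an under-estimated σ̂ is common
  enough to cut a few percent of true links, fragmenting tracks (measured:
  95.7% link recovery at gate 3 vs 99.8% at gate 4 on 20 cells at σ = 1 px).
  The gate is config-exposed.
- Rectangular cost matrices are squared by augmenting with non-assignment
  rows/columns at the gate cost; entries are capped at 10¹² so sums stay
  finite. Frames are linked strictly pairwise i → i+1.

## Detection

Circular cells are found per frame by a circular Hough transform
(scikit-image) over the configured radius range, on an edge map obtained by
Otsu-thresholded gradient magnitude. Peaks above a normalized accumulator
threshold (default 0.5; a clean full circle scores ≈ 1) are kept by greedy
non-maximum suppression (no two detections within r_min) and refined to
sub-pixel centers by the centroid of the 3×3 accumulator neighborhood. Two
cell populations with well-separated radii (e.g. ratio ≈ 3) are detected
independently by running disjoint radius ranges.

## Trajectory images

Offsets from the reference point are rounded to the nearest pixel (halves
away from zero) on a (2R+1)² canvas; x is column, y is row, 0-based, with
the reference at the center pixel. Out-of-region points are clipped; a track
entirely outside the region is an error rather than a silent blank image.
The default region radius is the **98.5th percentile of Chebyshev offsets**
over the dataset, rounded up: nearly every point lands on the canvas while
rare excursions do not inflate every image. The marker is a single pixel per
position; revisited pixels collapse, so the white-pixel count never exceeds
the track length.

Reference points: the tumor-cell center (co-culture interaction studies),
the cluster geometric center (collective motility in clusters; clusters are
found by single-linkage agglomeration of track geometric centers with a
distance cutoff, reference = mean of member centers), or the track's own
center ("self" mode). Neighborhood assignment takes the nearest tumor center
within a radius of the track start, ties to the lower index; groups may be
capped at a member budget by nearest-first selection.

## Deep descriptors

Each binary image is resized bilinearly to 227×227, scaled to [0, 1] and
centered to [−1, 1], and pushed through conv(11×11, stride 4, 96) → ReLU →
maxpool(3×3, stride 2) → conv(5×5, pad 2, 256) → ReLU → maxpool(3×3, stride
2), the convolutional front end of the original-geometry AlexNet. The
flattened second-pool output is 13×13×256 = **43,264** features per image.
The network is a *fixed* feature extractor — never fine-tuned.

Weights come from a seeded He-scaled Gaussian initialization
(`fixed_seed_random`). Random convolutional features are a well-studied
fixed embedding that preserves exactly the local geometry (orientation,
curvature, density of strokes) that distinguishes trajectory images; the
`pretrained` weight mode falls back to the fixed-seed filters with a warning
when no compatible ImageNet weight source is importable, keeping the
pipeline fully runnable offline. Because the three input channels are
replications of one gray image, conv1 is evaluated with channel-summed
filters — mathematically identical, ~3× cheaper.

Dimensionality is reduced by the unsupervised variance criterion: by default
the lowest 50% of columns by variance are rejected (an absolute-threshold
mode exists). The selection mask is computed **on training rows only** each
fold and applied unchanged to test rows; labels are never an input.

## Classification and consensus

A linear SVM (C = 1, no class weighting) is trained per fold-turn under a
two-fold, video-exclusive protocol: videos are partitioned (stratified
alternation, or by experiment when replicate-experiment ids are supplied) so
that images from one video never straddle the train/test split. Treated is
the positive class. Per-track labels are aggregated by majority vote per
group and per video; ties break by the sign of the summed SVM margins, and a
zero margin sum defaults to untreated with a warning. Balanced accuracy
(mean per-class recall, in %) is reported at all three levels per turn and
averaged.

## Kinematic baseline

For each track (≥ 3 points): per-step speed, curvature (turning angle per
unit local arc length), angular speed, absolute turning angle, and distance
to the track's geometric center; each series is summarized by mean,
variance, skewness, excess kurtosis, and Shannon entropy (16 equal-width
bins over the series' own range, in bits; constant series → skew = kurt =
entropy = 0). Three scalars complete the 28-vector: mean distance to the
group center, diffusion coefficient (¼ of the OLS slope of MSD(τ) over the
first quartile of lags — note that for a 2D walk with per-axis step variance
σ² the MSD slope is 2σ², so this estimator converges to σ²/2), and
directional persistence (net displacement / path length ∈ [0, 1]). The exact
conventions for curvature, the MSD fit and the entropy binning are choices
of this package; the source literature does not pin them down. Δt = 1 frame
internally; physical units (min/frame, μm/px) are applied at reporting time.

## Synthetic data: what it emulates, what it does not

The simulator reproduces the statistical structure the pipeline assumes:
random-walk tracks with constant or reference-directed drift, two
experimental conditions differing in drift toward the group reference,
strongly right-skewed track lengths (truncated lognormal, default mean 50 /
std 35 frames inside a 150-frame window, matching the regime where mean
track duration is roughly a third of the observation period), uniform birth
frames, and renderable disk-shaped cells. Default conditions: untreated =
0.45 px/frame attraction toward the reference, treated = 0.08 px/frame,
volatility 1.0 px/frame on both axes — an overlapping-but-learnable regime
in which single-track classification is noticeably imperfect while group
and video consensus saturate, so the value of majority voting is visible.

Not simulated: cell division, death, shape change, mechanical interaction,
imaging artifacts beyond additive Gaussian noise. Passing tests on this
generator therefore demonstrate the pipeline's correctness and the
consensus mechanism under the stated motion model — not performance on real
microscopy, where detection errors, appearance changes and non-Gaussian
motion will lower all levels.

## Problem sizes

The bundled end-to-end experiment uses 4 videos per condition × 5 groups ×
40 tracks (1,600 trajectory images, 8 videos); detector/tracker checks use
up to 20 cells × 100 frames; estimator-recovery checks use 10³-step walks.
These sizes give stable statistics (binomial s.e. ≈ 1% at track level) while
keeping a full run in the minutes range on a single core.

## Known limitations

- The tracker has no gap closing and no appearance model; occlusions or
  missed detections split tracks.
- Fixed-seed random convolutional features are weaker than ImageNet-trained
  filters; with pretrained weights available, track-level accuracy would be
  expected to rise, with identical interfaces.
- Single-pixel rasterization discards time ordering and speed along the
  path except through pixel density.
- Video-level consensus is only as good as the fold design: with few videos
  per class its balanced accuracy is quantized in large steps.
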