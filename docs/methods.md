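# Methods

This note records the model choices behind `mammotex`, the conventions
that had to be pinned down where the underlying descriptor definitions
leave freedom, and what the synthetic-data experiments do and do not
demonstrate.

## Descriptor geometry and conventions

All descriptors operate on 2-D grayscale arrays in image coordinates:
x = column, y = row, 0-based, pixel centres at integers, y increasing
downwards.  Neighbour i = 1 of a sampling ring sits at angle 0 (east) and
the ring proceeds counter-clockwise on screen; bit i carries weight
2^(i−1).

**Sampling.**  Elliptical neighbour coordinates are real-valued, so a
sampling rule is required.  The default is bilinear interpolation (the
convention of the classic rotation-invariant LBP literature), in the
incremental form `v00 + tx·(v01−v00) + ty·(v10−v00) + tx·ty·(…)`, which
is exact when the four surrounding pixels are equal and exactly
equivariant under adding or scaling a constant intensity — properties the
invariance guarantees below rely on.  Nearest-pixel rounding (half-up) is
available as a config option.  Coordinates are snapped to 8 decimals so
float residue of `cos(π/2)` cannot decide a threshold tie; with this
convention the circular special case agrees bit-for-bit with
scikit-image's `local_binary_pattern(method="default")`, which serves as
an independent oracle in the tests.

**Orientation.**  theta rotates the canonical ellipse offsets about the
centre by a standard rotation expressed in image coordinates, so
theta = 90° swaps the roles of R1 and R2 on the pixel grid.  Under this
convention rotating a square image with `np.rot90` and adding 90° to
theta maps the sampling grid onto itself, making the code histogram
exactly invariant — the tests assert this within an L1 tolerance of 2%
but the implementation achieves 0.

**M-ELBP.**  Each neighbour coordinate is rounded to the nearest pixel
and the mean of the surrounding 3×3 window (odd sizes configurable) is
compared to the centre.  Internally the comparison is `window sum ≥
n·g_c`, which is sign-identical to the mean comparison but exact for
integer images.  With R1 = R2 the construction degenerates to a
mean-filtered circular LBP, not to LBP itself, so the exact circular
degeneracy is asserted only for ELBP.

**LDP.**  The Kirsch compass kernels are the standard set: the east
kernel has +5 in its right column and −3 elsewhere (zero centre), and
M_j rotates the +5 triple counter-clockwise in 45° steps.  Bit j (weight
2^j) is set when |m_j| ranks among the k largest responses; ties break
toward the lower index so codes are deterministic, and popcount(code) = k
always.  k defaults to 3, the convention of the directional-pattern
literature; LDP is computed at a single orientation since its responses
already span the eight compass directions.

**Margins.**  Codes are computed only where every sample (and, for
M-ELBP, every mean window) lies inside the image:
margin = ceil(max(R1, R2)) (+ half the mean window for M-ELBP), 1 for
LDP.  No padding is used, so histograms never contain extrapolated
values; the border ring is marked invalid and excluded.

## Features

Per orientation, the code histogram over valid pixels is L1-normalised;
blocks concatenate in ascending theta.  Normalisation (rather than raw
counts) makes features from 100-, 200- and 256-pixel ROIs comparable in
ROI-size sweeps.  The uniform mapping assigns the 58 uniform 8-bit codes
to bins 0..57 in ascending code order and all others to bin 58.

## ROI extraction

The breast mask is a deliberately simple stand-in for dedicated
mammogram preprocessing: global Otsu threshold, largest 8-connected
component, hole filling, and an optional straight-line corner cut
approximating pectoral-muscle removal.  This is a documented fidelity
gap: dedicated pectoral segmentation (contour growing with polynomial
fitting) is published prior work that the fibroglandular ROI rarely
touches, so a coarse cut suffices here.  The fibroglandular centre is the
(column of the longest vertical run, row of the longest horizontal run);
ties break toward the lowest index for determinism.  ROI crops clamp to
the image, and denoising is a 3×3 median with reflected borders.

## Feature selection

CFS correlations are symmetric uncertainties after equal-frequency
discretisation into min(10, √n) bins — the standard CFS configuration;
class labels are used as-is.  The merit of a size-k subset simplifies to
`Σr_cf / sqrt(k + 2·Σr_ff)`, which the search exploits to score all
add-one expansions of a node vectorised (one contingency sweep per
encountered feature column).  Best-first search keeps every generated
subset on a priority queue and stops after 5 consecutive non-improving
expansions (the customary backtracking allowance); on problems with ≤ 10
features it attains the exhaustive-search merit in all tested datasets.
If no subset achieves positive merit the single best-correlated feature
is returned, so degenerate (e.g. constant) feature sets never produce an
empty selection.  Selection defaults to running inside each training
fold; selecting once outside the folds is supported for comparison but
leaks test information.

## Evaluation

Stratified folds deal each class round-robin after a seeded shuffle,
with the remainder rotated across classes so fold sizes differ by at
most one (321 cases at 106/104/111 per class split 10 ways into folds of
32–33).  The "Bayesian network" classifier is realised as naive Bayes
over supervised-discretised features: Fayyad–Irani MDL cut points per
feature, then categorical naive Bayes with Laplace smoothing — the
discrete-classifier baseline that CFS-selected, weakly coupled features
reduce to; this is a documented fidelity approximation.  k-NN uses k = 5,
the SVM an RBF kernel with default regularisation, the random forest 100
trees; none of these are dictated by the task and all are logged in the
result provenance.  Accuracy is reported in percent (tables to one
decimal; full precision internally, run std with ddof = 1).  Az is the
prevalence-weighted mean of one-vs-rest rank-statistic AUCs computed per
run from out-of-fold probabilities.  Descriptor/classifier comparisons
use a two-sided Welch t-test at α = 0.05.

## Synthetic data

The generator emulates the visual signature of the three density
classes: fatty = dark and smooth, glandular = mid-intensity with mixed
blobs and weak strands, dense = bright and coarse with strongly oriented
fibres.  An image is base level + Gaussian blobs (Poisson-placed,
per-1000-px rate) + anti-aliased line segments with von Mises orientation
(concentration κ controls anisotropy) + Gaussian noise, clipped to
8 bits.  Class presets separate along blob density, streak anisotropy and
noise level *as well as* base intensity — necessary because the LBP
family is invariant to intensity shifts, so classes that differed only in
brightness would be invisible to it.  An `effect` parameter interpolates
every preset toward the glandular midpoint: effect = 1 gives the full
presets, effect = 0 makes all classes statistically identical (the
chance-level control).

What passing the synthetic experiments shows: the descriptor, selection
and evaluation stages are wired correctly, sensitive to planted texture
differences, monotone in effect size, and honest at chance level when no
signal exists.  What it does not show: performance on real mammograms —
real parenchymal patterns, scanner characteristics, labelling noise and
pectoral-muscle interference are all absent from the generative model.

## Problem sizes

The end-to-end experiments use 40 images per class at 128×128 px with
M-ELBP at 8 orientations (2048 features) and single-run stratified
10-fold CV; the effect-size sweep uses 15 per class at 64×64 with ELBP
and 3-fold CV over 3 effect levels × 5 seeds.  These sizes give stable
accuracy estimates for the strongly separated presets while keeping the
full suite quick to run.

## Known limitations

* The breast mask assumes a single bright breast on a dark background;
  heavily annotated or low-contrast films may need the pectoral cut and
  threshold policy adjusted.
* Whole-breast mode zeroes the background inside the bounding box, so
  background pixels participate in (and dilute) the histograms — matching
  the observation that whole-breast features underperform fibroglandular
  ROIs, but not a calibrated simulation of it.
* MDLP discretisation is univariate; correlated selected features are
  modelled independently by the naive Bayes stage.
* Whether ROI sub-crops (100/200 px) should be placed randomly within
  the 256-px ROI is underdetermined; seeded uniform placement is used.
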