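# Methods

This note documents the models, algorithmic choices and limitations behind
`lysoquant`, in the order data flows through the pipeline.

## Synthetic cells

The generator emulates a single adherent HeLa-like cell per field, imaged
in widefield or spinning-disc conditions, with exact ground truth for every
downstream measurement.

**Geometry.** The outline is star-convex: r(θ) = R·(1 + a·p(θ)) with R =
`cell_radius_px` (default 90 px in a 256-px field), a = `shape_irregularity`
(default 0.15) and p a random sum of cosine modes 2–5 normalized to
max|p| = 1. Star-convexity keeps the centroid well-defined and every radial
segment inside the cell, which the clustering model relies on.

**Radial clustering.** Each punctum's normalized centroid distance d ∈ [0, 1]
is drawn from the density ∝ d·(1 − d)^β — a Beta(2, β + 1) law — and placed
at fraction d of the boundary radius along a uniform angle. β = 0 recovers a
uniform distribution over the cell area (E[d] = 2/3); E[d] = 2/(β + 3)
decreases monotonically in β, so a single parameter moves puncta from
dispersed to perinuclear. No quantitative radial distribution of lysosomes
in real cells is published for these conditions; this family is a stand-in
chosen for its analytic tractability, not a claim about HeLa data.

**Intensities.** The organelle channel is background (default 400 grey
values) plus a diffuse cytoplasmic level inside the cell (default 300) plus
isotropic Gaussian spots (σ = 1.5 px, peak 8000). The cytoplasmic term
matters: real organelle stains ride on diffuse cellular haze, and the
saturated-threshold segmentation below identifies the cell by exactly that
haze. The Golgi channel carries a filled 2:1 ellipse adjacent to the
centroid covering `golgi_fraction` (default 8%) of the cell area; an
optional expression channel is uniform inside the cell. The camera model is
Poisson shot noise, then additive Gaussian read noise (default sd 60), then
clipping to the bit depth and quantization.

**Motility.** Mobile puncta (fraction `fraction_mobile`) advance a fixed
step `run_speed_um_s × frame_interval_s / pixel_size_um` per frame along a
persistent direction, resampled with probability 0.05 per frame and
whenever the step would exit the cell; immobile puncta jitter uniformly
within `confinement_radius_px` of their anchor. Defaults (1 frame/s,
0.16 µm/px at high magnification, runs at 1 µm/s) reproduce the observed
dichotomy between fast linear runs and short saltatory movements. There is
no photobleaching, fusion/fission, or 3-D structure.

**Render-free sampling.** `sample_profile_population` draws per-cell
cumulative profiles directly from the clustering law (the empirical CDF of
d at the decile radii √(k/10)), skipping rendering and segmentation. It is
the generator used for thousand-repetition simulation studies (null
calibration); single-condition experiments and power checks run the full
image pipeline. Problem sizes throughout (30 cells/group for distribution
experiments, 5 movies/group for motility, 1000 repetitions for calibration)
match the study designs the assays are meant for.

## Segmentation

"Saturate, then threshold" is implemented as: clip the image at
`saturation_factor` (default 2) times its median, then Otsu-threshold the
clipped copy, keep the largest connected component and fill holes. For a
single-cell field the median estimates the camera background, so the clip
collapses cytoplasm and bright organelles onto one foreground level; a
plain Otsu threshold on the raw image would instead segment the puncta,
whose contrast against everything else dominates the histogram. When the
median is zero the clip falls back to the `saturation_quantile` (default
0.99) intensity quantile. The procedure is invariant to multiplying the
image by a positive constant. Known failure mode: cytoplasm within about
two noise standard deviations of background (IoU against ground truth drops
from ≥0.95 to ~0.3 in synthetic tests); such images need externally
supplied masks, which every stage accepts (TIFF or ROI-polygon CSV).

Background subtraction removes the median intensity outside the mask and
clamps at zero; it is idempotent. A rolling-ball filter was deliberately
not used — the flat-background camera model does not need one, and the
median is robust and exactly testable.

## Decile regions and profiles

The boundary polygon (longest 0.5-level contour) is scaled about the
binary — not intensity-weighted — centroid by √f, rasterized, clipped to
the full mask, and nesting is enforced from the outside in. The
outermost region is the input mask itself. Achieved area fractions are
recorded; a deviation beyond ±0.02 of target raises a warning rather than
an error, because strongly non-convex shapes (e.g. crescents whose centroid
falls outside the mask) cannot meet the tolerance under centroid scaling.
On circular and star-convex masks the achieved fractions are within ~0.002.
Distance-transform shells were rejected as an alternative: the assay is
defined by geometric scaling of the perimeter, which weights all directions
equally rather than following local boundary curvature.

Profiles are y[k] = (intensity inside region k)/(intensity inside the
cell), with (0, 0) prepended; they are scale-invariant, non-decreasing and
end at 1 by construction, and equal a brute-force per-pixel accumulation
exactly.

## Curve statistics

The centred 6th-order polynomial is fitted by ordinary least squares to the
pooled per-cell points (11 per cell including (0, 0)); x₀ = 50 (the
midpoint of the 0–100 axis) minimizes collinearity on this fixed grid. The
fit is unconstrained: the endpoint conditions are enforced on the data, not
the model. The extra sum-of-squares F-test compares one shared fit against
per-group fits, F ~ F(df_shared − df_separate, df_separate). The t-test for
scalar metrics is pooled-variance by default with a Welch option.

**Calibration caveat (measured, not hypothetical).** Under its own model —
independent Gaussian errors at every point — the F-test's simulated type-I
error is 0.045–0.055 at α = 0.05 (1000 reps). Under the cell generator's
null (two populations of 30 cells from the identical condition) it rejects
at ≈0.22: the 11 points of one cell are computed from the same sampled
puncta, so errors are correlated within cells, the effective number of
independent observations is closer to the number of cells than to the
number of points, and the pooled F-test — which divides by a residual
variance that treats all points as independent — is anti-conservative. The
inflation depends only on the correlation structure of an empirical CDF at
the decile radii, not on the number of puncta, so no realistic generator
setting removes it. `analysis/05_ftest_calibration.py` reproduces both
numbers. Practical reading: pooled-design p-values order effect strengths
but overstate evidence; genuine biological contrasts in these assays
produce F statistics orders of magnitude beyond the inflated null, so the
qualitative conclusions are unaffected. A cell-level summary statistic
(e.g. comparing per-cell y(50%) by t-test) is the calibrated alternative
the library also supports.

## Colocalization and Golgi overlap

Spot detection is scale-space Laplacian-of-Gaussian (σ between 1 and 3 px,
threshold relative to the in-mask maximum) with sub-pixel refinement by
local intensity centroid. Detection parameters have no published reference
values; they are calibrated against generator ground truth (isolated spots
are recovered to <1 px; dense perinuclear clusters merge, so detected
counts undercount true puncta at high clustering). Matching is greedy by
increasing pair distance with lexicographic tie-breaks, which makes the
score symmetric and deterministic; at the assay's punctum densities greedy
matching agrees with optimal assignment. The positivity threshold is 5
matched puncta per cell, exposed as a parameter. The Golgi region is Otsu
inside the cell mask, morphological closing, largest component; overlap is
the intensity fraction inside that region, bounded in [0, 100]% and
invariant to intensity rescaling.

## PCC decay

Frame 0 is the fixed reference throughout (never sliding). Each frame is
Otsu-thresholded inside the cell mask; the default evaluation set is the
union of above-threshold pixels of the two frames. The union avoids biasing
the set toward persistent structures, but it has a known selection
property: for completely independent frames the union-set correlation sits
at a negative baseline (pixels chosen for being bright in either frame are
anti-correlated by construction), so fully decorrelated movies plateau
below zero rather than at zero. `intersection` and whole-`mask` modes are
provided; the mask mode is unbiased and is used when the raw statistic
itself is of interest. The decay curve is summarized by
pcc(t) = P + (1 − P)e^(−kt) with P ∈ [−1, 1], k ≥ 0, fitted by bounded
least squares; the constant curve (k = 0) is nested within the model, and a
perfectly constant input short-circuits to k = 0 exactly. On noisy
synthetic curves (sd 0.02, 120 points) the rate is recovered within 10%
(max error ~6% over 50 seeds). Group comparison reuses the extra
sum-of-squares F-test with the decay model; the same within-curve
correlation caveat applies.

## Reproducibility

All randomness flows from integer seeds through `numpy` Generators;
per-cell and per-condition seeds are derived deterministically (conditions
derive their seed from the master seed plus the condition's parameters, so
a duplicated condition reproduces identical cells and compares at F = 0,
p = 1). Experiment outputs embed a hash of the serialized config and no
timestamps, so re-runs are byte-identical.

## What passing tests do and do not show

The synthetic data exercise every code path with known truth, but they are
idealized: flat illumination, a single cell per field, isotropic spots, no
focal drift or bleaching, and a one-parameter radial law. Passing tests
demonstrate the measurements are correct and well-calibrated on data
satisfying their assumptions — not that the biological effect sizes or the
detector settings transfer to any particular microscope without checking
segmentation IoU and detection recall on that instrument's images.
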