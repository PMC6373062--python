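# Methods

`papscreen` implements an automated screening pipeline for bright-field
cervical cytology (Pap-smear) images: contrast enhancement, trainable
pixel-level scene segmentation, three-phase debris rejection, nucleus and
cytoplasm morphometry, wrapper feature selection by simulated annealing, and
classification of cells into seven cytological classes (three normal, four
pre-malignant/malignant) with a fuzzy C-means model defuzzified through
Bayes' rule. This note records the model, its assumptions, the parameters
that matter, and the choices made where the design was genuinely open.

## Enhancement

Colour images are converted with the perceptual weighting
`gray = 0.3 R + 0.59 G + 0.11 B`, kept real-valued, and enhanced with CLAHE.
The clip limit is expressed in the classical convention — multiples of the
mean histogram bin height of a tile — with default 2.0 on an 8x8 tile grid
and 256 bins; internally this maps onto scikit-image's normalized clip
parameter as `clip/nbins`. A constant image is returned unchanged (there is
no contrast to redistribute). Intensities are quantized to 8 bit only on
file export.

## Scene segmentation

Each pixel is described by a filter bank covering three families: noise
reduction (Kuwahara at radii 2 and 4; bilateral), edge structure (Sobel
magnitude; Hessian eigenvalue pairs at sigma 1 and 2; zero-mean Gabor
magnitudes at 4 orientations x 2 frequencies), and local texture (mean,
variance, median, maximum, minimum and entropy at radii 2, 4 and 8) — 35
responses in total. The Gabor kernels have their DC removed so that constant
images produce identically zero edge responses. A seeded random forest (200
trees) is fitted on feature vectors sampled at scribbled pixels only and
predicts per-pixel probabilities over the four scene classes nucleus,
cytoplasm, background and debris; labels are the argmax, with ties broken in
that declaration order. The reference interactive tool's exact 226-feature
stack is not enumerated anywhere; fidelity here is to the named filter
families, and the bank is configurable.

The pipeline (but not the bare `segment_scene` default) applies a small
Gaussian regularization (sigma 1 px) to the probability planes before the
argmax; this suppresses single-pixel speckle while preserving the invariant
that labels equal the argmax of the stored probabilities.

## Debris rejection

Candidate objects are 8-connected nucleus components with any touching
cytoplasm component attached. Three gates run strictly in order; an object
reaches a later gate only if it passed the earlier ones.

* **Size.** Whole-object area must lie in [625, 85 267] area units,
  inclusive. Areas are pixel counts times a configurable squared linear
  scale so that the thresholds compare directly with the reference
  pixel-count statistics (the upper bound equals the superficial-class
  cytoplasm mean plus one SD; treating the printed µm² label literally would
  make the thresholds inconsistent with the same table).
* **Shape.** The perimeter-squared-over-area descriptor as printed cannot
  lie in (0.15, 0.97) — p²/A >= 4π for any region — so the gate uses the
  normalized circularity 4πA/p² in (0, 1], which makes the printed band
  meaningful: fibres fall below 0.15, near-perfect circles (droplets, blood
  cells) above 0.97. The raw p²/A value is stored alongside. Perimeters are
  measured on the outer 8-connected contour through pixel centres (Moore
  tracing, diagonal steps √2); on this convention a 10x10 square measures
  36 and a digital disk's circularity is stable to <2% between radii 20 and
  40.
* **Texture.** Zernike moments A_nl (orders n <= 9, repetitions l >= 0 with
  n−l even, evaluated on the unit disk inscribed in an m x m window, default
  m = 25) are computed in windows centred on nucleus pixels; the texture
  score is the mean |A_nl| over windows and index pairs. Windows are centred
  on nucleus-*interior* pixels (the evaluation region is eroded by up to the
  window radius, adaptively for small nuclei): nuclear stain is texturally
  homogeneous, and without the erosion the nucleus/cytoplasm boundary step
  dominates the score. Intensities are scaled to [0, 1]; moment magnitudes
  are rotation-invariant and — deliberately — insensitive to uncorrelated
  pixel noise, so the score responds to *structured* intensity variation,
  which is exactly what distinguishes folded/overlapping debris from nuclei.

The texture threshold is not stated numerically anywhere; two policies are
provided. `AUTO` applies an exact (unbinned) Otsu split to the score batch
(or to a supplied training-reference sample) and gates only when the split
is a genuine two-population separation: the gap at the split must be at
least half the score range and the above-threshold group must be the
minority (debris is the high-scoring minority; without these guards a
homogeneous all-nuclei batch would lose its highest-scoring members). A
fixed numeric threshold can be supplied instead; the screening pipeline
calibrates one as 1.2x the maximum score observed on known training cells.

## Morphometry

Twenty-nine features per cell. Operational definitions fixed here: shortest
diameter = largest inscribed circle (distance transform), longest diameter =
minimum enclosing circle (convex hull + exact bounding circle); elongation =
their ratio; roundness = area over the enclosing circle's area (clamped to 1
against sub-pixel discretization); regional intensity extrema counted under
a radius-3 disk; histogram statistics (mean, SD, variance, entropy, energy,
smoothness) on the 256-bin normalized histogram of mask intensities measured
on the enhanced image; eccentricity from second central moments; solidity =
area over convex hull area; compactness = 4πA/p² with the same perimeter
convention as the debris gates; relative position = nucleus-to-cell centroid
offset over the cell's longest radius; N/C ratio = NA/(NA+CA), which is 1
when no cytoplasm is attached. Cytoplasm area and gray level cover
cytoplasm-only pixels, while cytoplasm geometry (diameters, roundness,
perimeter) is measured on the filled whole-cell region — the convention that
matches how the reference statistics tabulate whole-cell sizes. Cells
without recovered cytoplasm carry NaN in the cytoplasm columns and are
excluded from training statistics rather than imputed.

## Feature selection

Subsets are scored by the stratified k-fold cross-validated
misclassification rate of the downstream fuzzy C-means classifier (the
wrapper's black box). Simulated annealing searches the subset lattice with
single-bit flips (redrawn if a flip would empty the subset), geometric
cooling T <- 0.95 T after 20 moves per temperature from T=1 down to 1e-3,
and acceptance probability exp(−Δ/T) for worse moves; the cooling schedule
is not specified by the reference method and these are conventional,
fully-seeded defaults. Fitness uses one fixed CV seed, so it is a
deterministic function of the subset, results are cached, and on an
8-feature benchmark the search provably reaches the exhaustive 255-subset
optimum. Features are z-scored with training-split statistics before any
distance computation (raw features span four orders of magnitude). The
18-feature operating subset reported for the reference data ships as
`REFERENCE_SELECTED_FEATURES`; a fresh search is data- and seed-dependent
and need not reproduce it. The package reports subset stability across
reruns (per-feature selection frequency) as the post-hoc selection
diagnostic.

## Classification

Fuzzy C-means with memberships

    m_ik = 1 / sum_j (d_ik / d_jk)^(2/(q-1)),

Euclidean distances, membership^q-weighted center updates, convergence on a
1e-5 max center shift or 300 iterations, and seeded farthest-point
initialization with best-of-restarts selection by final objective (default
60 restarts). Memberships are computed in log space because the default
fuzzifier q = 1.0930 makes the exponent 2/(q−1) ≈ 21.5; a point coinciding
with a center receives full membership there. The objective
sum m^q d² is non-increasing across iterations and is asserted on traces.

Defuzzification: training points are hard-assigned to their
maximum-membership cluster; the per-cluster class composition gives
likelihoods P(cluster | class) with Laplace smoothing alpha = 1 (small
clusters should carry little influence, and smoothing prevents zero
posteriors); class priors are proportional to class mass; Bayes' rule and
per-cluster normalization yield P(class | cluster). A new point's posterior
is its membership vector mixed through these per-cluster posteriors. The
crisp class is the argmax (declaration-order tie-break) and the binary
screening label follows the normal/abnormal grouping of the seven classes.
Default cluster count is 25, mirroring the reference operating point; the
cluster-count-versus-CV-error analysis is available
(`choose_cluster_count`), and the fuzzifier is treated as the same quantity
as the reported defuzzification exponent. A slide is called positive when at
least `min_abnormal` (default 1) cells classify as abnormal.

## Evaluation

Abnormal is the positive class. Sensitivity, specificity, accuracy and
their complements (FNR, FPR, classification error) are computed from
TP/FP/TN/FN as percentages, rounded half-up to two decimals only at
reporting. The ROC sweeps thresholds over the abnormal-posterior scores with
trapezoidal AUC, which equals the Mann-Whitney concordance statistic (tested
against an independent pairwise oracle). Segmentation overlap uses the
Zijdenbos similarity index 2|A∩B|/(|A|+|B|).

## Synthetic data

The generator ships the reference per-class statistics (mean and SD of
nucleus area, cytoplasm area, N/C ratio, nucleus/cytoplasm brightness and
perimeters for the seven classes, in pixels of the 0.201 µm/px reference
resolution). Feature tables sample each primary statistic as an independent
truncated Gaussian (areas positive, ratios in [0, 1], brightness in
[0, 255]); the remaining features are synthesized from a near-elliptical
cell model — semi-axes solved from (area, perimeter) by inverting
Ramanujan's perimeter approximation, diameters/elongation/eccentricity from
the axes, histogram features from a per-class nuclear texture dispersion
(SD 4 gray levels for normal classes, 9 for abnormal; chromatin in
dysplastic nuclei is coarser) — with small seeded jitter. A sampled
perimeter below the circle minimum for its area is geometrically infeasible
and is replaced by an area-derived value; this applies in particular to the
carcinoma-in-situ cytoplasm perimeter, whose shipped value (28 ± 67) is kept
verbatim from the reference table but is impossible for its cytoplasm area.
An optional correlation knob couples nucleus area with the N/C ratio;
otherwise features are independent within a class, because the reference
table gives marginals only.

Rendered scenes draw each cell as a cytoplasm ellipse with an interior
nucleus ellipse, sized and shaded from the same sampled parameters, packed
on a bright background with additive Gaussian noise. Two renderer-only
conventions depart from the raw marginals for physical realism: the nucleus
is forced at least 30 gray levels darker than its cytoplasm (stained
chromatin is always darker; independent marginals would invert the contrast
for roughly one columnar cell in six), and the whole-cell aspect ratio is
capped at 0.90 (a rasterized near-circle lands on the 0.97 circularity gate
edge). Debris archetypes are constructed to trip one gate each: dark specks
below the minimum area, thin fibres with circularity below 0.15, and
"noisy blobs" filled with coarse black/white blotches whose structured
variation drives the Zernike score far above any nucleus. The manifest
records every object's class, masks and calibrated area, and the generator
asserts its own gate-tripping guarantees.

What the generator does **not** emulate: overlapping and folded cell clumps,
staining gradients and colour variation, out-of-focus blur, and feature
correlations beyond the optional area/N-C knob. Passing end-to-end tests
therefore demonstrate that the pipeline machinery is correct and
well-calibrated under the reference class statistics, not that the reported
clinical accuracies transfer to real smears.

## End-to-end benchmark

`synthetic_end_to_end` trains on one rendered scene (40 cells per class) and
screens a second (20 per class, i.e. 140 cells, plus debris), both at render
scale 0.4 relative to the reference resolution — the problem size chosen for
the benchmark; measured pixel counts are converted back to reference units
through the inverse scale. Training runs the same measurement pipeline as
inference (segmentation-derived masks, labelled by matching detected objects
to the manifest by nucleus-mask overlap), which matters: a classifier
trained on ground-truth masks loses ~15 accuracy points at test time because
segmentation-derived features are systematically shifted. The screening
pipeline adds four segmentation post-processing steps, all defaults of the
pipeline module only: probability smoothing (above), merging of nucleus
fragments that share a cytoplasm component, morphological closing (radius 2)
of object masks before measurement, and a per-cell Otsu refinement of the
nucleus boundary inside a local window (the pixel classifier delimits cells
reliably but places the nucleus boundary noisily, and the N/C ratio is the
most diagnostic feature). Cells whose cytoplasm is not recovered are
classified by a nucleus-only fallback model in which the N/C ratio is 1 by
definition — the correct inductive bias, since a bare heavily-stained
nucleus is the high-N/C phenotype.

Binary (normal/abnormal) per-cell accuracy on this benchmark is 89–93%
across seeds; an unrecovered cell counts against accuracy unless its true
label is normal (a lost cell never raises an alarm). The residual errors
are concentrated where the reference statistics genuinely overlap —
columnar cells versus the small-cell dysplastic classes share nucleus area,
brightness and perimeter distributions almost completely — and the ceiling
with ground-truth masks is about 94%. Seven-class accuracy is much lower
(~55–60%), as expected from the same overlaps; the binary screening decision
is the clinically relevant output.

## Numerical and degenerate-input conventions

Argmax ties anywhere break by declaration order. Empty masks, empty
subsets, single-class truths, unfitted models and mismatched dimensions
raise typed errors (`ConfigError`, `DataError`, `ContractError`; the CLI
maps them to exit codes 2/3/4). Zero distances in membership computation,
zero histogram bins (0·log 0 := 0), all-empty ZSI masks and sub-two-object
AUTO texture batches are each handled explicitly as documented in the
respective docstrings. Every stochastic step — scene rendering, table
sampling, scribble sampling, forest training, annealing, clustering
restarts, CV splits — takes an explicit seed and is bit-reproducible.
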