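# Methods

## The measurement model

A colposcopic examination is modeled as a grayscale image sequence
`I(x, y, t)`: `n_baseline = 10` frames before acetic-acid application and
`n_post = 180` frames after it, at 1 frame/s (3 minutes), 352×240 px. The
acetowhite response function (Awrf) of a tissue region is the region's mean
intensity per frame. All downstream analysis operates on the post-acid
segment standardized to percent change relative to the basal value, defined
as the **mean of the 10 baseline frames** (a single reference frame would
work too, but the mean is less noise-sensitive; the choice is isolated in
`standardize`).

## Whitening kinetics

The standardized response is summarized by a five-parameter linear model on
time scaled to [0, 1] over the post-acid segment:

    f(t) = θ0 + θ1·√t + θ2·t + θ3·t² + θ4·t³

The √t term captures the fast initial whitening onset; the polynomial tail
captures the slower fade. The basis lives in one place
(`representations.design_matrix`) so an alternative five-function basis can
be swapped without touching the fitting, which is ordinary least squares
(`numpy.linalg.lstsq`). Scaling time to [0, 1] keeps the θ magnitudes
mutually comparable regardless of sequence length. Three of the five
representations derive from this model: the fitted curve evaluated on the
grid ("adjusted"), the coefficient vector θ ("parameters"), and the
standardized series itself.

Note the basis is strongly collinear on [0, 1] (√t, t, t², t³ correlate
highly), so individual θ̂ have large sampling variance under noise even
though the fitted curve is stable. The Monte-Carlo recovery test therefore
checks unbiasedness (mean θ̂ within 3 standard errors of truth over 100
replicates), not per-replicate closeness.

## Discretization

A discretization scheme is a set of strictly increasing segment end-indices
tiling the post-acid axis (variable word sizes) plus value thresholds:

- **PLA** maps each segment's mean to the half-open alphabet interval
  containing it (lowest/highest intervals unbounded); symbols are
  `0 … alphabet_size−1`.
- **PSA** maps each segment's least-squares line slope (computed on the
  scaled time grid; endpoint differences would be noise-dominated) through
  six thresholds, symmetric about zero, onto `{−3…3}`; the central interval
  is "no change". A one-point segment has undefined slope and maps to 0.

Alphabet cuts default to equal-frequency quantiles of pooled training
segment means; PSA thresholds to symmetrized 25/50/75% quantiles of absolute
training slopes (with an epsilon ramp to keep them strictly increasing on
degenerate data). Both are calibrated on training data and stored with the
scheme (`calibrate_scheme`), never recomputed at prediction time.

The scheme itself is chosen by a mutation-only evolutionary program
(`scheme_search`): each parent spawns one mutant — perturb one boundary,
insert or delete a boundary, or move the alphabet size by one — fitness is
stratified k-fold (default 5) CV accuracy of the downstream classifier
(default 1-NN) on the PLA encoding of the training set, and elitist
truncation selection keeps the best `population_size` of parents ∪
offspring. Fitness ties break toward fewer segments, then a smaller
alphabet: compression is the point of discretizing. Defaults (population 20,
50 generations, boundaries ≤ 30, alphabet 2–10) are config-exposed; the
pipeline uses a lighter 10×15 setting, which on the synthetic cohort already
reaches its fitness plateau within a few generations. The whole search is
deterministic given its seed.

## Registration

Patient motion between frames is treated as pure integer-pixel translation.
For each consecutive pair, the shift maximizing normalized cross-correlation
of a fixed window (default: the central 50% of the frame) is found by
exhaustive search over [−max_shift, max_shift]² (default 10 px); ties break
toward the smallest squared shift, then row-major order. Shifts are
accumulated and each frame is translated by the negated cumulative estimate
(edge-replicated fill), aligning everything to frame 0. No subpixel
refinement: with integer ground-truth jitter the inverse is exact, which the
tests exploit for bit-level checks. A constant-intensity window makes NCC
undefined and raises `DegenerateWindowError` rather than returning an
arbitrary shift.

## Classifiers

All three learners are implemented here, mirroring their WEKA counterparts'
defaults: 1-NN with Euclidean distance (distance ties by training order,
vote ties by class order; scores are Laplace-smoothed neighbor frequencies
so even k=1 produces a graded score for ROC curves); naive Bayes with
Gaussian conditionals for continuous attributes (sample variance, floored at
1e−6 and logged when a within-class attribute is constant) and
Laplace-smoothed categorical conditionals for symbols; and a C4.5-style tree
using gain ratio, multiway splits on symbol attributes, binary
midpoint-threshold splits on continuous ones, a minimum of two branches
carrying ≥ `min_leaf` (default 2) cases, and optional pessimistic-error
subtree replacement (confidence 0.25) that is off by default to keep the
core deterministic and simple. k for KNN defaults to 1 and is exposed.

## Evaluation

Metrics follow WEKA's "Detailed Accuracy By Class": per-class one-vs-rest TP
rate, FP rate, precision, recall, F-measure, MCC, ROC area (Mann–Whitney
rank form with midranks for ties) and PRC area (step interpolation over
score thresholds); weighted averages weight by actual class size (whence
weighted TP rate ≡ overall accuracy, an identity the tests check). Metrics
undefined through an empty margin are reported as 0 and flagged — this is
what makes the never-predicted classes' precision rows zero rather than NaN.
Headline binary proportions carry Wilson 95% intervals. Cross-validation is
stratified k-fold (default 10) with a rotating fold pointer carried across
classes so fold sizes differ by at most one; a class smaller than k triggers
a warned fallback to unstratified folds. Printed percentages use half-up
rounding to integer percent, which reproduces the published headline values
exactly from their matrices.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes: per
class, a θ vector of whitening kinetics (peak percent change ordered
HSIL ≈ 32 > LSIL ≈ 20 ≳ ectopy ≈ 16 ≳ inflammation ≈ 13 > atrophy ≈ 5 >
normal ≈ 1, hand-set so that the benign reactive classes confound with LSIL
as clinically observed), additive Gaussian lighting noise (SD 2 gray levels
≈ 2% of the basal 100), a one-cycle sinusoidal illumination drift (amplitude
1, random phase), integer translational jitter (SD 1 px by default), and the
reference cohort composition of 200 cases (93 positive). Image sequences
place rectangular tissue regions (uniform intensity = the class's simulated
Awrf plus a static zero-mean texture, so region means are exact) on a static
smooth-plus-mid-frequency textured background; the texture is what makes the
NCC peak sharp.

What the generator deliberately does **not** contain: between-patient
variability of the kinetics within a class, non-rigid deformation, specular
reflections, glare, mucus, or color/optics effects. Consequently the
synthetic classes are far more separable than real tissue — cross-validated
accuracies near 1.0 against the published ~0.70 — and passing tests
demonstrate correctness of the machinery (registration, encoding,
classification, scoring), not clinical performance. Clinical-scale results
enter the test suite only through the published confusion matrices, from
which every derivable metric is reproduced at printed precision.

## Problem sizes and determinism

Default problem sizes — 200 series of length 190; 80×100 px, 50-frame
sequences for registration checks; 100 replicates for Monte-Carlo recovery;
population 10 × 15 generations for the pipeline's scheme search — keep the
full default pipeline run around ten seconds on one core while exercising
every stage at the reference cohort size. Every stochastic component draws
from `numpy.random.default_rng` seeded from a master seed via per-stage
SHA-256-derived sub-seeds (`PipelineConfig.subseed`), so re-running a
pipeline with the same config reproduces all artifacts bit-identically.

## Known limitations

- The evolutionary scheme search is a reconstruction of the cited
  single-parameter word/alphabet optimizer from its description; operator
  set, population model and fitness are this package's own choices, all
  config-exposed.
- The five-function basis is one reading of an ambiguous printed model; the
  design-matrix indirection exists precisely because other readings are
  defensible.
- ROC/PRC areas of the original study are not reproducible without the
  original data and are reported only for synthetic runs.
- C4.5 pruning implements subtree replacement only (no subtree raising), and
  missing values are not supported anywhere.
- Registration assumes pure translation; rotation, scaling, and non-rigid
  motion are out of scope.
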