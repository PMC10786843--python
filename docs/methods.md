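# Methods

`crowdcell` models a crowdsourced workflow for labeling erythrocyte
morphology in peripheral blood smear (PBS) images from sickle cell disease
(SCD) patients: individual cells are cut out of smear images, each cell is
labeled by k non-expert annotators as *circular* (normal), *elongated*
(sickle) or *other* (any other deformation), and the per-cell label is
decided by plurality consensus.  The package implements the consensus
rule, the evaluation metrics used to compare crowd labels against expert
ground truth, a binomial model of consensus accuracy under annotator
independence, the Chan–Vese cell-extraction stage, and synthetic
generators that emulate both the images and the annotators.

## Consensus model

Each cell receives exactly `k` votes (default `k = 5`; `k` must be odd and
at least 3).  The plurality label wins if its count reaches the strict
majority `floor(k/2) + 1` — 3 of 5 — otherwise the cell is recorded as
*no answer* (N/A).  For `k = 5` the attainable vote configurations are
`5`, `4-1`, `3-2`, `3-1-1` (all valid) and `2-2-1` (no answer); the winner
is always unique when the threshold is met.  Cells are stratified by
agreement level (5, 4, 3, N/A), which serves as a reliability signal: the
packaged experiment counts are 463 / 226 / 135 / 24 cells, summing to the
848-cell total, and the 3-agree plus N/A cells (159/848 ≈ 19%) are the
fraction flagged for specialist review.  Panels with fewer than `k` votes
are rejected rather than aggregated, and unknown label strings are parse
errors — silent coercion would corrupt confusion counts downstream.

## Evaluation metrics

Confusion matrices have rows = expert ground truth and columns = predicted
label, in the fixed order (circular, elongated, other), or (circular,
deformed) after merging.  When consensus output is scored, no-answer cells
occupy a dedicated trailing column: they stay in each class's denominator
and never count as correct, so "aggregated" accuracy penalizes
indecision.  Per-class accuracy is recall (diagonal over row sum); a class
with no ground-truth cells is reported as missing, never as zero.

* **SDS-score** (sickle-cell-disease diagnosis support): `N / (N + Ec)`
  where `N` counts all true positives plus elongated↔other swaps (either
  way the patient is flagged as having deformed cells, which is the
  clinically relevant alarm) and `Ec` counts errors involving the circular
  class in either direction (a deformed cell read as normal suppresses the
  alarm; a normal cell read as deformed raises a false one).  With a
  no-answer column, an unanswered circular cell counts in `Ec`, an
  unanswered deformed cell in neither term.  On a 3-class matrix with no
  no-answer column `N + Ec` equals the total count, so the SDS-score is
  never below overall accuracy.
* **CBA** (class balance accuracy) ships in two variants.
  `cba_macro_recall` — the unweighted mean of per-class recalls — is the
  variant that reproduces the published values this package targets
  (0.7193 for the 3-class individual matrix, 0.8831 merged).
  `cba_mosley` is the literature form `mean_i diag_i / max(rowsum_i,
  colsum_i)`; it gives a different number on the same matrix and is
  provided, clearly labeled, for comparison with other work.
* **MCC**: the binary Matthews correlation coefficient on clean 2×2
  matrices, and Gorodkin's multiclass generalization otherwise.  A
  no-answer column is handled by appending a zero ground-truth row so the
  matrix is square — no-answer acts as a predicted-only category.  This is
  a package convention; it reduces exactly to the plain formulas when the
  column is absent.  The experiment's published 3-class MCC is not
  reproduced by Gorodkin's formula on the published counts (the variant
  behind that number is unresolved), so only the merged binary MCC
  (0.7194) is treated as reproducible.
* **F-measure** in macro / weighted / micro variants, cross-checked
  against scikit-learn in the test suite.  None of the three reproduces
  the experiment's printed F values on the published counts; the variant
  used there is likewise unresolved, and no F value is treated as a
  reproduction target.
* **Class merging**: elongated + other are consolidated into a single
  *deformed* class (both trigger the same clinical action).  Merging
  preserves the total count and the circular row/column marginals.

Published percentages are reproduced by rounding half-up at the printed
precision.  Where a printed percentage disagrees with the printed integer
counts it derives from, the counts are authoritative: the packaged
individual elongated row gives 614/905 = 67.85%, and it is this value
whose binomial transform matches the published consensus estimate of
80.73%.

## Independence model

If the k annotators of a cell are independent and each is correct with
probability α (the class's average individual accuracy), the consensus is
correct when at least `t = floor(k/2)+1` vote correctly:

    Acc_est(α, k) = Σ_{j=t}^{k} C(k, j) α^j (1−α)^{k−j}

For `k = 5` this is `α⁵ + 5α⁴(1−α) + 10α³(1−α)²` — binomial-tail
coefficients (1, 5, 10).  The model deliberately treats "at least 3
correct votes" as the success event and ignores that fewer than 3 correct
votes might still fail to elect a single *wrong* label, so it is an
idealization of the aggregation rule, not a bound.  It is strictly
increasing in α and exhibits Condorcet sharpening: for α > ½ the estimate
grows with k, for α < ½ it shrinks.  The estimated-vs-observed comparison
(`compare_estimate_vs_observed`) diagnoses the independence assumption:
a positive gap indicates correlated errors — annotators failing on the
same hard cells.

## Synthetic data

The generators define the regime in which the package is validated.

* **Votes.**  Each simulated worker carries a 3×3 row-stochastic response
  matrix (row = true class); the default is the row-normalized packaged
  individual-vote counts, so the simulated error structure matches the
  observed one (e.g. circular errors split 58:351 between elongated and
  other).  Without a difficulty model, votes are conditionally independent
  given the true class; the Monte-Carlo consensus accuracy then matches
  `Acc_est` within binomial noise, which the acceptance checks verify at
  n = 20,000 cells.  With a `DifficultyModel(pi_hard, hard_penalty)`
  (defaults 0.3, 0.5 — roughly a third of cells ambiguous enough to halve
  accuracy, a plausible reading of smear images with borderline
  morphology), a Bernoulli hard/easy latent is drawn once per cell and
  shared by all workers; on hard cells every worker's diagonal accuracy is
  multiplied by `hard_penalty` with off-diagonal mass rescaled
  proportionally.  This is the minimal mechanism that produces positive
  pairwise error correlation and drives observed consensus accuracy below
  the independence estimate; richer mechanisms (worker-specific biases,
  class-dependent difficulty) are out of scope.
* **Scenes.**  Images are dark cells (intensity ≈ 0.25 ± jitter) on a
  light background (0.88) with additive Gaussian noise (default sd 0.02,
  mild sensor noise at an 8-bit scale).  Circular cells are discs (radius
  7–11 px), elongated cells are rotated ellipses with aspect ratio 3–3.8
  (sickle-like), "other" cells are star-shaped blobs with random radial
  harmonics.  Cells are placed by rejection sampling with disjoint
  bounding discs; a scene that cannot fit the requested count raises an
  error reporting how many were placed.  The default class mix is the
  experiment's cell composition (617, 181, 50)/848.  The scenes emulate
  geometry and contrast only — not staining variation, overlapping or
  touching cells, debris, or illumination gradients — so segmentation
  results on them demonstrate correctness of the implementation, not
  performance on real smears.

All randomness flows through a single seeded NumPy generator per call;
identical seeds give byte-identical outputs.

## Segmentation numerics

The Chan–Vese functional is minimized by explicit gradient descent on a
level-set function φ with a smoothed Heaviside/delta pair of width
`epsilon` (default 1 px), curvature discretized by central differences,
time step `dt = 0.5`, and region means recomputed each iteration.
Defaults: `mu = 0.2` on images rescaled to [0, 1] and `max_iter = 1000`,
the settings of the workflow this package models; `lambda_in = lambda_out
= 1`.  Design choices made where the scheme was open:

* **Initialization** (`init="threshold"`): φ starts at a scaled Otsu
  threshold residual, `8·(t_otsu − u)`.  This separates the two region
  means immediately and typically converges within a few dozen
  iterations.  The classical checkerboard start is available
  (`init="checkerboard"`) but stalls for a long time near the symmetric
  `c_in ≈ c_out` state when foreground occupies a few percent of the
  image, as it does in smear-like scenes.
* **Convergence**: checked every 10 iterations; the solver stops when the
  maximum per-pixel |Δφ| falls below `tol` (1e-3) *or* the sign pattern of
  φ — the segmentation itself — has stopped changing over the window.
  The second criterion is the one that fires in practice: under the
  explicit scheme a thin band of boundary pixels keeps oscillating in φ
  value long after the boundary is stationary.
* **Polarity**: after convergence, the region whose mean differs most
  from the image-border mean is declared foreground, which is robust when
  the background dominates the border — cells brighter *or* darker than
  background both end up as foreground.
* **Degenerate input**: a constant image (no contrast) is an error, as is
  a collapse to a single region.
* `min_area = 64` px at the default generator scale removes sub-cellular
  specks before crop extraction; there is no canonical value, it is
  configurable.  Small-object removal and connected-component labeling
  use scikit-image (8-connectivity); crops are ordered by bounding-box
  (top, left) with zero-padded ids, boxes 0-based and half-open, padded by
  `crop_margin = 2` px and clipped to the image.

No reinitialization of φ is performed by default (a signed-distance
rebuild every N iterations is available).  Intensity rescaling to [0, 1]
makes the mask invariant under affine intensity shifts; reported region
means are mapped back to original units.  Energy descent holds up to a
small tolerance (the explicit scheme admits sub-percent transients).

## Problem sizes and verification

The test suite verifies the consensus rule against exhaustive enumeration
of all 3⁵ = 243 ordered panels, the binomial estimator against exhaustive
pattern enumeration for k ≤ 7, the metric suite against the packaged
experiment counts and against scikit-learn / hand oracles, the in-package
Chan–Vese against scikit-image's implementation on a synthetic scene, and
the simulators against their distributional contracts.  Monte-Carlo
checks use 8,000–20,000 cells (3-standard-error bands); segmentation
checks use 64–256 px images with up to 12 planted cells.  The acceptance
script (`scripts/acceptance.py`) recomputes the headline quantities at
these sizes in a few seconds.

## Limitations

* The consensus rule is unweighted plurality; worker-reliability models
  (Dawid–Skene and kin) are deliberately out of scope.
* The difficulty model captures shared cell difficulty only, the simplest
  source of inter-annotator correlation.
* Synthetic scenes do not render realistic stained smears; conclusions
  about segmentation on real microscopy require real images.
* The published 3-class MCC and F-measure values and the merged overall
  accuracy of the experiment are not derivable from the published counts
  with any standard variant implemented here; they are documented but not
  reproduced.
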