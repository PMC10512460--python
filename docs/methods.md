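# Methods

## Model and assumptions

The pipeline treats a subject's functional connectome as a vector of
Fisher-z edge values over the strict upper triangle of the symmetric
node × node correlation matrix (row-major, pairs (i, j) with i < j,
0-based — the contract every mask and vector in the package follows).
The diagonal is excluded and stored as 0: self-connectivity is
uninformative and arctanh(1) is undefined.  When starting from node
time series, connectivity is the Pearson correlation of mean node time
courses, r-to-z transformed; matrices supplied as raw r are transformed
on load (the reader requires an explicit `values="r"|"z"` declaration
rather than guessing the scale).

Feature selection is mass-univariate: the point-biserial correlation of
each edge with the 0/1 group label, with the two-sided p from
t = r·√((N−2)/(1−r²)) on N−2 df.  This is algebraically the
equal-variance two-sample t-test, which the test suite asserts to
1e-10.  Selected edges (p < θ) are split by sign of r into
increased-in-patients and decreased-in-patients sets and summed per
subject into at most two summary features.  The classifier is the
classic soft-margin linear SVM (hinge loss, box constraint C, default
C = 1, no feature standardization).  The implicit assumptions: group
effects are additive shifts on edges, large enough in aggregate to move
the *sum* of selected edges, and the two directional sums are linearly
separable up to noise.  Nothing nonlinear is attempted on purpose — the
1–2 dimensional feature space is what makes the directional comparison
interpretable.

Conventions that needed a decision:

* p-values for selection are **two-sided** (the sign split then gives
  each direction its meaning); one-sided selection would double-count
  the chosen direction.
* Edges with zero variance get r = 0, p = 1 and are never selected.
* A decision value of exactly 0 is classified as patient (class 1);
  the tie direction is arbitrary but fixed and tested.
* If no edge survives selection for the requested mode, the model falls
  back to majority-class prediction (ties toward control) with a logged
  warning rather than failing — relevant for very strict thresholds on
  small cohorts.
* Threshold search picks the LOOCV-best θ from {0.05, 0.01, 0.005,
  0.001}, ties toward the smallest θ.  Because the search and the
  evaluation share the dataset, the winning accuracy is optimistically
  biased; the per-threshold table is kept in the output so readers can
  see the spread, and no correction is applied (the procedure itself is
  the object of study).

## Validation machinery

LOOCV refits everything — correlations, masks, sums, classifier —
inside each fold.  The per-fold correlations are computed by downdating
cohort-level sufficient statistics (Σx, Σx², Σxy per edge), which is
algebraically identical to correlating the fold from scratch; a test
asserts fold-by-fold equality with direct refits.  Selection on hot
paths compares |r| against the critical value r_c = t_c/√(t_c²+df)
(the exact monotone image of p < θ), so full p-vectors are only
materialized when asked for.  k-fold CV stratifies folds by class from
a seeded shuffle (unstratified folds can go single-class at these
sample sizes); k = n is treated as LOOCV's fold structure.

The permutation test shuffles the *full* label vector and re-runs the
entire pipeline per shuffle (B = 1000 by default), reporting the
add-one estimator p = (1 + #{null ≥ observed})/(1 + B), whose floor
1/(B+1) is the resolution of the test.  For cross-dataset transfer the
*training* labels are shuffled and the test set stays fixed.  The sign
test is the exact one-sided binomial tail on per-subject correctness
vs. chance 0.5.  Consensus edges use an inclusive boundary (an edge in
exactly 90% of folds counts), implemented with an integer fold-count
threshold to avoid float boundary artifacts.  Network aggregation
counts each selected edge once per unordered network pair (diagonal =
within-network), in the fixed canonical label order CBL, SC, SAL, VAs,
VI, VII, Mot, DMN, FP, MF.

All randomness (fold shuffles, permutations, generators) descends from
one integer seed via `numpy.random.SeedSequence` spawning; identical
seeds give bit-identical outputs, which the suite asserts.

## The classifier solver

The 1–2 dimensional SVM subproblem is solved by a small numba-jitted
SMO (maximal-violating-pair selection, the standard pairwise analytic
update with box clipping, stopping gap 1e-6, intercept from the KKT
interval).  A dedicated solver is used because the resampling
procedures refit the classifier millions of times (a permutation null
over a LOOCV loop is B × n fits per dataset), and a general-purpose
library fit carries ~20× overhead at this problem size.  The test
suite cross-checks decision functions and primal objectives against the
libsvm reference implementation on hundreds of random problems; the
solver is never allowed to be the only route to a number.

## Synthetic data: what it does and does not emulate

`generate_cohort` plants effects directly in Fisher-z edge space: edge
baselines ~ Normal(0.25, 0.15) fixed per cohort (typical resting-state
z-values), subject noise ~ Normal(0, 0.2) i.i.d. per edge, patients
shifted ±delta on planted edges.  Default delta = 0.2 equals one noise
SD — a moderate, realistically detectable per-edge effect.  The
two-site design shares the decreased edge set across sites, draws each
site's increased set with a configurable overlap (default 0), and
redraws baselines independently per site (a site effect), so only
group *differences* transfer.  The time-series route draws
multivariate-normal node signals whose population correlation is the
subject's target matrix projected to the nearest valid correlation
matrix (eigenvalue clipping at 1e-4, renormalization to unit diagonal).

Deliberately not emulated: hemodynamic autocorrelation, motion
artifacts, heavy-tailed noise, edge-edge correlation structure beyond
what the planted effects induce, and scanner effects richer than a
baseline shift.  Passing tests therefore show the *pipeline* behaves
correctly under its own statistical assumptions — calibrated selection
under the null, recovery of planted directional structure, the
both-beats-single and decreased-transfers patterns — not that real
cohorts satisfy those assumptions.

## Problem sizes and numerical choices

The statistical tests run at 60 nodes (1,770 edges) and 60–100
subjects, with 100–200 replicate datasets and B = 200 permutation
shuffles where a full B = 1000 would add nothing but runtime; the
acceptance script uses B = 1000.  Symmetry tolerance for user matrices
is 1e-12 (inputs are symmetrized only within that tolerance, else
rejected).  Variance floors treat an edge as constant when its
centered sum of squares falls below 1e-12 of its raw sum of squares.
The positive-definiteness repair raises an error if it moves any
correlation by more than 0.5 — beyond that the requested structure was
not meaningfully a correlation matrix.

## Known limitations

* Threshold search is not nested inside the cross-validation, so the
  reported best-threshold accuracy is biased upward (kept deliberately;
  see above).
* The permutation test for transfer shuffles training labels only;
  shuffling test labels instead would test a different null.
* Summation weights all selected edges equally; edges with opposite
  within-set effect sizes partially cancel.
* The consensus-edge fraction is computed over all folds, including
  folds where nothing was selected.
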