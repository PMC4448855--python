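# Methods

## Setting and data model

An aggregation matrix `W` holds a per-site signal for `n` genomic
regions against a common reference point: row `i` is a region, column
`j` a distance from the boundary (one column = one base pair at site
resolution), and cell `W_ij` the bisulfite methylation rate of the CpG
at that position — missing when the position carries no CpG. Missingness
is an explicit boolean mask; observed values lie in [0, 1]. Coordinates
are 0-based half-open (BED convention) and all matrices are
transcription-oriented: minus-strand regions are flipped at construction
so column 0 is always the position adjacent to the boundary in the
5′→3′ sense.

A functional boundary is represented by a row-coupled pair of matrices,
left (5′) and right (3′), row `i` of both deriving from the same
boundary instance.

Three averaging statistics are defined over observed cells only:
`C` (mean of column averages, the %mCG metaplot value), `R` (mean of
row averages) and `M` (grand mean). Rows or columns with no observed
cell have no average and are excluded from `R` or `C` respectively;
this changes the effective `n` and is reported in the result
(`n_rows_used`, `n_cols_used`). The count–methylation correlation `r`
is the Pearson correlation between each row's observed-site *count*
(not fraction) and its mean; it is `nan` when fewer than two rows have
data or either variable is constant. A strongly negative `r` is the
signature of deamination-coupled missingness.

### Realizability construction

For any rational `r, c, m` strictly inside (0, 1) there is a matrix
with `R = r`, `C = c`, `M = m` exactly. The construction used here is
bipartite: with `r = a/b`, `c = e/d`, `m = g/f` in lowest terms, the
matrix has `a·k1` "hi" rows (all observed cells = 1) among `b·k1`, and
`e·k2` "hi" columns among `d·k2`; `g·t` cells of ones live in the
hi-row × hi-column block and `(f−g)·t` zeros in the lo × lo block,
everything else missing. Because every hi row/column mean is exactly 1
and every lo mean exactly 0, `R`, `C` and `M` reduce to the three
ratios by construction. Integers `(k1, k2, t)` are found by a small
search subject to each block covering all of its rows and columns while
fitting its grid; cells are dealt to rows round-robin with a global
cyclic column counter, which guarantees coverage. Matrix size is capped
(default 10 000 per dimension) to guarantee termination; floats are
accepted by snapping to a nearby rational within a stated tolerance
(default 1e-9).

## Yule–Simpson randomization test

For each coupled row, the concatenated left‖right observed values are
permuted uniformly over that row's observed positions; the mask is
untouched, so every joined row conserves its value multiset exactly
(rows with ≤ 1 observed value are fixed points). The step statistic is
`C_right − C_left`; the test reports the observed step, the null
distribution over replicates, their mean and standard error, and a
two-sided empirical p-value with the add-one rule
`(1 + #{|null| ≥ |observed|}) / (n_reps + 1)`, which cannot be zero.
Per-replicate generators are spawned from one master `SeedSequence`, so
the entire result is reproducible from one integer. The numeric step
statistic and its p-value are this package's formalization of a
diagnostic that is traditionally read off randomized profile plots.

A calibration subtlety, reflected in the test suite: the permutation
null conditions on the realized mask and row multisets. When row values
are near-constant within rows (e.g. regions that are essentially all
methylated or all unmethylated), within-row permutation moves almost
nothing, so the permutation spread is tiny while the null-step mean
tracks the mask realization's own sampling noise (both scale as
`1/√n`). The statement "equal CpG densities give a zero mean null
step" is therefore a *marginal* statement over datasets, and is checked
by averaging one permutation replicate from each of many independently
generated equal-density datasets; on a single dataset the meaningful
comparison is observed step versus null distribution (the p-value).

## Paired Region Averaging

For each boundary instance the left and right means are computed over
observed cells within a window of `w` columns from the boundary
(`w = 100` for UTR–coding analyses, `w = 200` for intron–exon, both
overridable; the library default uses each side's full span, which
makes padding with an all-missing column a no-op). Instances lacking
data on either side are discarded — the step that removes the bias —
and the retained mean pairs are compared two-sidedly:

- `rank_sum` (default, matching the Mann–Whitney–Wilcoxon naming):
  scipy's exact null for ≤ 50 pairs without ties; an in-house midrank
  permutation enumeration when ties are present and the pooled sample
  has ≤ 16 values (exact enumeration under ties is combinatorially
  infeasible beyond that); the tie-corrected normal approximation
  otherwise.
- `signed_rank`: the paired Wilcoxon test, offered because the pairs
  are intrinsically coupled. All-zero differences return `p = 1` with a
  degeneracy flag.

Every result carries a caveat that the method is strictly relative:
discarded instances are preferentially the sparse (more methylated)
regions, so retained means are not quantitative tendency estimates.

## COMPARE completion model

Features per cell `(i, j)`, computed from the row excluding the target
cell: `B_ij` (1 iff no other observed value), `X_ij` (leave-one-out
mean, 0 when `B = 1`), `Y_ij` (leave-one-out missing fraction; 1 when
the exclusion set is empty). In block mode the row is first restricted
to columns within `block` columns of `j` (a half-width, truncated at
the edges) — the meta-region variant for long or heterogeneous regions.
Features are computed with prefix sums and match a per-cell loop to
1e-12.

Column `j`'s coefficients `(b_j, x_j, y_j, z_j)` maximize the
fractional-response (quasi-binomial) cross-entropy of the column's
observed rates under the logistic mean — rates in [0, 1] are treated
as fractional successes, unweighted by coverage by default (coverage
weights are exposed as an option). A ridge penalty (default 1e-6) on
the slope terms, never the intercept, keeps coefficients finite on
separable columns; with centered constant features the penalty drives
the slopes to exactly zero, so an all-0.5 column recovers
`b = x = y = 0`, `expit(z) = 0.5`. Optimization is Newton/IRLS with
backtracking line search (objective tolerance 1e-8, ≤ 100 iterations)
falling back to L-BFGS-B; an independent statsmodels GLM(Binomial) fit
cross-checks the likelihood in the test suite. Columns with fewer than
`min_obs = 10` observations are left unfitted and are absent from the
completed matrix.

The completed matrix holds `expit(b_j B + x_j X + y_j Y + z_j)` at
*every* cell of a fitted column (strictly inside (0, 1)); a
`keep_observed` flag substitutes measured values at observed cells for
users who want imputation only. Because `Y` enters the model, the
inferences are decoupled from CpG availability: on deamination-coupled
pairs with equal true tendencies the completed-matrix `C` step is
roughly three orders of magnitude smaller than the naive one, and in
the methylated-sparse regime the completed `C` exceeds the naive `C`,
as it must when %mCG under-represents methylated regions.

### Cross-validation

Each fitted column's observed cells are split into 10 folds (per-column
generators spawned from one master seed); each fold is predicted by a
model trained on the remainder, and all (observed, inferred) pairs are
pooled — every observed cell of every cross-validated column exactly
once. Columns where a fold would leave fewer than `min_obs` training
points are skipped with a warning. Note the leave-one-out features are
computed once from the full matrix, so a held-out cell still influences
its row-mates' features; this mirrors the completion procedure itself
and is inherent to the feature definition.

The pooled cloud is scored by a total-least-squares line: the first
principal component of the centered but *not* standardized pairs (both
axes carry error and share units, so perpendicular distances are
meaningful on raw axes). Reported are the TLS slope (≈ 1 for a
calibrated model) and the variance explained, formalized as the
first-eigenvalue share of total variance, i.e.
`1 − perpendicular SS / total SS`.

## Simulators and what they do (not) show

- **Worked example** (`fig1_pair`): deterministic 12 × 4 pair; left
  statistics `C = M = 1/3`, `R = 2/3`, right `C = R = M = 2/3`,
  verified exactly. The grid layout (one CpG per methylated left
  region, two per column) is a canonical witness of those statistics.
- **Equal-tendency null** (`equal_tendency_null`): delegates to the
  randomization shuffle; a `shuffle_mask` variant permutes values and
  missing positions jointly, additionally equalizing the selective
  structure across the boundary.
- **Differential simulation**: binarizes each joined row by its mean
  (≥ 0.5 → 1, the tie going to methylated), selects
  `round(n_meth × fraction)` methylated rows (at least one when the
  fraction is positive) and zeroes their left-side observed cells; with
  64 % methylated regions and 5 % selection this yields 3.2 % of all
  regions differential. The optional boundary-column substitution
  copies each side's three boundary-adjacent columns wholesale (values
  *and* mask) from the adjacent three — with the flag off, the mask is
  preserved exactly.
- **Deamination generator** (`deamination_pair`): regions methylated
  with probability `p_methylated = 0.6`; binary tendencies (right side
  shifted by `true_step`, default 0); per-cell observation probability
  by class and side, default 0.1 for methylated-left versus 0.8
  elsewhere — the contrast that produces a naive `C` step of ≈ 0.4
  with no true difference; observed values jittered by a truncated
  normal (SD 0.05, small enough never to flip a binarized class).
  Defaults are desk-scale study conditions: `n = 400` regions and
  `m = 10` columns per side keep a 100-seed de-biasing experiment and a
  1000-replicate randomization calibration within seconds while leaving
  every per-column fit comfortably above `min_obs`.
- **Graded-tendency matrix**: continuous row tendencies uniform on
  [0.1, 0.9], used for calibration checks where binary tendencies would
  make the fit separable and the TLS slope degenerate.

What passing these tests does *not* show: the generators draw cells
independently given the region class, with no positional autocorrelation
of CpG density, no coverage heterogeneity, no partially methylated
domains, and binary or uniform tendencies rather than the bimodal-but-
smeared distributions of real methylomes. They establish the
correctness and calibration of the machinery — that the artifact arises
from coupled missingness and that the corrections remove exactly it —
not the magnitude of the effect in any particular genome, which depends
on real annotation and bisulfite data.

## Numerical and interface choices

- CG dyads: the two strand calls of a CpG, when both pass the coverage
  filter (default ≥ 3 reads), are merged coverage-weighted into one
  plus-strand record at the dyad start; unpaired minus-strand calls are
  re-anchored to the dyad start. Merging is an explicit step
  (`collapse_cg_dyads`; on by default in the CLI `build-matrix`)
  because upstream pipelines differ in whether they report strands
  separately.
- Descriptive statistics use `min_obs = 1` per column; COMPARE
  inference uses `min_obs = 10`. Both are exposed.
- Degenerate inputs: all-missing matrices, zero retained pairs, and
  unfittable matrices raise validation errors rather than returning
  NaNs; all-zero signed-rank differences return `p = 1` with a flag.
- All stochastic procedures accept one integer seed and derive internal
  streams via `SeedSequence` spawning; identical (config, seed) runs
  are byte-identical, and CLI provenance records deliberately contain
  no timestamps.
- The CLI maps exceptions to exit codes (3 parse, 4 validation, 5
  numerical) so drivers can branch on failure class.

## Known limitations

- COMPARE's three features summarize a row by its mean and missing
  fraction; gradients *within* a row are only captured through the
  column-specific intercepts, and block mode is the only locality
  mechanism.
- The fractional-response likelihood ignores the precision differences
  between rates estimated from 3 reads and from 300; coverage weighting
  is available but off by default.
- The cross-validation shares leave-one-out features across folds (see
  above), slightly flattering the reported accuracy for very sparse
  rows.
- Paired Region Averaging is strictly pairwise and relative; it cannot
  compare more than two region types at once nor estimate absolute
  tendencies.
- The exact rank-sum enumeration under ties is limited to pooled
  samples of ≤ 16 values; beyond that the tie-corrected normal
  approximation is used.
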