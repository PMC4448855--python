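# methcompare

Bias-aware comparison of sparse per-site DNA methylation signals across
functional genomic boundaries.

## The problem

Genome-wide methylation studies summarize bisulfite data by *aggregation
matrices*: one row per genomic region (e.g. one side of an intron–exon
junction), one column per position relative to the boundary, each cell
the methylation rate of the CpG at that position — or *missing* where the
sequence carries no CpG. The field-standard metaplot statistic is the
mean of column averages,

```
C = (1/m) Σ_j  mean_i { W_ij : observed },
```

alongside the mean of row (regional) averages `R` and the grand mean over
observed cells `M`. On a complete matrix `C = R = M`; with missing data
the three can be *arbitrarily* different, and for any rational triple
`(r, c, m)` in (0, 1) there is a matrix realizing all three
(`witness_matrix` constructs one exactly).

This matters because missingness is not random: deamination erodes CpGs
specifically in constitutively methylated, weakly selected regions, so
CpG availability co-varies with the methylation signal itself. Comparing
`C` across a boundary whose two sides differ in conservation then shows a
"step" even when every region is equally methylated on both sides — an
instance of the Yule–Simpson effect. `methcompare` detects and corrects
this bias:

- **Randomization diagnostic** (`randomization_test`): permutes observed
  values within each coupled row while freezing the missingness pattern;
  a non-zero mean null step `C_right − C_left` shows the step expected
  from data structure alone.
- **Paired Region Averaging** (`paired_region_averages`,
  `compare_paired`): compares per-boundary row-mean pairs, discarding
  boundaries lacking data on either side, then applies a
  Mann–Whitney–Wilcoxon (or paired Wilcoxon) rank test. Unbiased but
  strictly relative.
- **COMPARE** (`CompareModel`): logistic-regression matrix completion.
  For each cell, leave-one-out row features — `B` (rest of row empty),
  `X` (leave-one-out row mean), `Y` (leave-one-out missing fraction) —
  feed a column-specific logistic model

  ```
  M_ij = 1 / (1 + exp(−(b_j B_ij + x_j X_ij + y_j Y_ij + z_j)))
  ```

  fitted on the column's observed cells (columns with fewer than 10
  observations are left unfitted). The completed matrix supports
  `C`/`R`/`M` comparisons free of the missing-data bias, at site-specific
  resolution. Every fit includes a 10-fold cross-validation scored by a
  total-least-squares (first principal component) line through the
  pooled (observed, inferred) pairs.
- **Simulators** (`methcompare.simulate`): the 12-region worked example,
  equal-tendency permutation nulls, a differential-methylation
  simulation, and a deamination-coupled generator with known ground
  truth.

## Worked example

The canonical 12-region junction: eight regions fully methylated, four
fully unmethylated, identical tendencies on both sides — but methylated
regions retain only one CpG on the left side.

```python
import methcompare as mc

pair = mc.simulate.fig1_pair()
left, right = mc.summary_stats(pair.left), mc.summary_stats(pair.right)
print(f"left : C={left.C:.2f} R={left.R:.2f} M={left.M:.2f}")
print(f"right: C={right.C:.2f} R={right.R:.2f} M={right.M:.2f}")

res = mc.compare_paired(mc.paired_region_averages(pair))
print(f"paired averaging: diff={res.mean_difference:+.2f} "
      f"p={res.p_value:.2f}")

ys = mc.randomization_test(pair, n_reps=1000, seed=7)
print(f"YS test: observed step={ys.observed_step:.2f} "
      f"mean null step={ys.mean_null_step:.2f}")
```

prints

```
left : C=0.33 R=0.67 M=0.33
right: C=0.67 R=0.67 M=0.67
paired averaging: diff=+0.00 p=1.00
YS test: observed step=0.33 mean null step=0.33
```

The naive `C` comparison reports a 0.33 step across the boundary; the
regional averages agree exactly (`R = 0.67` both sides), paired
averaging finds a difference of exactly zero, and the randomization test
shows the entire observed step is reproduced under the no-difference
null — it is pure missing-data artifact.

The same pipeline from the shell:

```
methcompare simulate fig1 --out-prefix fig1
methcompare stats --matrix fig1.left.tsv
# C=0.333333 R=0.666667 M=0.333333 r=-1.000000
methcompare paired-avg --left fig1.left.tsv --right fig1.right.tsv \
    --out-prefix pa
methcompare ys-test --left fig1.left.tsv --right fig1.right.tsv \
    --reps 1000 --seed 7 --out ys.tsv
```

On deamination-coupled synthetic data the COMPARE correction is
dramatic: with methylated regions at CpG density 0.1 on the left against
0.8 elsewhere, the naive `C` step across the boundary is ≈ 0.41 despite
equal tendencies, while the completed-matrix step is ≈ 0.000:

```
methcompare simulate deamination --seed 11 --out-prefix de
methcompare complete --matrix de.left.tsv --seed 1 \
    --out completed.tsv --cv-report cv.json
```

Other subcommands: `build-matrix` (calls + BED → junction matrix pair,
with coverage filtering, CG-dyad collapsing and flank/exclusion
filters), `profile` (%mCG column profile), `cv` (cross-validation
report only). Every command writes a `*.provenance.json` record
(command, config, version) so runs are reproducible from the record and
seed; exit codes distinguish parse (3), validation (4) and numerical (5)
failures.

File formats: per-CpG calls as 5-column TSV
(`chrom pos strand rate coverage`), boundaries as 6-column BED, matrices
as TSV with an `NA` missing token and a `#orientation=` header
(lossless round-trip).

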