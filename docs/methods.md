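# Methods

## Hairpin anatomy and coordinates

A hairpin (pre-miRNA) is an extended precursor with a genomic span
(1-based inclusive, GFF3 convention), a strand, a 5'→3' RNA sequence and
0–2 mature arms given in hairpin-local 1-based offsets. Minus-strand
hairpins store the reverse complement of the genomic plus strand, and all
`AllelicSNV` ref/alt alleles are plus-strand DNA bases, so they join
directly against VCF records; HGVS `n.` names use hairpin-sense RNA
alleles instead.

Subregions follow the definitions used throughout the package: the seed is
mature positions 1–8 (a deliberate choice over the canonical 2–8 seed
convention), positions 9..end of each mature are "rest of mature"; with
exactly two matures the remaining sequence splits into "loop" (strictly
between the arms) and "out of loop" (outside both arms, both the 5' and 3'
segments), and with at most one mature every non-mature position is "rest
of pre-miRNA". The labels partition the hairpin exactly, which the tests
assert as a property. A mature shorter than 8 nt leaves the seed undefined
and is a hard error.

Enumeration yields exactly 3 alternate alleles per unambiguous position;
positions with non-ACGU bases are skipped with a warning. Hairpins that
overlap on the genome are enumerated independently (a genomic position can
therefore appear once per hairpin), which is the convention that makes
"3 × total nucleotides" arithmetic exact. Length sanity bands (41–180 nt
hairpins, 16–28 nt matures) produce warnings, not errors, so unusual but
valid annotations survive parsing.

## Feature matrix and imputation

Ten precomputed scores form the feature space, in a fixed column order
(cadd, remm, eigen_pc, funseq, ncer, fathmm_xf, dann, linsight, phylop,
phastcons). phyloP, phastCons and LINSIGHT are position-level: one value is
broadcast to the three alternate alleles of a site; the rest are
allele-level. Scores are kept on their native scales here — standardization
happens inside the model — so the assembled table stays interpretable. The
`autosomal` flag is derived from the chromosome name and is never missing.

Missing cells are filled by iterative (round-robin) imputation with an
extremely-randomized-trees regressor of 126 trees per incomplete column.
The whole run is repeated 10 times with distinct seeds and the imputed
values are averaged; observed cells are restored bitwise afterwards, so
imputation can never alter data. Averaging across repeats is one possible
reading of "repeat the imputation"; it is the only one that changes the
output, and it reduces the Monte-Carlo variance of the imputed values
(tested empirically). A fully missing column cannot be regressed on and is
a hard error naming the column. The PCA collinearity diagnostic
standardizes columns first (correlation-matrix PCA), so it reflects
redundancy among tools rather than their arbitrary scales.

## The classifier

Pipeline order: standardize the ten scores → full-rank PCA (all ten
components are retained; the transform decorrelates, it does not reduce
dimension) → append the autosomal boolean → degree-2 polynomial expansion
(no bias column; the intercept lives in the logistic regression) → bag of
L2 logistic regressions. Appending the boolean *after* PCA and *before*
the expansion lets it interact multiplicatively with every component, so
the ensemble can weight scoring systems differently for X-chromosome
variants; the alternative (boolean inside the PCA) would let a never-
missing binary column distort the rotation.

The bootstrap is asymmetric because deleterious examples are rare (the
reference regime is 24 deleterious vs 219 neutral): each of the 200 base
learners trains on all deleterious rows exactly once plus
`round(ratio × n_del)` neutral rows drawn with replacement, and on
`ceil(fraction × d)` of the d derived features drawn without replacement.
Every base learner therefore has an identical class composition.
`(X, y, hyperparameters, random_state)` fully determine the fit: all
randomness flows from one `numpy` generator, and lbfgs is deterministic.

Cross-validation deals the minority class round-robin across the 12 folds
(24 deleterious → exactly 2 per fold) and balances fold sizes with neutral
rows; four repeats use four independent splits. Every transform is re-fit
inside each training fold. AUC is the Mann–Whitney rank statistic
(average ranks for ties) on out-of-fold scores, reported per repeat, as
the repeat mean, and pooled over repeats together with the pooled ROC
curve — the two summaries can differ slightly and both are exposed. Grid
search scores each point with the same seeded CV; ties in mean AUC break
toward stronger regularization, then lower neutral ratio, then lower
feature fraction (an overfitting guard). The default grid is
l2_strength ∈ {0.01, 0.1, 1, 10}, ratio ∈ {1, 2, 4, 8},
fraction ∈ {0.3, 0.6, 1.0}; the feature subsample is parameterized as a
fraction rather than a count so it transfers across expansion sizes.

Models serialize to a versioned JSON file (scaler moments, PCA loadings,
polynomial degree, per-learner coefficients and index subsets, seed), so
scoring is reproducible from the file alone.

## Population statistics

Substitutions classify into two transition and four transversion
strand-symmetric categories; the Ts/Tv ratio is reported as +inf (flagged,
not a crash) when no transversions exist. Density is SNVs per kb with
multi-allelic sites counted once per alternate allele. Density comparisons
use a 2×2 chi-square on (variant sites, non-variant sites) without
continuity correction — the intended regime has thousands of counts — and
small expected cells are flagged rather than rejected. The coverage rule
("≥ 20 reads over ≥ 80 % of bases in ≥ 80 % of individuals") uses
inclusive comparisons at every threshold and accepts either a raw
bases × individuals depth matrix or the per-base
fraction-of-individuals-at-depth form; with the per-base form the rule
reads "enough bases each covered in enough individuals". Distribution
comparisons are two-sided Mann–Whitney with tie correction; correlations
are Spearman with average ranks. The high-percentile selection takes the
linear-interpolation quantile of the whole score table as the threshold
and keeps strictly greater scores, so on an all-equal table nothing is
selected, and the threshold/percentile pairing is reproducible for a
given table.

## Synthetic data

The generators define the study conditions and emulate the structure of
the real inputs, not their biology: sequences are uniform random RNA, no
secondary structure or site-specific mutation model is attempted, and
missingness is MCAR (no mechanism is implied by the imputer contract).

* Hairpin lengths are drawn from a right-skewed shifted-gamma distribution
  truncated to 41–180 nt so the mean sits near 80 nt, matching the
  real catalogue's skew (a uniform draw over the band would average
  110 nt); matures are uniform 16–28 nt, two-mature hairpins (default
  probability 0.5) keep a ≥ 2 nt loop, and ~5 % of hairpins land on chrX
  to exercise the autosomal flag.
* Scores follow a 3-latent-factor model: each column's loading vector has
  fixed communality 0.9, so ~90 % of each score's variance is shared —
  the few-components-dominate regime the PCA diagnostic is meant to
  detect — and a per-column affine map gives each tool a plausible native
  range. Position-level columns share their value across the three
  alternate alleles. Cells go missing at rate 0.11.
* Labeled sets shift the deleterious rows' first latent factor by d′
  (default 3.0 — clearly separable but not trivially so; d′ = 6 is
  effectively perfectly separable and d′ = 0 is the null); default sizes
  are 24 deleterious / 219 neutral, the reference-dataset shape.
* Population VCFs place PASS variants at the target density (default
  72/kb) over hairpins plus 300 nt flanks, drawing positions without
  replacement (so each site carries at most one alternate allele — real
  multi-allelic sites are not emulated), transitions with probability
  ts_tv/(1 + ts_tv) (default target 2.03), allele frequencies from a
  mixture putting 73 % of mass at AF ≤ 1e-4, and non-PASS records on top
  so PASS variants are a configurable fraction (default 0.95).

Passing tests on these inputs demonstrates the pipeline's correctness and
calibration under known structure; it does not certify performance on real
score tracks, whose error structure, missingness mechanism and class
overlap are unknown here.

## Dataset rules and the annotation table

The stringent rule takes curated deleterious variants **absent** from the
population cohort and neutral variants with AF > 10 %; the relaxed rule
takes curated variants **present** in the cohort and neutral variants with
AF < 10 %. Both comparisons are strict, so AF exactly 0.10 falls in
neither neutral set; such rows, failed-filter variants and curated/common
conflicts all land in an audit log with a reason, and audit rows + output
rows always equal input rows — conflicts are exposed, never silently
resolved. Only PASS variants enter any statistic or dataset. The
annotation table (one row per possible allelic SNV, deterministically
ordered by hairpin, offset, allele) joins subregion, HGVS name, cluster
flag, population AF, the ten scores and the model score; arbitrary
external annotations join by the chrom/pos/ref/alt key. hg38 coordinates
are a passthrough column, never computed.

## Problem sizes and numerical choices

The test-suite and acceptance-script sizes are chosen to make each check
statistically meaningful at desk scale: the census enumeration uses a
synthetic catalogue trimmed to exactly 152,975 nt; classifier CV checks
run 12 folds × 2–4 repeats with 20–30 base learners (the bagging contract
is size-independent, and 200-learner composition is asserted separately);
the label-permutation null uses 20 permutations (standard error of the
mean AUC ≈ 0.014 against a ±0.05 band); generator recovery uses a
~50,000-variant cohort judged at 3 sampling standard deviations; the
imputation benchmark uses 150 rows with an 11 % hole rate in a
near-deterministic column, where the tree imputer's RMSE is ~2 % of
column-mean imputation's. Quantiles use linear interpolation; the logistic
solver is lbfgs with max_iter = 2000; seeds derive from a single
`SeedSequence` per entry point, and every output writer is deterministic
down to bytes (fixed column order, `%.6g` floats), which the end-to-end
rerun test asserts.

## Known limitations

Real score tracks, population cohorts and curated disease variants are out
of scope; the package reads their formats but ships none of their data.
Secondary-structure scoring, assembly liftover and external annotation
fetching are likewise out of scope (the key-join interface stands in).
The synthetic generators do not model sequence composition, per-site
mutation-rate variation, linkage or multi-allelic sites, so absolute
performance numbers on synthetic data (e.g. CV AUC near 1.0 at d′ = 6)
characterize the pipeline, not expected real-data accuracy.
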