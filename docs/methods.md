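# Methods

## The analysis in one paragraph

Circular RNAs (circRNAs) are quantified through the reads that span
their diagnostic back-splice junction (BSJ); linear transcription of
the same loci is approximated by forward-splice junction (FSJ) reads,
which — unlike gene-level counts — cannot contain reads of circular
origin. After building a high-confidence BSJ catalogue from the
agreement of several detection tools, gene and junction counts are
placed on one scale via gene-derived size factors, each feature is
tested for a case/control difference with a negative-binomial (NB)
regression, and the *imbalance* of each RNA class — the fraction of
directional features (|log2FC| > 0.1) whose fold change is positive —
is tested against its symmetric Binomial(n, ½) null. A global loss of
circRNA expression in cases appears as a BSJ imbalance far below 0.5
with FSJ, host-gene and gene classes near 0.5. Classification
(elastic-net logistic regression and a model-free concordance score
under nested cross-validation, with transfer to an independent cohort)
quantifies whether any of this is usable as a diagnostic signal.

## Synthetic cohort model

The generator exists because the motivating patient datasets are
access-restricted; it reproduces the *statistical structure* the
analysis assumes, not the biology of blood.

Counts are negative binomial, `Var = mu + alpha * mu^2`, with a single
dispersion `alpha` (default 0.2, a typical bulk RNA-seq value) applied
to every feature. Per-gene log2 means are normal with centre
`mean_log_expression` (default 7, i.e. a median of ~128 reads —
"abundant" features, matching the analysis's low-count filtering) and
spread `mean_log_sd = 1.5`. Each BSJ is assigned a uniformly random
host gene and its per-sample mean is
`circ_fraction * mu_host * 2^(delta * case)`, with `circ_fraction = 0.1`
and `delta = global_circ_log2fc` (default −0.5). Two flanking FSJs per
BSJ get mean `fsj_fraction * mu_host` (default 0.5) with no `delta`, so
host-gene effects propagate to *both* junction types while the global
circRNA shift touches BSJs only — this is the coupling that makes
"circRNA change is not just host-gene change" a testable statement.
Case/control effects on genes are sparse (`de_gene_fraction = 0.05` of
genes at ±0.5 log2 units); a technical batch shifts a random half of
the features by `batch_log2fc = 0.2`; per-sample library factors are
log-normal with log2-scale SD `library_size_spread = 0.2`.

Default cohort sizes are the study design the pipeline emulates:
discovery 259 cases / 161 controls, replication 48 / 48. The default
transcriptome size is `n_genes = 16000` (the scale of an abundant
whole-blood gene set) with `n_bsj = 400` (the scale of an abundant
circRNA set after filtering). The transcriptome size matters beyond
realism: size factors estimated from few genes carry per-sample noise
that is *shared* across all junction fold changes, and that common
component inflates the imbalance test's variance beyond its binomial
null. At ~16k genes the component is negligible; see "Calibration"
below. No effect-size distribution is published for the global circRNA
reduction, so `delta = −0.5` was chosen once for clear test power, not
fidelity.

Three pseudo detection tools each report an independent
Bernoulli(`tool_sensitivity`) subset of true BSJs plus private spurious
junctions (rate `fp_rate_per_tool`, placed on tool-specific
chromosomes so they can never collide with real coordinates, and hence
are always removed by the two-tool consensus rule).

Feature-level structure (means, effect assignment, hosts, coordinates)
is drawn from a stream seeded by `structure_seed`, sample-level
randomness from `seed`; the pipeline gives its two cohorts the same
structure seed so they share a feature space, as real cohorts share a
genome.

What the generator does *not* model — and therefore what green tests do
not establish about real data: cell-type composition shifts, trended
mean–dispersion relationships, correlated technical covariates,
isoform structure within circRNAs, or read-level artefacts. Tool calls
carry the true counts; real callers disagree on counts, not just on
detection.

## Catalogue rules

"Read count > 1 in at least two individuals" is applied strictly
(count ≥ 2) *within a single tool's quantification*; counts are never
pooled across tools — the conservative reading. Junction identity is
exact (chrom, start, end, strand) equality, 1-based inclusive; no fuzzy
boundary merging. A BSJ's "corresponding" FSJs are those sharing its
donor or acceptor coordinate (an FSJ ending at the BSJ start or
starting at the BSJ end, same chromosome and strand), and its linear
signal is the mean of the flanking FSJ counts. The circular-to-linear
ratio is `2*BSJ / (2*BSJ + linear)` — the BSJ count is doubled because
a circle contributes one junction where the linear form contributes
two — defined as 0 when both signals are 0. Host annotation assigns the
gene whose span contains both BSJ boundaries on the same strand;
when several genes qualify, the smallest span wins, remaining ties
break lexicographically by gene id (the published analyses are silent
on both choices).

## Differential expression engine

Per feature, counts follow an NB log-linear model with the log size
factor as fixed offset; the design is intercept + covariates + a
case indicator, and the reported effect is the case coefficient in
log2 units. Fitting is IRLS (capped at 100 iterations, relative
deviance tolerance 1e-8). Dispersion is per-feature maximum likelihood:
a method-of-moments start, then a golden-section search over
log-dispersion in [1e-8, 50] maximizing the likelihood with a
Cox–Reid-style adjustment (−½ log det X'WX) that compensates for the
estimated regression coefficients; the floor is 1e-8. There is *no*
shrinkage of dispersions or fold changes toward a trend: plain
per-feature ML keeps the implementation self-contained, and calibration
is demonstrated on simulation rather than by matching any particular
tool's point estimates. Wald p-values use the standard normal.
Features that fail to converge are flagged, their p set missing, and
excluded from BH adjustment.

All per-feature quantities are vectorized across features (batched
linear solves and a batched golden-section search), which is what makes
500-replicate calibration studies tractable on one CPU.

The low-count filter keeps features whose raw-count total in the
smallest sample group strictly exceeds 10; with equal group sizes the
smaller of the two group sums is used. The variance-stabilizing
transform used for classification features is deliberately the shifted
log `log2(count/sf + 1)` — a declared stand-in, monotone per sample,
not a reproduction of any mean–variance-modelled transform.

## Imbalance statistics

The two-sided exact binomial test uses the minimum-likelihood
convention (sum of all Binomial(n, ½) point probabilities no larger
than the observed one), matching the standard statistical routines of
R and scipy; this differs from tail-doubling at some (k, n) and is
therefore pinned by an enumeration oracle for all n ≤ 12. The 95%
interval on the imbalance is Clopper–Pearson, consistent with the
exact-test framing. Bonferroni correction multiplies by the number of
panel classes (4), capped at 1. Classes with no directional feature
are reported explicitly as degenerate rather than as a silent 0.5.

Two comparisons needed a unit convention the published description
leaves open. The expression-shift test compares *per-feature mean*
normalized expression of cases against controls with an unpaired
rank-sum test (exact enumeration when both sides are ≤ 50 and tie-free,
normal approximation with tie correction otherwise). The fold-change
shift between junction types is likewise the unpaired rank-sum test of
BSJ fold changes against FSJ fold changes, matching the named test
rather than a paired alternative. Both are documented choices, not
inferences of intent. Fold changes entering the imbalance are those of
the features that survived low-count filtering and converged in DE.

## Calibration of the panel's null

The type-I-error suite runs 500 null cohorts (delta = 0, no gene or
batch effects, 300 BSJs, 60+60 samples, 16k genes for size factors,
with the gene class tested on a 2,000-gene subsample per replicate to
keep the loop tractable). Because the exact binomial test is discrete,
its achievable size depends on the per-replicate number of directional
features (for the BSJ-host class the median is ~15 features, where the
achievable size is ≈ 3.5%, not 5%). The suite therefore compares the
observed rejection count per class against the sum of per-replicate
exact sizes (a Poisson-binomial band), plus a nominal-5% upper bound
that catches anti-conservatism. Measured rates at these conditions are
≈ 5.4% (BSJ), 5.0% (FSJ), 3.8% (gene) and 3.0% (BSJ-host) — the last
two reflecting discreteness, not miscalibration.

## Classification

Feature sets: gene expression (vst), BSJ counts (vst), circular-to-
linear ratios (raw), the concordance score, and gene+BSJ combined.
Gene features are preselected at nominal DE p < 0.05 — recomputed
strictly inside each training fold; in combined sets the screen applies
only to gene features and junctions are always kept. Models are
elastic-net logistic regressions (scikit-learn saga) with the mixing
parameter tuned over {0.1, 0.5, 1.0} and a log-spaced penalty grid
(C in 10^−2 … 10^1), standardized inputs, tuned by inner-fold AUC.
Outer folds are stratified by label with a fixed seed. Held-out outer
predictions are pooled into one ROC per feature set with a DeLong
structural-components interval.

The concordance score bypasses model fitting: each BSJ scores 1 when
the sample's deviation from the training-control mean lies in the
training-cohort fold-change direction (zero deviation never agrees —
the tie rule), and the per-sample sum is used directly as the ROC
score. It is invariant under any strictly monotone per-feature
transform applied consistently to samples and control means.

For transfer, the model is refit on the full training cohort at
hyperparameters selected by an inner cross-validation on that cohort,
then applied frozen to the second cohort; features absent there are
imputed at the training control mean and the imputation count is
reported.

Note that on the generator's default conditions the classifiers sit
near AUC 1.0: a global shift applied uniformly to *every* BSJ, with no
between-sample biological variability beyond counting noise, is a far
cleaner multivariate signal than any real cohort provides. The
classification machinery is therefore validated by its calibration
(permuted labels centre on 0.5) and by graded-signal recovery, not by
the absolute AUC values on defaults.

## Numerical and degenerate-input conventions

- Size factors are undefined (rejected with a diagnostic) when no gene
  is positive in every sample.
- `match_fsj` on an empty BSJ set raises: an unmatched *fraction* has
  no value there.
- Spearman correlation on a constant vector raises rather than
  returning NaN silently.
- Rank-sum tests return p = 1 exactly at the null centre (including the
  all-tied case where the rank variance is 0).
- DeLong intervals are clipped to [0, 1]; perfect separation yields the
  degenerate interval (1, 1).
- The NB Wald fold-change sign can differ from the sign of the plain
  normalized-mean difference for effects indistinguishable from zero,
  because IRLS weighs samples by mu/(1 + alpha*mu); the sign-agreement
  test applies away from zero.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` runs the full pipeline at the study's cohort
sizes (259+161 and 48+48) with a 3,000-gene / 400-BSJ transcriptome and
5 outer / 4 inner cross-validation folds — a desk-sized configuration
chosen so the whole study re-runs in minutes; all other parameters are
the generator defaults. All randomness derives from the `--seed`
argument, and identical seeds reproduce identical JSON output.

## Known limitations

- Dispersion is estimated per feature with no information sharing, so
  power at very small sample sizes is below that of shrinkage-based
  engines; calibration, not power, is the design goal.
- The shifted-log transform under-stabilizes variance for very
  low-count features relative to a fitted mean–variance transform.
- The imbalance test treats fold changes as independent across
  features; residual size-factor noise shared across junctions makes it
  mildly anti-conservative when size factors are estimated from few
  genes (see "Calibration").
- The covariate screen is the simplified univariate PC-regression
  version (R² > 0.5, Spearman-|ρ| > 0.9 deduplication); no variance
  partitioning is implemented.
- Classification reports pooled-fold ROC with DeLong intervals; the
  pooling slightly understates between-fold variability.
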