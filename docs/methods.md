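# Methods

This note documents the models and procedures implemented in
`stagecluster`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Study design being modelled

A multi-tissue developmental time course: five tissues (source leaf SoL,
stem bark, stem wood, fibrous root FR, storage root SR) sampled at three
stages of storage-root bulking (pre-bulking PB, early-bulking EB,
during-bulking DB), with a few replicate plants per stage (default 4;
real studies of this kind have 3–5). Gene expression arrives as a
gene × sample matrix of read counts; phenotypes are strictly positive
analyte contents (glucose, fructose, sucrose, starch in mg g⁻¹ DW);
compartment data are per-replicate fractions of each sugar across
cytosol, vacuole and plastid.

## Synthetic data generator

Counts for gene *i*, sample *j* are negative binomial with
`E[K_ij] = s_j · b_i · f_i(stage_j)` and `Var = mu + alpha_i mu^2`:

- baselines `b_i` log-normal, location 5.0 and scale 1.0 on the natural
  log (median ≈ 148 counts) — a realistic expressed-gene mean;
- dispersions `alpha_i` log-normal around 0.05 (sigma 0.5), the canonical
  order for well-replicated bulk RNA-seq;
- size factors `s_j` log-uniform on [0.5, 2], rescaled to geometric mean
  1 so recovery is well-posed;
- planted modules: per tissue, K = 4 disjoint sets of 100 genes share one
  stage-profile template — monotone up `f^t`, monotone down `f^(1−t)`,
  EB peak, EB dip (t the normalized stage position, fold `f = 4` by
  default). Background genes are flat, so module membership implies (and
  exhausts) true differential expression;
- an optional second batch multiplies each gene by a shared log-normal
  offset (sigma 0.1), emulating a duplicated storage-root experiment;
- phenotypes are Gamma draws with log-link mean structure (shape 10 —
  CV ≈ 32%, typical of biochemical assays) in which storage-root analytes
  rise toward DB and wood starch declines;
- compartment fractions are Dirichlet with mean (0.40, 0.35, 0.25) for
  vacuole/plastid/cytosol and concentration 200, matching the observed
  ordering of subcellular sugar pools, 7 replicates per sugar.

All draws are deterministic functions of a single seed; named substreams
separate counts, phenotypes and fractions.

What the generator does **not** emulate: gene-length and GC effects,
correlated background genes, outlier replicates, count heteroskedasticity
beyond NB, compositional library effects, or batch–condition interaction.
Passing recovery tests therefore shows the estimators are correct under
the stated model, not that real libraries satisfy that model.

## Normalization

Size factors are median-of-ratios over genes expressed in every sample,
anchored to geometric mean 1 (an error is raised when no gene is
positive everywhere). The variance-stabilizing transform is the
monotone surrogate `log2(count/size_factor + 1)`; the exact
dispersion-dependent VST of dedicated DE packages is deliberately not
reproduced, and every downstream consumer takes the transformed matrix
generically so the transform is swappable. The expression filter keeps
genes whose mean normalized count (linear scale) reaches 50 in at least
one tissue × stage condition; grouping by sample reproduces the global
variant of the filter. Batch adjustment removes per-gene batch offsets
by ordinary least squares with the tissue × stage condition design
retained, preserving each gene's grand mean; a batch confounded 1:1 with
condition raises an error.

## Differential expression

Per tissue, each gene is fit by an NB GLM with log link and
log(size factor) offset via IRLS, at a fixed per-gene dispersion
estimated by method of moments on normalized counts:
`alpha = mean over conditions of (s² − m)/m²`, floored at 1e-8. The
stage effect is the likelihood-ratio statistic of the full model (stage,
plus batch when present) against intercept (plus batch), referred to
chi² with (stages − 1) df; BH-adjusted p-values below 0.001 define DEGs.
All-zero and non-converged genes are reported with missing p-values and
never called.

Two properties of this deliberately simple dispersion treatment matter:

- with adequate replication (n ≳ 10 per condition) or a known
  dispersion, the LRT p-values are uniform under the null (verified by
  simulation), and power on 4-fold effects at dispersion 0.05 exceeds
  99% even at n = 4;
- at n = 4 per stage the plug-in estimate carries only ~9 df of
  information, and the chi²-referenced LRT behaves like an F statistic
  with a small denominator: the null P(p < 0.05) inflates to ≈ 0.11 and
  a KS uniformity test on 2,000 null genes rejects. This is the known
  price of forgoing empirical-Bayes dispersion shrinkage; the stringent
  FDR < 0.001 gate still keeps null calls near zero (≤ 2 in 2,000).
  Production analyses at n = 4 should interpret borderline calls
  accordingly.

## Co-expression network

Profiles (transformed expression across one tissue's samples) are
centered and scaled per gene (SD with ddof = 1; constant genes are
dropped with a warning). The edge threshold is calibrated on the
permutation null: per replication, every gene's values are permuted
independently across samples — destroying all between-gene correlation
while preserving marginals — and the 99.995% quantile of the resulting
pairwise correlations is recorded; the threshold is the median over
1,000 replications. When the number of gene pairs exceeds
`pairs_per_rep` (default 200,000) a random pair subset keeps the cost
linear; a warning is emitted when the pair count cannot resolve the
requested quantile. On 12 iid Gaussian samples the procedure lands
within a few 1e-3 of the analytic null quantile
`r* = t_q / sqrt(t_q² + n − 2)`.

Edges connect pairs with signed correlation strictly above the
threshold (positive co-regulation; an absolute-value mode exists behind
a flag). Nodes with fewer than `min_degree` (default 50) edges are
removed in a single pass; an iterate-to-fixpoint mode is available and
off by default. The degree filter scales with graph size in validation
runs (20 for the 2,000-gene synthetic study).

## Community detection

Modularity is the resolution-scaled Newman–Girvan quality
`Q = Σ_c [e_c/m − gamma (d_c/2m)²]` on the unweighted thresholded edge
set (the pipeline thresholds rather than weights; a weighted mode is
off by default), with gamma = 0.75 as the pipeline default. Louvain runs
the standard two phases — greedy local moves to a fixpoint, then graph
aggregation — with three numerical choices:

- node visiting order is shuffled once per level from the seed;
- equal-gain moves are tie-broken by a seeded random draw restricted to
  strictly improving candidates (a fixed rule such as "lowest community
  id" provably funnels every run into the same suboptimal basin on
  symmetric graphs, and ties with staying resolve to staying so moves
  monotonically increase Q and terminate);
- the whole two-phase procedure is restarted 8 times from seed-derived
  substreams and the best-Q partition kept, making the result
  deterministic under the seed while escaping most order-dependent
  local optima.

The returned partition never scores below the one-community or
all-singleton baselines. An exhaustive Bell-number oracle
(`exhaustive_best_partition`, ≤ 10 nodes) provides the reference
optimum: on random 8-node graphs the restarted Louvain matches it for
98% of runs; the residual gap comes from rare graphs whose optimum is
separated from every greedy basin by simultaneous multi-node moves — a
known limitation of local-move heuristics that refinement methods
address at larger scale.

## Cluster summaries

Stage profiles follow the heatmap convention: per gene, average the
transformed values over each stage's samples, z-score those averages
across stages (constant genes map to zero), then report a cluster as the
per-stage mean of member z-scores (the per-cluster-mean-then-z
alternative is a flag). Intersections use exclusive UpSet semantics —
each gene counts toward exactly the pattern of all tissue:cluster sets
containing it, so pattern counts partition the gene universe; the 25
largest patterns are reported with per-set totals. Partition agreement
is the adjusted Rand index from the pair-counting contingency table.

## Phenotype statistics

Per tissue × analyte, contents are modelled by a Gamma GLM with log
link (constant shape, dispersion estimated by Pearson chi²/df). The
stage effect is the type-II test, which for the single-factor model is
the full-vs-intercept likelihood ratio on the scaled deviance, referred
to chi² with (stages − 1) df; p-values are BH-adjusted across all
tissue × analyte models and models below FDR 0.05 receive a compact
letter display. Calibration was verified at n = 100 per group (type-I
rate 5.3% at alpha = 0.05 over 1,000 simulations); at very small group
sizes the scaled-deviance chi² shares the usual anti-conservatism of
plug-in dispersion tests.

Tukey-HSD contrasts are computed on the link scale from the model-based
covariance, with p-values from the studentized range distribution at the
model's residual df (the response-scale alternative was not chosen; on
the log link the contrasts are fold-changes, matching the multiplicative
error structure). The compact letter display uses insert-and-absorb,
whose final columns are exactly the maximal cliques of the
non-significance graph; the iff-invariant (two levels share a letter iff
their adjusted comparison is non-significant) is checked programmatically
on every output.

Compartment fractions are tested per sugar by an ordinary linear model
`fraction ~ compartment` (the fractions are compositional — rows sum to
one — which a plain linear model ignores; it is retained as the
procedure this pipeline standardizes, and the simplex constraint is
validated on input), with the per-sugar ANOVA p-values BH-adjusted
across sugars and Tukey letters for significant models.

## Pipeline

`run_pipeline` chains normalize → per-tissue DEG → network → clustering
→ profiles/intersections (plus phenotype and fraction statistics when
tables are supplied), writing TSV outputs and a JSON manifest with
parameters, per-stage seeds, row counts and SHA-256 checksums of every
file. One top-level seed is split into named substreams per stage and
tissue, so stages can be re-run in isolation; a tissue with no DEGs (or
an empty graph after filtering) is skipped with a logged notice. All
tabular I/O is tab-delimited UTF-8 with a header row; gene ids are
opaque strings.

## Validation problem sizes

The validation studies use 2,000 genes, 12 samples per tissue and
1,000 permutation/simulation replications — sizes at which every
recovery target is sharp (size-factor error ~1%, DEG power > 99%,
threshold error < 0.005, end-to-end ARI 1.0) while a full run of the
suite plus the acceptance script completes in a few minutes on one core.

## Known limitations

- No empirical-Bayes dispersion shrinkage: null p-values are
  anti-conservative at n ≲ 5 replicates per stage (see above).
- The VST surrogate is not the dispersion-dependent exact transform;
  low-count genes retain more variance than under a true VST.
- The permutation null assumes exchangeable samples within a gene;
  structured designs (paired samples, strong batch) would need a
  restricted permutation scheme.
- Louvain is a heuristic: on adversarial graphs the modularity optimum
  can be unreachable by single-node moves regardless of restarts.
- The NAF linear model treats compositional fractions as unconstrained
  responses, as is conventional for this assay.
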