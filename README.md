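# stagecluster

Stage-wise differential expression and co-expression clustering for
multi-tissue bulk RNA-seq studies, with the matching phenotype statistics.

The package re-implements, as a tested and reusable pipeline, the
computational analysis of a source–sink study on a storage-root crop:
five tissues (source leaf, bark, wood, fibrous root, storage root) are
sampled at three developmental stages of root bulking (pre-bulking PB,
early-bulking EB, during-bulking DB), and the analysis asks which genes
respond to the stage within each tissue and how those genes organize into
co-regulated clusters. Alongside the expression side it provides the
measurement-side statistics used for non-structural carbohydrates (NSC)
and subcellular sugar fractions, and a synthetic-data generator with full
ground truth so every step can be validated by parameter recovery.

## Methods at a glance

- **Normalization** — median-of-ratios size factors
  `s_j = median_i ( K_ij / (prod_j K_ij)^(1/n) )`, anchored to geometric
  mean 1, followed by the variance-stabilizing surrogate transform
  `log2(K_ij / s_j + 1)`.
- **Differential expression** — per tissue, a negative-binomial GLM with
  log link and `log s_j` offset (`Var = mu + alpha mu^2`, per-gene
  method-of-moments dispersion), tested by the likelihood-ratio statistic
  `2(l_stage − l_intercept) ~ chi^2(levels − 1)`, optionally with an
  experimental-batch covariate in both models; Benjamini–Hochberg FDR,
  genes called at FDR < 0.001.
- **Co-expression network** — per-gene centered/scaled profiles, Pearson
  correlation edges above a permutation threshold (median of the 99.995%
  quantile over 1,000 within-gene permutation replications), then removal
  of nodes with fewer than 50 edges.
- **Clustering** — Louvain optimization of resolution-scaled modularity
  `Q = sum_c [ e_c/m − gamma (d_c/2m)^2 ]` at `gamma = 0.75`, with an
  exhaustive small-graph oracle for validation.
- **Summaries** — per-cluster stage profiles (z-score across stages of
  each gene's per-stage mean expression), exclusive UpSet intersection
  counts across tissues, adjusted Rand index against ground truth.
- **Phenotype statistics** — Gamma GLM (log link) per tissue × analyte,
  type-II ANOVA with BH correction across models, Tukey-HSD compact
  letter display; compartment fractions (cytosol / vacuole / plastid) per
  sugar by a linear model with the same post-hoc letters.

## Worked example

```python
import stagecluster as sc

cfg = sc.SimConfig(seed=42)                 # 5 tissues x 3 stages x 4 plants
counts, truth = sc.generate_counts(cfg)     # 2,000 genes, 4 planted modules/tissue
pipe = sc.PipelineConfig(out_dir="run", min_degree=20, seed=42)
manifest = sc.run_pipeline(counts, pipe, truth=truth)
print(manifest["stages"]["deg"])
print(manifest["stages"]["module_recovery_ari"])
```

prints

```
{'SoL': 403, 'Bark': 410, 'Wood': 403, 'FR': 401, 'SR': 401}
{'SoL': 1.0, 'Bark': 1.0, 'Wood': 1.0, 'FR': 1.0, 'SR': 1.0}
```

Each tissue yields ~400 stage-responsive genes at FDR < 0.001 (the 400
planted module genes plus a handful of false calls), and the recovered
Louvain clusters agree perfectly (adjusted Rand index 1.0) with the four
planted co-expression modules in every tissue. The run directory
contains the normalized matrix, per-tissue DEG tables, edge lists,
cluster assignments, stage profiles, intersection counts, and a manifest
with parameters, seeds and file checksums.

The same run is available from a shell:

```sh
stagecluster simulate --out sim/ --seed 42
stagecluster run-all --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --phenotypes sim/phenotypes.tsv --naf sim/naf.tsv --out run/ --seed 42
```

## Layout

- `src/stagecluster/simulate.py` — synthetic counts / phenotypes / NAF with ground truth
- `src/stagecluster/normalize.py` — size factors, transform, expression filter, batch removal
- `src/stagecluster/deg.py` — NB GLM, stage LRT, BH adjustment
- `src/stagecluster/network.py` — scaled profiles, permutation threshold, graph construction
- `src/stagecluster/community.py` — modularity, Louvain, exhaustive oracle
- `src/stagecluster/profiles.py` — stage z-score profiles, UpSet counts, ARI
- `src/stagecluster/stats.py` — Gamma GLM, type-II ANOVA, Tukey letters, NAF model
- `src/stagecluster/pipeline.py`, `io.py`, `cli.py` — orchestration, formats, CLI

See `docs/methods.md` for the statistical details and design decisions.
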