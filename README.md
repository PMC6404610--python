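# coexnet

Coexpression-network analysis of evolved transcriptional plasticity in a
crossed population × environment RNA-seq design, with a synthetic-data
generator that plants known modules so every stage of the pipeline can
be validated against ground truth.

## The scientific problem

When populations evolve under stress (heat, oxidative), their
transcriptomes can change in three qualitatively different ways relative
to the ancestor: the plastic response to the environment can be retained
unchanged (*shared plasticity*), the baseline expression level can shift
while the plastic response is retained (*divergent baseline*), or the
plastic response itself can change (*evolved/divergent plasticity*, whose
extreme — complete loss of the response — is genetic assimilation).
Distinguishing these patterns gene-by-gene is underpowered and
unstructured; the network approach instead groups genes into
coexpression modules, summarizes each module by its **eigengene** (the
first principal component of the module's standardized expression), and
classifies each module's reaction norm from a population × temperature
ANOVA on the eigengene.

The pipeline implements, for a gene × sample count matrix with 4
populations (ancestor, control, heat-selected, oxidative-selected) × 2
rearing temperatures (20°, 30°) × 6 replicates:

1. **Preprocessing** — median-of-ratios size factors, variance-
   stabilizing transform (default `log2(count/factor + 1)`), removal of
   the 40% lowest-variance genes, and surrogate-variable analysis (SVA):
   latent batch-like factors are estimated from the design-residual
   expression (genes importance-weighted by their design p-value, then a
   two-step rebuild from raw data of associated genes) and regressed out.
2. **Ordination** — Bray–Curtis dissimilarities, non-metric MDS in five
   dimensions (Kruskal stress-1, isotonic regression + SMACOF updates,
   multiple restarts), and crossed-factor PERMANOVA
   (sequential sums of squares, free permutation, 1000 permutations).
3. **Network** — signed adjacency `a_ij = ((1 + cor_ij)/2)^5`,
   topological overlap matrix
   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, average-linkage
   clustering of `1 − TOM`, and a dynamic hybrid tree cut
   (cut height 0.905, deep split 2, minimum module size 30, PAM stage).
4. **Stability** — the module-support resampling procedure: rebuild the
   network on 100 (here 25) subsamples keeping 4 of 6 replicates per
   treatment cell; a resampled module that captures ≥ 10% of a full-
   network module credits its overlapping genes to that module; genes
   credited in ≥ 70% of resamples keep their label, everything else is
   unassigned; modules with eigengene r > 0.9 are merged; modules under
   30 genes are dissolved.
5. **Eigengene statistics** — per module: PC1 variance explained,
   a t-test of the ancestor's eigengene across environments, a two-way
   fixed-effects ANOVA (df 1/3/3 over 40 for the full design), Tukey HSD
   with compact-letter display, and the reaction-norm classification
   (interaction significant → evolved/divergent plasticity; temperature +
   population → divergent baseline; temperature only → shared
   plasticity; population only → non-plastic divergence).
6. **Enrichment** — one-to-many homolog expansion of gene-set
   collections (GMT), one-tailed Fisher exact tests of each set in each
   module, and Benjamini–Hochberg FDR within each collection.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted truth:

```sh
python analysis/01_simulate_study.py     # counts, metadata, truth tables
python analysis/02_preprocess.py         # VST + variance filter + SVA
python analysis/03_ordination.py         # nMDS + PERMANOVA
python analysis/04_network_modules.py    # signed network + tree cut
python analysis/05_module_stability.py   # resampling stability filter
python analysis/06_eigengene_analysis.py # ANOVA/Tukey + classification
python analysis/07_enrichment.py         # Fisher enrichment of planted sets
```

The simulation plants five modules (400/350/250/150/50 genes) spanning
the reaction-norm taxonomy plus 800 background genes. With the default
seed the run prints, among other things:

```
PERMANOVA on Bray-Curtis dissimilarities:
temperature             0.0855   1  24.4275  0.3008  0.0010
recovery vs planted truth: ARI = 0.986, background unassigned = 85.4%
    module  n_genes  pct_var_pc1  category
         1      402       64.225  SHARED_PLASTICITY
         2      381       53.966  DIVERGENT_BASELINE
         ...
```

Temperature dominates global expression (as it should — two planted
modules respond to it in opposite directions), the stability-filtered
modules recover the planted partition almost exactly (adjusted Rand
index 0.986), every module eigengene explains well over 40% of its
module's variance, and each planted gene set's strongest enrichment is
its own recovered module. The occasional off-by-one classification
(a planted shared-plasticity module called divergent baseline) is the
expected ~10% false-positive rate of the α = 0.05 decision table, not a
pipeline defect.

A `coexnet` command-line interface exposes the same stages
(`coexnet simulate | preprocess | ordinate | network | stability |
eigengene | enrich | run | validate`); `coexnet run --config config.yaml`
executes everything from a config file with a single global seed.

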