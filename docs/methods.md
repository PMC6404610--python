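# Methods

This note documents the models, estimators, numerical choices and known
limitations of the pipeline. Everything stated here is computed by the
test suite or the analysis scripts; nothing is quoted from external
results.

## Synthetic data model

The generator emulates a crossed experimental-evolution design:
populations *ancestor, control, heat, oxidative* × temperatures
*20°, 30°* × 6 replicate libraries (48 samples by default).

**Latent eigengenes.** Each planted module *m* has a latent per-cell
mean

    e_m(pop, temp) = temperature_effect · I[temp = 30]
                   + population_effect(pop)
                   + interaction_effect(pop, temp)

realized per sample with standard-normal replicate noise. Effects are
therefore in replicate-SD units: an effect of 2 moves a cell two
replicate standard deviations.

**Genes.** Gene *g* in module *m* has log-scale expression

    x_gs = μ_g + λ_g · e_m(s) + Σ_b w_gb · batch_b(s) + ε_gs

with loading λ_g ~ N(loading_mean, loading_sd²) (defaults 0.8, 0.1),
gene noise ε ~ N(0, 0.6²), batch loadings w_gb ~ N(0, batch_effect_sd²)
(default 0.5, two factors) applied to *all* genes including background,
and baseline μ_g ~ N(5.5, 1²) in natural-log units (median ≈ 250
counts). Background genes have λ = 0. Counts are negative-binomial with
dispersion α = 0.05 (variance μ + αμ²) after multiplying by a per-sample
library-size factor drawn uniformly from (0.7, 1.4). All draws use named
RNG substreams keyed on (seed, purpose, module), so adding a module
never perturbs another module's draws, and identical designs + seed are
bit-reproducible.

**Canonical study design** (`default_study_design`): five modules of
400/350/250/150/50 genes plus 800 background genes. The latent profiles
are deliberately non-collinear, as distinct modules in real
transcriptomes are: shared plasticity up (+2) and down (−2); divergent
baseline with the baseline shift weighted more heavily than the retained
temperature response (oxidative +3, temperature +1.5) — matching the
empirical signature where the population F of diverged modules is well
above their temperature F; evolved plasticity as opposite-direction
temperature responses in the two stress lines (heat +2, oxidative −2 at
30°, no shared temperature effect) — the signature of independently
evolved plasticity, and the configuration whose interaction
noncentrality (λ = 24 at n = 6/cell) gives the ANOVA adequate power,
where a single-cell bump of the same magnitude (λ = 9) would not; and
non-plastic divergence confined to the control line. A module whose
latent profile correlates ≈ 0.4+ with another's is *not* reliably
separable by any correlation-network method at realistic per-gene
signal-to-noise ratios — that is a property of the inference problem,
not of this implementation.

**Compositional caveat.** Median-of-ratios normalization assumes most
genes are not differentially expressed. If a simulated dataset consists
mostly of one coregulated module, the size factors absorb the module's
own treatment response. Simulated studies therefore always include
background genes in realistic proportion.

**What the generator does not emulate:** gene-length and GC effects,
count outliers/contamination, correlated (non-factorial) batch
structure, dropout, and any sequence-level process. Passing tests show
the pipeline recovers structure of this idealized kind; they do not
certify performance on real libraries.

## Preprocessing

Order is fixed and recorded in a transform log: normalize → variance
filter → VST → surrogate-variable removal.

* **Size factors** — median over reference genes (nonzero in every
  sample) of the ratio to the gene's geometric mean. Exact invariant:
  scaling one sample's counts by c scales its factor *relative to every
  other sample* by c (all factors also pick up the common geometric-mean
  renormalization c^(−1/n)).
* **VST** — default `log2(count/factor + 1)`; an NB-motivated
  `log2(count/factor + 1/(2α))` dialect is available. Closed-form and
  variance-stabilizing to first order for large means (checked by
  simulation: the slope of variance against mean across genes is ≈ 0).
* **Variance filter** — drops the 40% of genes with lowest variance,
  computed on the VST scale across all samples (the VST scale is robust
  to library size; raw-count variance would conflate depth with
  biology). Retains ceil(0.6·G) genes, stable order, ties broken by
  position.
* **SVA** — each gene is regressed on population + temperature +
  interaction; surrogate variables are the top sample-space singular
  vectors of the residual matrix. Two essential refinements of the plain
  residual-SVD estimator, both standard in practice:
  1. *Design-p weighting*: genes are weighted by √(design p-value)
     before the SVD. Without it, the shared replicate noise of a large
     coexpression module — which is a genuine latent factor — dominates
     the leading singular vectors, and regressing it out bleeds
     correlation across modules (measured on synthetic data: full-network
     recovery ARI drops from ≈ 0.9 to ≈ 0.7).
  2. *Two-step rebuild*: each factor is re-estimated as the first PC of
     the raw (unresidualized) expression of the genes most associated
     with it, recovering the component of the latent factor that is
     collinear with the design (otherwise a batch vector partially
     aligned with the design can only be recovered up to its residual
     projection; measured recovery improves from |r| ≈ 0.84–0.92 to
     ≈ 0.999 for a planted batch factor at SD 1).
  The number of factors is chosen by permutation parallel analysis
  (20 within-gene permutations, 95th-percentile threshold) or pinned.
  Removal is per-gene OLS on intercept + SVs, keeping the intercept; the
  residuals re-regress on the SVs to ≤ 1e−8.

## Ordination and PERMANOVA

Bray–Curtis requires non-negative data; SVA residuals are shifted by the
global minimum first (rank structure preserved; recorded in the
transform log). nMDS minimizes Kruskal stress-1 by alternating isotonic
regression of configuration distances on dissimilarity ranks with
Guttman (SMACOF) updates; disparities are rescaled each iteration so
Σd̂² = Σd²; if stress ever increases the previous configuration is kept,
so the recorded stress sequence is non-increasing. Twenty starts by
default: one metric (principal-coordinates) start plus random starts;
best stress wins; scores are centered.

PERMANOVA partitions the Gower-centered matrix G with sequential
(Type-I) projections in the order population, temperature, interaction;
pseudo-F uses the residual mean square; p-values come from free
permutation of sample labels, p = (1 + #{F* ≥ F}) / (1 + n_perm). With
199 permutations and α = 0.05 the type-I error is exact on the
permutation grid; calibration is verified on 200 null simulations.
A degenerate but instructive case: when *all* pairwise distances are
equal, the between-group sum of squares is strictly positive and the
pseudo-F equals exactly 1 for balanced groups (not 0); every permutation
gives the same F, so p = 1.

## Network construction and tree cut

Signed adjacency `((1 + r)/2)^β` with Pearson r and β = 5; zero-variance
genes are rejected by name. TOM uses the standard formula applied to the
signed adjacency (the WGCNA default for signed networks); the matrix
implementation is oracle-checked against the triple-loop sum.
Clustering is exact average linkage (UPGMA) on 1 − TOM.

The dynamic hybrid tree cut works in two stages. Stage 1: a static cut
at height 0.905 defines branches; branches are then recursively split
at a merge node when both children (i) hold ≥ 30 leaves, (ii) have a
tight core — the mean of their lowest 29 internal merge heights, on a
scale normalized so the 5th percentile of merge heights is 0 and the cut
height is 1, below 0.64 + 0.08·deepSplit — and (iii) are separated from
the joining height by at least (1 − maxCoreScatter)·3/4. Small side
branches (< 30 leaves) are trimmed off and the recursion continues down
the main branch. Stage 2 (PAM-like, crossing branch boundaries since
`pam_respects_hybrid = false`): each unlabeled gene joins the module
with the smallest average TOM dissimilarity, provided that average is at
most the cut height; ties break toward the lower label. Labels are
renumbered by decreasing module size; 0 means unassigned. The behavioral
standard for this component is planted-block recovery, not label-exact
agreement with any particular implementation.

## Stability resampling

Each of the n_resamples subsamples keeps exactly 4 of the 6 replicates
per treatment cell (uniform, without replacement, independent across
cells and resamples, deterministic given the seed) and the network is
rebuilt with the full network's parameters. Credit rule: a resampled
module overlapping ≥ 10% of a full module's genes credits the
overlapping genes to that module; one resampled module may credit
several full modules; a gene is credited at most once per resample and
only toward its own full-network module. A gene keeps its label iff
credited in ≥ 70% of resamples. Threshold comparisons use an epsilon
guard so 0.10 × 100 = 10 and 0.70 × 100 = 70 behave as exact integer
boundaries. Merging of eigengene-correlated modules (r > 0.9) uses
connected components of the thresholded correlation graph and iterates
to a fixed point (merging changes eigengenes; iteration makes the
operation idempotent — a single-pass switch exists). Finally modules
under 30 genes are dissolved ("fewer than 30", so 30 survives).

The default analysis uses 25 resamples rather than 100: at this problem
size (2,000 genes) the retention fractions are far from the 70%
boundary for essentially all genes, so the decision is insensitive to
the extra resamples; the full 100 remains the library default for the
`run_stability`/CLI surface.

## Eigengene statistics and classification

Genes are standardized (centered, unit variance) before the SVD, so
variance-explained percentages are comparable across modules; the
eigengene is the first right singular vector, oriented to correlate
positively with the module's mean standardized profile (deterministic).
The ancestor environment test is a pooled-variance two-sample t
(df = n₁ + n₂ − 2; Welch available behind a flag). The ANOVA is
fixed-effects with Type-I sums of squares from cell means — identical to
Type-III on the balanced design this pipeline assumes (df 1, 3, 3 over
40 for 4 × 2 × 6); a zero residual SS is flagged degenerate and
reported with p = 0. Tukey HSD uses the two-way ANOVA residual mean
square and df (not a one-way MSE), studentized-range adjusted p over all
6 population pairs, pooled across temperatures — matching the single
population main effect in the ANOVA. The compact letter display assigns
a letter to each maximal clique of the non-significance graph, so two
populations share a letter iff their adjusted p exceeds α.

Classification at α = 0.05 (configurable): interaction < α →
evolved/divergent plasticity; else temperature and population < α →
divergent baseline; temperature only → shared plasticity; population
only → non-plastic divergence; otherwise no signal. This decision table
has an irreducible error floor: a true shared-plasticity module is
misclassified whenever either null term is spuriously significant
(≈ 1 − 0.95² ≈ 10%, slightly less because the tests share a
denominator). Classification-rate checks therefore hover near 90%
correct for shared plasticity by construction.

## Enrichment

The universe is the set of testable genes (those present after
preprocessing / carrying a label), not the genome — conditioning on
testability. Homolog expansion replaces each set member by all of its
mapped target genes (set semantics; unmapped genes drop out). The test
is the upper-tail hypergeometric (one-tailed Fisher), odds ratio
(a·d)/(b·c) with ∞ when b·c = 0 and a·d > 0. BH FDR is applied within
each collection (so adding an unrelated collection never changes another
collection's q-values), step-up with capping at 1.

## Numerical and engineering choices

* Unassigned is integer label 0 throughout.
* All thresholds compare with a 1e−9 epsilon where a fraction times a
  count must behave as an integer boundary.
* Adjacency/TOM are computed as dense matrices (fine to ~10⁴ genes on a
  laptop); the contract for any blockwise variant is value-identity.
* The pipeline derives per-stage seeds from one global seed by hashing
  the stage name, so stages can be re-run in isolation and the full run
  is byte-reproducible.
* Module eigengene requires ≥ 2 non-constant genes; singleton modules
  are skipped by the merge step and dissolved by the minimum-size purge.

## Known limitations

* The dynamic tree cut is a faithful but independent implementation of
  the hybrid algorithm's published ideas; its deep-split → parameter
  mapping is calibrated to planted-block recovery, and label-exact
  agreement with other implementations is not claimed.
* PERMANOVA uses free permutation only; restricted/residual permutation
  schemes are out of scope.
* SVA here is not iteratively reweighted to convergence; one weighting
  pass plus the two-step rebuild suffices for factorial batch structure,
  but confounding between batch and design degrades gracefully rather
  than being modeled.
* nMDS axes are descriptive; no axis-significance testing is performed,
  and gene-level contributions to axes are deliberately not reported
  (they are not interpretable for a non-metric embedding).
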