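# Methods

`osteosig` implements a two-arm prognostic-signature analysis for bulk tumor
RNA-seq cohorts, modeled on comparative-oncology practice in osteosarcoma:
a *signature application* arm (cluster a cohort on a supplied gene
signature, then compare the clusters' outcomes) and a *signature discovery*
arm (derive signatures de novo from enrichment-space clustering, moderated
differential expression, and consensus bi-clustering, then transfer them to
a second cohort by shared gene symbols).  This note records the models,
parameter choices, numerical decisions, and limits of what the synthetic
cohorts can demonstrate.

## Preprocessing

**Low-count filter.** A gene is retained when its CPM reaches
`min_count / median(library size) x 1e6` in at least `S` samples, where `S`
equals the smallest group size `n_min` if `n_min <= large_n`, else
`large_n + (n_min - large_n) * min_prop`, and when its total count is at
least `min_total_count`.  Defaults: `min_count = 10`, `min_prop = 0.5`,
`large_n = 5`, `min_total_count = 15`.  Comparisons carry a 1e-14 slack so
floating-point ties resolve as in the R reference implementation.  The
filter is idempotent and returns a row subset.  A gene whitelist argument
stands in for annotation-based filtering (e.g. protein-coding-only
universes) without a GTF parser.

**Probe collapsing.** Rows sharing an uppercased symbol are replaced by
their arithmetic mean; empty/"NA" symbols are dropped with a logged count.

**Quantile normalization.** Every sample is forced onto the per-rank mean
of the sorted columns.  Ties receive the mean of the reference values at
their tied ranks (the "average ties" dialect).  On tie-free matrices this
agrees with limma's `normalizeQuantiles` to 1e-13 (cross-checked via
Rscript in the test suite); tie handling is deliberately the rank-mean rule
rather than limma's interpolation.

**TMM scaling.** Between-sample factors are the classic trimmed mean of
M-values: reference column = the one whose 75th count-fraction percentile
is closest to the mean; 30% trim on M, 5% on A, inverse asymptotic-variance
weights, factors rescaled to geometric mean 1.  Agreement with edgeR's
`calcNormFactors` is ~1e-5 on test fixtures.  Note the method corrects only
part of a compositional shift when a large fraction of genes moves in one
direction; the DE simulations therefore plant signed (balanced) effects.

**log2-CPM.** `log2((count + prior) / (libsize x factor + 2 prior) x 1e6)`
with `prior = 0.5`.  The prior bounds the transform at zero counts at the
cost of exact depth invariance (distortion ~ `prior / (2 count ln 2)`).

## ssGSEA and two-class GSEA

Per sample, genes are ranked by expression descending with average ranks on
ties.  The ssGSEA score of a set is the integrated difference between the
weighted in-set ECDF (weights `rank^alpha`, `alpha = 0.25`, the top gene
carrying the largest rank value) and the uniform out-of-set ECDF; scores
are normalized by the global max-min range of the profile.  The
implementation is vectorized but is pinned, to 1e-9, against a literal
O(n^2) running-sum oracle in the tests.  `alpha` and the normalization
switch are exposed; scores depend on ranks only, so any monotone
within-sample transform of expression leaves them unchanged.

Two-class GSEA ranks genes by signal-to-noise (group mean difference over
summed SDs, each SD floored at `0.2 |mean| + 1e-8`), scores sets by the
maximum deviation of the weighted KS running sum (hit increments
proportional to `|metric|^weight`, `weight = 1`), and builds the null from
phenotype permutations when the smaller group has >= 7 samples, else from
random gene sets of matching size.  NES divides ES by the mean |null ES| of
the same sign; FDR q follows the pooled positive/negative-ratio rule.  The
permutation count (default 1000) bounds the p-value resolution at
~1/n_perm.

## Clustering

Sample clustering is K-means (scikit-learn, `n_init = 50` restarts per k)
over k = 2..6, selecting the k with maximum mean Euclidean silhouette (ties
to the smaller k), with labels canonicalized by descending cluster size.
For signature-based clustering the feature space is quantile-normalized
expression restricted to the signature genes, z-scored per gene by default
(`zscore_features` switches this off).  Clustering functions never receive
outcome data; FP (favorable) / PP (poor) prognosis labels are attached
afterwards by comparing Kaplan-Meier medians between the two clusters
(undefined median = longest; exact ties label cluster 0 FP with a
warning).  Ward partitions for ISA seeding use scipy's `linkage(...,
"ward")`, i.e. classic Ward on squared Euclidean distances, cut to 10 gene
and 7 sample clusters.

## Moderated differential expression

The voom idea is reimplemented for the two-group design: gene-wise sqrt
residual SDs from an ordinary fit are regressed on average log2-CPM by
lowess (span 0.5); predicted sqrt-SD at each observation's fitted value
gives weight `pred^-4`, clipped to [1e-6, 1e6] with constant extrapolation
beyond the trend range.  Weighted least squares per gene then yields
moderated t-statistics with an empirical-Bayes prior `(d0, s0^2)` estimated
by moment-matching log variances to a scaled F distribution
(digamma/trigamma matching with a Newton trigamma inverse).  `prior_df`
overrides allow the two limiting cases used in the tests: `0` (ordinary t)
and `inf` (pooled variance).  The contrast is lexicographically-first label
minus second, so relabeling groups negates every log2FC.  DEG selection is
strict: linear |FC| > 3 AND BH-adjusted p < 0.05.  BH adjustment delegates
to statsmodels and is property-tested against a hand-rolled step-up.

## Consensus ISA bi-clustering

ISA alternates between sample scores (mean of column-standardized values
over the current gene set, z-scored across samples, thresholded at
`t_sample = 1.5`) and gene scores (mean of row-standardized values over the
current sample set, z-scored across genes, thresholded at `t_gene = 2.0`),
by default keeping |z| exceedances ("signed"); "up" keeps positive ones
only.  The thresholds are the algorithm's customary operating range and are
exposed in `IsaParams`.

**Convergence.** A run converges at a fixed point (identical sets in
consecutive iterations).  In practice ISA frequently enters period-2 limit
cycles in which the state oscillates between two sets differing by a
member or two; treating those runs as failures silently discards perfectly
recovered modules at many RNG seeds.  When the state returns to the state
two iterations back, the run therefore converges on the intersection of
the two alternating states — the stable core — with fixed points as the
special case.  Runs exhausting `max_iter = 50` without either are excluded
from consensus.

**Seeding and consensus.** Ward partitions (10 gene x 7 sample clusters)
are computed once; each of 25 repetitions draws one random 3-member seed
per cluster (17 seeds/run) from an independent RNG stream, runs ISA from
every seed, and contributes its converged modules.  Modules are matched
across runs greedily (largest gene set first) at gene-set Jaccard >= 0.66;
a consensus module must span strictly more than 75% of runs (>= 19 of 25,
reading "more than 75%" strictly), and its membership is items present in
at least half of the matched instances.  Identical seeds reproduce the
output byte for byte.

## Survival statistics

Kaplan-Meier estimation, the two-group log-rank test, and univariate Cox
regression (Breslow ties, Wald test) delegate to lifelines; the log-rank
path was verified against R `survival::survdiff` to 7 digits.  Median
survival is the smallest time with S(t) <= 0.5, undefined when never
reached.  The chi-square goodness of fit uses the Pearson statistic with
k-1 df and the scipy upper tail (property-tested against an independent
incomplete-gamma continued-fraction evaluation to 1e-10); Mann-Whitney U
uses scipy's automatic exact/asymptotic selection with mid-rank ties, and
reports the rank-biserial correlation as effect size.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset: per-gene log2 baselines ~ Normal(5, 2); a planted
"immune module" (270 genes by default) up-shifted by `module_log2fc` in
cluster A (the favorable, immune-hot cluster, 50% of 186 samples);
bi-cluster blocks planted inside the module (default sizes 30/19/39/15
genes, crossed with
sample subsets alternating between the clusters, shifted by 2x the
asymptotic NB log2 noise SD `sqrt(phi)/ln 2`); negative-binomial counts
with `Var = mu + phi mu^2`, `phi = 0.15`, over log-normal library sizes
around 3e7 reads; exponential survival at hazard 1/300 events/day in
cluster A with hazard ratio 2 in cluster B, right-censored by a uniform
administrative horizon solved numerically to hit the target censoring
fraction (25%).

`module_log2fc` defaults to 2.0 (linear FC 4).  A module planted below the
pipeline's own DEG cutoff of linear FC > 3 would be undetectable by
construction, which would defeat the generator's purpose of emulating a
study in which the pipeline demonstrably recovers its immune module; FC 4
is a realistic magnitude for immune hot-versus-cold contrasts in bulk
tumors.  Desk-scale defaults use 2,000 genes rather than ~13,000 so the
full discovery workflow runs in seconds; sizes are configurable.

What the synthetic cohorts do **not** model: batch effects, gene-length
bias (no TPM generation), correlated gene-gene noise beyond the planted
blocks, non-proportional hazards, informative censoring (the euthanasia
problem in veterinary cohorts is treated as plain right-censoring), and
cross-species ortholog divergence (transfer is identity-by-symbol).
Passing the planted-truth tests therefore shows the machinery is correct
and calibrated, not that any particular biological claim holds on real
data.

## Reproducibility

Every stochastic stage draws from a single root seed through named,
CRC-derived substreams (`PipelineConfig.substream`), so individual stages
are independently reproducible and a rerun with the same seed and config
produces byte-identical report bundles.  Report bundles write all tabular
outputs as TSV plus a JSON manifest enumerating files, parameters, and
seeds.

## Known limitations

- Two-group designs only (no covariates, no multi-factor contrasts).
- GSEA leading-edge reporting and plots are not implemented.
- TMM under-corrects strongly one-sided compositional shifts (inherent to
  the method; see above).
- The ISA consensus is stochastic by design; with 25 runs the support
  threshold has a resolution of 1/25.
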