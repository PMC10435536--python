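# osteosig

Prognostic gene-signature discovery and cross-cohort transfer for bulk
tumor RNA-seq.

Osteosarcoma cohorts — canine and human alike — split into immune-hot and
immune-cold sub-populations with different survival.  `osteosig` implements
the full computational path for finding and validating such prognostic
signatures, for bioinformaticians working with genes x samples count
matrices and time-to-event clinical tables:

- **Signature application** (workflow A): preprocess a cohort (edgeR-style
  low-count filtering, quantile normalization), harmonize a supplied gene
  signature into its gene universe by shared symbols, cluster samples
  *outcome-blind* with K-means (k = 2..6 chosen by maximum silhouette),
  label the clusters FP/PP (favorable/poor prognosis) post hoc by
  Kaplan-Meier median, and compare them by log-rank tests, two-class GSEA,
  and voom-style moderated-t differential expression.
- **Signature discovery** (workflow B): score every sample against a
  hallmark-style gene-set collection by ssGSEA, cluster the enrichment
  profile, derive a DEG signature between the clusters (linear FC > 3,
  BH-adjusted p < 0.05), decompose it into gene/sample modules with the
  seeded consensus Iterative Signature Algorithm (25 runs, >75% consensus),
  and re-apply every exported signature to a second — possibly
  cross-species — cohort.
- **Synthetic cohorts**: a first-class generator plants immune-module
  clusters, bi-cluster blocks, negative-binomial count noise and
  cluster-linked exponential survival with known truth, so the entire
  pipeline is testable without any download.

Statistical primitives that have no Python implementation (TMM factors,
`filterByExpr` filtering, quantile normalization, voom/eBayes moderated t,
ssGSEA, permutation GSEA, consensus ISA) are implemented here and
cross-checked against independent oracles — including edgeR and limma via
Rscript — in the test suite; standard survival estimation delegates to
lifelines.  See `docs/methods.md` for models, defaults, and limitations.

## Worked example

Discover a signature on one simulated cohort and transfer it to a second:

```python
import osteosig as og

cfg = og.SimConfig(rng_seed=101)               # 186 samples x 2,000 genes
counts, clinical, truth = og.simulate_cohort(cfg)
sets = og.simulate_genesets(n_genes=cfg.n_genes, rng_seed=303,
                            gene_ids=counts.gene_ids,
                            alias_module=truth.module_genes)
counts2, clinical2, _ = og.simulate_cohort(og.SimConfig(rng_seed=202))

res = og.run_discovery_workflow(counts, clinical, sets,
                                og.PipelineConfig(seed=11),
                                second_cohort=(counts2, clinical2))

degs = set(res["degs"])
jac = len(degs & truth.module_genes) / len(degs | truth.module_genes)
print(f"k selected:            {res['clustering']['k_selected']}")
print(f"DEG signature size:    {len(degs)}")
print(f"module Jaccard:        {jac:.3f}")
print(f"consensus bi-clusters: {len(res['biclusters'])}")
p = res["transfer"]["deg_signature"]["survival"]["logrank_DFI"]["p"]
print(f"transfer log-rank p:   {p:.2e}")
```

prints

```
k selected:            2
DEG signature size:    237
module Jaccard:        0.878
consensus bi-clusters: 2
transfer log-rank p:   2.63e-06
```

The ssGSEA clustering finds the two planted immune clusters (k = 2); the
DEG signature recovers the planted 270-gene module (Jaccard 0.878 — high
precision, with the module genes whose noisy fold change fell under the
strict FC > 3 cutoff accounting for the miss); consensus ISA splits the
signature into coherent gene/sample modules; and K-means clustering of a
*second* cohort on the transferred signature separates survival at
log-rank p = 2.6e-06.

Small-sample statistics work the same way; for example a goodness-of-fit
check of an observed 5/15 two-group split against expected 6.3/13.7:

```python
r = og.chisq_gof([5, 15], [6.3, 13.7])
print(f"chi2 = {r.statistic:.3f}, p = {r.p:.3f}")
# chi2 = 0.392, p = 0.531
```

## Command line

Every stage is also a subcommand of the `osteosig` console script:

```sh
osteosig simulate --seed 4 --out-dir sim/
osteosig preprocess --counts sim/counts.tsv --norm tmm-logcpm \
    --collapse-duplicates --out lcpm.tsv
osteosig ssgsea --expr lcpm.tsv --gmt sim/sets.gmt --out scores.tsv
osteosig workflow-b --counts sim/counts.tsv --clinical sim/clinical.tsv \
    --gmt sim/sets.gmt --seed 9 --out-dir results/
```

Inputs are plain text (TSV or GCT 1.2 expression, GMT gene sets,
one-symbol-per-line signatures, TSV clinical tables); outputs are TSV/JSON
plus a manifest recording every file, parameter, and seed, byte-identical
across reruns with the same seed.

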