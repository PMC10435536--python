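"""End-to-end workflows: signature application and signature discovery.

Workflow A (application): preprocess a cohort, harmonize a supplied gene
signature into its gene universe, cluster samples outcome-blind on the
signature genes, attach FP/PP prognosis labels post hoc, and compare the
clusters by Kaplan-Meier/log-rank, two-class GSEA, and differential
expression.

Workflow B (discovery): preprocess, score every sample against a gene-set
collection by ssGSEA, cluster the enrichment profile, derive a DEG
signature between the clusters, decompose it into modules by consensus ISA
bi-clustering, and re-apply each exported signature to a second (held-out
or cross-species) cohort via workflow A.

Clustering stages never see clinical data: outcome enters only after the
partition is fixed.  All stochastic stages draw from a single root seed
through named substreams, so every stage is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from . import io as osio
from .cluster import assign_prognosis_labels, kmeans_select_k, zscore_rows
from .dge import DegThresholds, fit_moderated, select_degs, voom_transform
from .enrichment import gsea_two_class, ssgsea_score
from .isa import IsaParams, isa_consensus
from .preprocess import (
    FilterParams,
    collapse_duplicate_genes,
    filter_low_counts,
    logcpm,
    quantile_normalize,
    tmm_factors,
)
from .survival import km_estimate, logrank_test
from .types import (
    ClinicalTable,
    ClusteringResult,
    ExpressionMatrix,
    GeneSetCollection,
    GeneSignature,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "WorkflowAbort", "run_signature_workflow", "run_discovery_workflow"]


class WorkflowAbort(RuntimeError):
    """Raised when a workflow cannot proceed; carries a report dict."""

    def __init__(self, message: str, report: Optional[dict] = None):
        super().__init__(message)
        self.report = report or {}


@dataclass
class PipelineConfig:
    """Shared knobs for both workflows; ``seed`` is mandatory."""

    seed: int
    filter_params: FilterParams = field(default_factory=FilterParams)
    deg_thresholds: DegThresholds = field(default_factory=DegThresholds)
    isa_params: IsaParams = field(default_factory=IsaParams)
    ssgsea_alpha: float = 0.25
    k_min: int = 2
    k_max: int = 6
    n_init: int = 50
    zscore_features: bool = True
    gsea_n_perm: int = 1000

    def substream(self, name: str) -> int:
        """A deterministic 31-bit child seed for a named stage."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        return int(ss.generate_state(1)[0] % 2**31)

    def params_dict(self) -> dict:
        d = asdict(self)
        return d


def _survival_comparison(clust: ClusteringResult, clinical: ClinicalTable) -> dict:
    """KM curves and log-rank per endpoint between the two prognosis groups."""
    out = {}
    for endpoint in clinical.endpoints():
        table = clinical.for_endpoint(endpoint)
        groups, times, events = [], [], []
        for c in sorted(clust.labels.unique()):
            ids = [s for s in clust.cluster_samples(c) if s in table.index]
            sub = table.loc[ids]
            label = clust.prognosis_labels.get(c, str(c)) if clust.prognosis_labels else str(c)
            curve = km_estimate(sub["time_days"].to_numpy(), sub["event"].to_numpy())
            out[f"km_{endpoint}_{label}"] = {
                "median": curve.median,
                "n": len(ids),
                "n_events": int(sub["event"].sum()),
            }
            groups += [label] * len(ids)
            times += list(sub["time_days"])
            events += list(sub["event"])
        lr = logrank_test(times, events, groups)
        out[f"logrank_{endpoint}"] = {"chi2": lr.statistic, "p": lr.p}
    return out


def run_signature_workflow(
    counts: ExpressionMatrix,
    clinical: ClinicalTable,
    signature: GeneSignature,
    cfg: PipelineConfig,
    gene_sets: Optional[GeneSetCollection] = None,
    run_dge: bool = True,
    out_dir=None,
) -> dict:
    """Apply a gene signature to a cohort and compare the resulting clusters.

    Returns a results dict; writes a report bundle with a manifest when
    ``out_dir`` is given.  Aborts (with a report) when fewer than 2
    signature genes survive harmonization into the cohort's gene universe.
    """
    filtered = filter_low_counts(counts, cfg.filter_params)
    collapsed = collapse_duplicate_genes(filtered)
    qnorm = quantile_normalize(collapsed)

    mapped, dropped = osio.harmonize_symbols(signature, qnorm.gene_ids)
    if mapped is None or len(mapped) < 2:
        report = {"signature": signature.name, "n_mapped": 0 if mapped is None else len(mapped),
                  "dropped": dropped}
        raise WorkflowAbort(
            f"fewer than 2 genes of signature {signature.name!r} survive harmonization",
            report,
        )

    sub = qnorm.subset_genes(mapped.genes)
    feats = zscore_rows(sub.values).T if cfg.zscore_features else sub.values.T
    clust = kmeans_select_k(
        feats,
        sub.sample_ids,
        k_range=range(cfg.k_min, cfg.k_max + 1),
        n_init=cfg.n_init,
        seed=cfg.substream("kmeans"),
        feature_space="signature-genes",
    )
    results: dict = {
        "signature": {"name": signature.name, "n_mapped": len(mapped), "dropped": dropped},
        "clustering": {
            "k_selected": clust.k_selected,
            "silhouette_by_k": clust.silhouette_by_k,
        },
    }
    survival = None
    if clust.k_selected == 2:
        clust = assign_prognosis_labels(clust, clinical)
        survival = _survival_comparison(clust, clinical)
        results["survival"] = survival
        results["clustering"]["prognosis_labels"] = clust.prognosis_labels
    labels_named = clust.labels.map(
        lambda c: clust.prognosis_labels.get(c, str(c)) if clust.prognosis_labels else str(c)
    )
    results["labels"] = labels_named

    if gene_sets is not None and clust.k_selected == 2:
        gsea = gsea_two_class(
            qnorm,
            labels_named.reindex(qnorm.sample_ids).tolist(),
            gene_sets,
            n_perm=cfg.gsea_n_perm,
            seed=cfg.substream("gsea"),
            positive_label="FP",
        )
        results["gsea"] = [
            {"set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p, "q": r.q,
             "direction": r.direction, "n_genes": r.n_genes}
            for r in gsea
        ]

    if run_dge and clust.k_selected == 2:
        counts_collapsed = collapse_duplicate_genes(filtered)
        factors = tmm_factors(counts_collapsed)
        group_labels = labels_named.reindex(counts_collapsed.sample_ids).tolist()
        lcpm, weights = voom_transform(counts_collapsed, factors, group_labels)
        deg_table = fit_moderated(lcpm, weights, group_labels)
        degs = select_degs(deg_table, cfg.deg_thresholds)
        results["deg_table"] = deg_table
        results["degs"] = sorted(degs.genes) if degs else []

    if out_dir is not None:
        _write_bundle(results, out_dir, cfg, workflow="signature")
    return results


def run_discovery_workflow(
    counts: ExpressionMatrix,
    clinical: ClinicalTable,
    gene_sets: GeneSetCollection,
    cfg: PipelineConfig,
    second_cohort: Optional[Tuple[ExpressionMatrix, ClinicalTable]] = None,
    out_dir=None,
) -> dict:
    """Derive signatures de novo from a cohort and optionally transfer them.

    Pipeline: filter -> TMM -> log2-CPM -> collapse duplicates -> ssGSEA on
    ``gene_sets`` -> K-means on the enrichment profile -> voom/moderated-t
    DEG between the clusters -> consensus ISA on the DEG-restricted
    expression -> signature export.  When zero genes pass the DEG cutoffs
    the workflow ends after the DEG stage with an explanatory report.  Each
    exported signature (the DEG signature and one per ISA module) is
    re-applied to ``second_cohort`` through the signature workflow.
    """
    filtered = filter_low_counts(counts, cfg.filter_params)
    factors = tmm_factors(filtered)
    lcpm = logcpm(filtered, factors)
    lcpm_collapsed = collapse_duplicate_genes(lcpm)

    profile = ssgsea_score(lcpm_collapsed, gene_sets, alpha=cfg.ssgsea_alpha)
    clust = kmeans_select_k(
        profile.scores,
        profile.sample_ids,
        k_range=range(cfg.k_min, cfg.k_max + 1),
        n_init=cfg.n_init,
        seed=cfg.substream("kmeans-ssgsea"),
        feature_space="ssgsea-scores",
    )
    results: dict = {
        "ssgsea": profile.to_frame(),
        "clustering": {
            "k_selected": clust.k_selected,
            "silhouette_by_k": clust.silhouette_by_k,
        },
        "labels": clust.labels.astype(str),
    }
    if clust.k_selected != 2:
        log.warning("discovery clustering selected k=%d; using top-2 split for DEG",
                    clust.k_selected)
    group_labels = clust.labels.map(lambda c: "C0" if c == 0 else "C1")

    counts_collapsed = collapse_duplicate_genes(filtered)
    factors_c = tmm_factors(counts_collapsed)
    lab_list = group_labels.reindex(counts_collapsed.sample_ids).tolist()
    lcpm_c, weights = voom_transform(counts_collapsed, factors_c, lab_list)
    deg_table = fit_moderated(lcpm_c, weights, lab_list)
    degs = select_degs(deg_table, cfg.deg_thresholds, name="deg_signature")
    results["deg_table"] = deg_table
    if degs is None:
        results["degs"] = []
        results["biclusters"] = []
        results["status"] = "no genes passed the DEG thresholds; stopped after DEG stage"
        if out_dir is not None:
            _write_bundle(results, out_dir, cfg, workflow="discovery")
        return results
    results["degs"] = sorted(degs.genes)

    deg_expr = lcpm_collapsed.subset_genes(degs.genes)
    isa_params = IsaParams(
        **{
            **{f: getattr(cfg.isa_params, f) for f in cfg.isa_params.__dataclass_fields__},
            "rng_seed": cfg.substream("isa"),
        }
    )
    biclusters = isa_consensus(deg_expr.values, deg_expr.gene_ids, deg_expr.sample_ids, isa_params)
    results["biclusters"] = [
        {"genes": sorted(b.gene_set), "samples": sorted(b.sample_set), "support": b.support}
        for b in biclusters
    ]

    signatures = [degs] + [
        GeneSignature(f"isa_signature_{i + 1}", b.gene_set) for i, b in enumerate(biclusters)
    ]
    results["signatures"] = {s.name: sorted(s.genes) for s in signatures}

    if second_cohort is not None:
        counts2, clinical2 = second_cohort
        transfer = {}
        for sig in signatures:
            try:
                res2 = run_signature_workflow(
                    counts2, clinical2, sig, cfg, gene_sets=None, run_dge=False
                )
            except WorkflowAbort as exc:
                transfer[sig.name] = {"status": "aborted", "reason": str(exc)}
                continue
            transfer[sig.name] = {
                "status": "ok",
                "k_selected": res2["clustering"]["k_selected"],
                "survival": res2.get("survival"),
            }
        results["transfer"] = transfer

    if out_dir is not None:
        _write_bundle(results, out_dir, cfg, workflow="discovery")
    return results


def _write_bundle(results: dict, out_dir, cfg: PipelineConfig, workflow: str) -> dict:
    import pandas as pd

    writable = {}
    for key, obj in results.items():
        if isinstance(obj, (pd.DataFrame, pd.Series, ExpressionMatrix, ClinicalTable)):
            writable[key] = obj
        else:
            writable[key] = obj  # JSON-serializable payloads
    params = {"workflow": workflow, "seed": cfg.seed,
              "filter_params": asdict(cfg.filter_params),
              "deg_thresholds": asdict(cfg.deg_thresholds),
              "isa_params": asdict(cfg.isa_params),
              "ssgsea_alpha": cfg.ssgsea_alpha,
              "k_range": [cfg.k_min, cfg.k_max],
              "n_init": cfg.n_init,
              "zscore_features": cfg.zscore_features}
    manifest = osio.write_report_bundle(writable, out_dir, params=params)
    results["manifest"] = manifest
    return manifest
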