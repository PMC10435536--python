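"""Gene-set enrichment scoring.

Two flavors are provided: per-sample ssGSEA scores (the feature space for
outcome-blind clustering of a cohort) and a two-class GSEA with a
permutation null (the contrast between prognosis clusters).  Both follow
the canonical rank-weighted running-sum formulation; ssGSEA integrates the
running difference over all ranks while two-class GSEA takes the maximum
deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .types import EnrichmentProfile, ExpressionMatrix, GeneSetCollection, warn

log = logging.getLogger(__name__)

__all__ = ["ssgsea_score", "gsea_two_class", "GseaResult"]


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentProfile:
    """Single-sample GSEA enrichment scores (samples x sets).

    Per sample, genes are ranked by expression descending (average ranks on
    ties).  The enrichment score for a set is the sum over ranked positions
    of the difference between the weighted in-set ECDF (weights proportional
    to rank^alpha, the top gene carrying the largest rank value) and the
    uniform out-of-set ECDF.  With ``normalize``, all scores are divided by
    the global (max - min) across the profile.
    """
    genes_upper = [g.upper() for g in expr.gene_ids]
    if len(set(genes_upper)) != len(genes_upper):
        raise ValueError("ssgsea_score requires unique gene symbols; collapse duplicates first")
    gene_index = {g: i for i, g in enumerate(genes_upper)}
    n = expr.n_genes

    set_rows = []
    kept_names = []
    for set_name, members in sets:
        idx = np.array(sorted(gene_index[g] for g in members if g in gene_index), dtype=int)
        if idx.size == 0:
            warn(f"gene set {set_name!r} has no genes in the matrix; skipped")
            continue
        if idx.size == n:
            raise ValueError(f"gene set {set_name!r} covers every gene (empty out-set)")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        set_rows.append(mask)
        kept_names.append(set_name)
    if not set_rows:
        raise ValueError("no gene set overlaps the expression matrix")

    scores = np.empty((expr.n_samples, len(kept_names)))
    for j in range(expr.n_samples):
        col = expr.values[:, j]
        ranks = rankdata(col)  # ascending, average ties: top gene gets ~n
        order = np.argsort(-col, kind="mergesort")
        w = ranks[order] ** alpha
        for si, mask in enumerate(set_rows):
            hit = mask[order]
            w_hit = np.where(hit, w, 0.0)
            cum_in = np.cumsum(w_hit) / w_hit.sum()
            cum_out = np.cumsum(~hit) / (n - hit.sum())
            scores[j, si] = np.sum(cum_in - cum_out)

    if normalize:
        rng_span = scores.max() - scores.min()
        if rng_span > 0:
            scores = scores / rng_span
    return EnrichmentProfile(list(expr.sample_ids), kept_names, scores, alpha, normalize)


@dataclass
class GseaResult:
    """One gene set's two-class GSEA outcome."""

    set_name: str
    es: float
    nes: float
    p: float
    q: float
    direction: str  # group label the set is enriched in
    n_genes: int

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("FDR q must lie in [0, 1]")
        if self.es * self.nes < 0:
            raise ValueError("NES must carry the sign of ES")


def _signal_to_noise(X: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Per-gene (mean_A - mean_B) / (sd_A + sd_B) with SD floors at 0.2|mean|."""
    a, b = X[:, in_a], X[:, ~in_a]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sa = np.maximum(sa, 0.2 * np.abs(ma) + 1e-8)
    sb = np.maximum(sb, 0.2 * np.abs(mb) + 1e-8)
    return (ma - mb) / (sa + sb)


def _es_max_dev(metric: np.ndarray, order: np.ndarray, mask: np.ndarray, weight: float) -> float:
    """Weighted KS running-sum enrichment score (maximum deviation)."""
    hit = mask[order]
    n = metric.size
    n_hit = int(hit.sum())
    w = np.abs(metric[order]) ** weight
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        w_hit = hit.astype(float)
        denom = float(n_hit)
    running = np.cumsum(w_hit / denom - (~hit) / (n - n_hit))
    return float(running[np.argmax(np.abs(running))])


def gsea_two_class(
    expr: ExpressionMatrix,
    labels: Sequence,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: Optional[int] = None,
    positive_label=None,
) -> list:
    """Two-class GSEA with a permutation null and FDR by the pooled-NES rule.

    Genes are ranked by signal-to-noise between the two groups (positive
    metric = higher in ``positive_label``, defaulting to the first label in
    order of appearance).  The null is phenotype permutation when the
    smaller group has at least 7 samples, otherwise gene-set permutation.
    NES divides ES by the mean |null ES| of the same sign; FDR q follows the
    positive/negative pool-ratio rule.  Results are sorted by NES
    descending.
    """
    labels = np.asarray([str(x) for x in labels])
    if labels.size != expr.n_samples:
        raise ValueError("labels length must equal sample count")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    if positive_label is None:
        positive_label = uniq[0]
    negative_label = uniq[1] if str(positive_label) == uniq[0] else uniq[0]
    in_a = labels == str(positive_label)
    if in_a.sum() < 3 or (~in_a).sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    if n_perm < 100:
        warn(f"n_perm={n_perm} is low; p-values and FDR will be coarse")
    rng = np.random.default_rng(seed)

    genes_upper = [g.upper() for g in expr.gene_ids]
    gene_index = {g: i for i, g in enumerate(genes_upper)}
    n = expr.n_genes
    masks, names = [], []
    for set_name, members in sets:
        idx = [gene_index[g] for g in members if g in gene_index]
        if not idx:
            warn(f"gene set {set_name!r} has no genes in the matrix; skipped")
            continue
        if len(idx) == n:
            raise ValueError(f"gene set {set_name!r} covers every gene")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        masks.append(mask)
        names.append(set_name)
    if not masks:
        raise ValueError("no gene set overlaps the expression matrix")

    X = expr.values
    metric = _signal_to_noise(X, in_a)
    order = np.argsort(-metric, kind="mergesort")
    es_obs = np.array([_es_max_dev(metric, order, m, weight) for m in masks])

    null_es = np.empty((n_perm, len(masks)))
    phenotype_null = min(in_a.sum(), (~in_a).sum()) >= 7
    if phenotype_null:
        for p in range(n_perm):
            perm = rng.permutation(in_a)
            pm = _signal_to_noise(X, perm)
            po = np.argsort(-pm, kind="mergesort")
            null_es[p] = [_es_max_dev(pm, po, m, weight) for m in masks]
    else:
        for si, m in enumerate(masks):
            size = int(m.sum())
            for p in range(n_perm):
                rand_mask = np.zeros(n, dtype=bool)
                rand_mask[rng.choice(n, size=size, replace=False)] = True
                null_es[p, si] = _es_max_dev(metric, order, rand_mask, weight)

    nes_obs = np.empty_like(es_obs)
    null_nes = np.full_like(null_es, np.nan)
    for si in range(len(masks)):
        pos = null_es[:, si] > 0
        neg = null_es[:, si] < 0
        mean_pos = null_es[pos, si].mean() if pos.any() else np.nan
        mean_neg = np.abs(null_es[neg, si]).mean() if neg.any() else np.nan
        scale = mean_pos if es_obs[si] >= 0 else mean_neg
        nes_obs[si] = es_obs[si] / scale if np.isfinite(scale) and scale > 0 else 0.0
        if pos.any():
            null_nes[pos, si] = null_es[pos, si] / mean_pos
        if neg.any():
            null_nes[neg, si] = null_es[neg, si] / mean_neg

    results = []
    pool = null_nes[np.isfinite(null_nes)]
    for si, set_name in enumerate(names):
        es, nes = es_obs[si], nes_obs[si]
        col = null_es[:, si]
        if es >= 0:
            same = col[col > 0]
            p_nom = (same >= es).sum() / max(same.size, 1)
        else:
            same = col[col < 0]
            p_nom = (same <= es).sum() / max(same.size, 1)
        if nes >= 0:
            num_pool = pool[pool > 0]
            obs_pool = nes_obs[nes_obs > 0]
            num = (num_pool >= nes).mean() if num_pool.size else 1.0
            den = (obs_pool >= nes).mean() if obs_pool.size else 1.0
        else:
            num_pool = pool[pool < 0]
            obs_pool = nes_obs[nes_obs < 0]
            num = (num_pool <= nes).mean() if num_pool.size else 1.0
            den = (obs_pool <= nes).mean() if obs_pool.size else 1.0
        q = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
        results.append(
            GseaResult(
                set_name=set_name,
                es=float(es),
                nes=float(nes),
                p=float(min(p_nom, 1.0)),
                q=q,
                direction=str(positive_label) if es >= 0 else str(negative_label),
                n_genes=int(masks[si].sum()),
            )
        )
    results.sort(key=lambda r: -r.nes)
    return results
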