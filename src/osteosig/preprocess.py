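"""Entry-stage preprocessing for bulk RNA-seq count matrices.

Implements the standard edgeR-style low-count filter (``filterByExpr``
semantics), probe-to-gene collapsing by averaging, quantile normalization,
TMM between-sample scaling factors, and the log2-CPM transform.  The filter
and TMM are reimplemented here to the published semantics of those methods
because no installed Python package provides them for dense matrices; both
are cross-checked against the R reference implementations in the test
suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, warn

log = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "NormFactors",
    "filter_low_counts",
    "collapse_duplicate_genes",
    "quantile_normalize",
    "tmm_factors",
    "logcpm",
]


@dataclass(frozen=True)
class FilterParams:
    """Low-count filter settings (edgeR ``filterByExpr`` parameterization).

    ``min_count`` is converted to a CPM cutoff against the median library
    size; a gene must reach that CPM in enough samples, where "enough" is
    the smallest group size shrunk through ``large_n``/``min_prop`` when
    groups are large.
    """

    min_count: float = 10.0
    min_prop: float = 0.5
    large_n: int = 5
    min_total_count: float = 15.0

    def __post_init__(self):
        if self.min_count <= 0:
            raise ValueError("min_count must be > 0")
        if not (0.0 <= self.min_prop <= 1.0):
            raise ValueError("min_prop must lie in [0, 1]")


@dataclass
class NormFactors:
    """Per-sample positive scaling factors with geometric mean 1."""

    factors: pd.Series  # sample_id -> factor

    def __post_init__(self):
        self.factors = pd.Series(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors.to_numpy())))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")

    def align(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors.index]
        if missing:
            raise KeyError(f"no scaling factor for samples: {missing}")
        return self.factors.reindex(sample_ids).to_numpy()

    @classmethod
    def trivial(cls, sample_ids: Sequence[str]) -> "NormFactors":
        return cls(pd.Series(1.0, index=list(sample_ids)))


_TOL = 1e-14


def filter_low_counts(
    counts: ExpressionMatrix,
    params: FilterParams = FilterParams(),
    groups: Optional[Sequence] = None,
    gene_whitelist: Optional[set] = None,
) -> ExpressionMatrix:
    """Remove genes too lowly expressed to support inference.

    A gene is kept iff (a) its CPM reaches ``C = min_count / median(lib) * 1e6``
    in at least ``S`` samples, where ``S`` is the smallest group size
    ``n_min`` when ``n_min <= large_n`` and
    ``large_n + (n_min - large_n) * min_prop`` otherwise, and (b) its total
    count is at least ``min_total_count``.  Comparisons carry a 1e-14 slack
    against floating-point ties, matching the reference semantics.

    ``gene_whitelist`` optionally restricts the universe first (e.g. a
    protein-coding gene list used in place of annotation parsing).
    """
    if counts.scale != "counts":
        raise ValueError(f"filter_low_counts needs a counts-scale matrix, got {counts.scale!r}")
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if counts.n_genes == 0:
        raise ValueError("empty matrix")

    mat = counts
    if gene_whitelist is not None:
        mat = mat.subset_genes(gene_whitelist)
        if mat.n_genes == 0:
            raise ValueError("gene whitelist removed every gene")

    lib = mat.values.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero total count")
    if groups is None:
        n_min = mat.n_samples
    else:
        if len(groups) != mat.n_samples:
            raise ValueError("groups length must equal sample count")
        n_min = int(pd.Series(list(groups)).value_counts().min())
    if n_min > params.large_n:
        n_min = params.large_n + (n_min - params.large_n) * params.min_prop
    cpm_cutoff = params.min_count / np.median(lib) * 1e6

    cpm = mat.values / lib * 1e6
    keep_cpm = (cpm >= cpm_cutoff - _TOL).sum(axis=1) >= n_min - _TOL
    keep_total = mat.values.sum(axis=1) >= params.min_total_count - _TOL
    keep = keep_cpm & keep_total
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("low-count filter removed every gene (retained 0)")
    log.info("filter_low_counts: retained %d of %d genes", n_kept, mat.n_genes)
    return ExpressionMatrix(
        [g for g, k in zip(mat.gene_ids, keep) if k],
        list(mat.sample_ids),
        mat.values[keep, :],
        "counts",
    )


_AMBIGUOUS = {"", "NA", "NAN", "NONE", "<NA>"}


def collapse_duplicate_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows that map to the same (uppercased) symbol.

    Rows with empty or ambiguous symbols ("NA" and friends) are dropped and
    the drop count logged.  First-appearance row order is preserved.
    """
    symbols = [g.strip().upper() for g in matrix.gene_ids]
    named = [s not in _AMBIGUOUS for s in symbols]
    n_dropped = len(symbols) - sum(named)
    if n_dropped:
        log.info("collapse_duplicate_genes: dropped %d unnamed/ambiguous rows", n_dropped)
    df = pd.DataFrame(matrix.values[np.asarray(named, bool), :])
    df.insert(0, "_gene", [s for s, n in zip(symbols, named) if n])
    collapsed = df.groupby("_gene", sort=False).mean()
    return ExpressionMatrix(
        list(collapsed.index), list(matrix.sample_ids), collapsed.to_numpy(), matrix.scale
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the per-rank mean empirical distribution.

    The reference distribution is the across-sample mean of sorted columns;
    tied values within a column receive the mean of the reference values at
    their tied ranks.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = matrix.values
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = np.empty_like(ref)
        i = 0
        n = len(col)
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            assigned[i : k + 1] = ref[i : k + 1].mean()  # ties share the rank-mean
            i = k + 1
        out[order, j] = assigned
    return matrix.with_values(out, "quantile_normalized")


def tmm_factors(counts: ExpressionMatrix, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the column whose 75th count-fraction percentile
    is closest to the mean across samples.  Each factor is 2^(weighted
    trimmed mean of M-values) with 30% trim on M, 5% trim on A, and inverse
    asymptotic-variance weights; factors are rescaled to geometric mean 1.
    """
    if counts.scale != "counts":
        raise ValueError("tmm_factors needs a counts-scale matrix")
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = counts.values
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero total count")

    q75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    f = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        f[j] = _tmm_pair(X[:, j], X[:, ref_idx], lib[j], lib[ref_idx],
                         logratio_trim, sum_trim)
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(pd.Series(f, index=list(counts.sample_ids)))


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, sum_trim):
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks are 1-based, ties broken by average rank as in the reference
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    w = 1.0 / v[keep]
    val = 2 ** (np.sum(w * m[keep]) / np.sum(w))
    if not np.isfinite(val) or val <= 0:
        return 1.0
    return val


def logcpm(
    counts: ExpressionMatrix,
    factors: Optional[NormFactors] = None,
    prior: float = 0.5,
) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count against zeros.

    ``value = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)``.
    """
    if counts.scale != "counts":
        raise ValueError("logcpm needs a counts-scale matrix")
    if prior < 0:
        raise ValueError("prior must be non-negative")
    lib = counts.values.sum(axis=0)
    f = factors.align(counts.sample_ids) if factors is not None else np.ones(counts.n_samples)
    eff = lib * f + 2.0 * prior
    vals = np.log2((counts.values + prior) / eff * 1e6)
    return counts.with_values(vals, "logcpm")
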