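"""Seeded consensus Iterative Signature Algorithm (ISA) bi-clustering.

ISA alternates between scoring samples over a current gene set and scoring
genes over the current sample set on standardized expression, thresholding
z-scores at each step until a self-consistent gene-set/sample-set pair (a
transcription module) is reached.  Because the outcome depends on the
seeds, the full seeded algorithm is repeated ``n_runs`` times from
Ward-partition-derived random seeds, converged modules are matched across
runs by gene-set Jaccard similarity, and only modules recurring in strictly
more than ``consensus_frac`` of the runs are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cluster import ward_clusters
from .types import Bicluster, warn

log = logging.getLogger(__name__)

__all__ = [
    "IsaParams",
    "isa_normalize",
    "isa_iterate",
    "make_seeds",
    "isa_consensus",
    "consensus_from_instances",
]


@dataclass(frozen=True)
class IsaParams:
    """Operating parameters for seeded consensus ISA.

    ``t_gene`` and ``t_sample`` are z-score thresholds; ``direction``
    "signed" keeps |z| exceedances (up- and down-coherent members) while
    "up" keeps positive exceedances only.  A module must recur in strictly
    more than ``consensus_frac`` of the ``n_runs`` repetitions (>75% of 25
    means at least 19) to be reported.
    """

    t_gene: float = 2.0
    t_sample: float = 1.5
    direction: str = "signed"
    max_iter: int = 50
    n_runs: int = 25
    consensus_frac: float = 0.75
    match_jaccard: float = 0.66
    seeds_per_cluster: int = 3
    n_gene_clusters: int = 10
    n_sample_clusters: int = 7
    rng_seed: Optional[int] = None

    def __post_init__(self):
        if self.t_gene <= 0 or self.t_sample <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.consensus_frac < 1.0):
            raise ValueError("consensus_frac must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.direction not in ("up", "signed"):
            raise ValueError("direction must be 'up' or 'signed'")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def isa_normalize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row- and column-standardized copies of a matrix.

    ``row_std`` gives each gene mean 0 / SD 1 across samples; ``col_std``
    gives each sample mean 0 / SD 1 across genes.  Constant rows or columns
    cannot be standardized: they are zeroed with a warning (callers that
    need them gone should drop them first; see ``nonconstant_mask``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and columns")
    row_const = X.std(axis=1) == 0
    col_const = X.std(axis=0) == 0
    if (~row_const).sum() < 2:
        raise ValueError("fewer than 2 non-constant rows")
    if row_const.any():
        warn(f"{int(row_const.sum())} constant rows zeroed during standardization")
    if col_const.any():
        warn(f"{int(col_const.sum())} constant columns zeroed during standardization")

    mu_r = X.mean(axis=1, keepdims=True)
    sd_r = X.std(axis=1, keepdims=True)
    sd_r[sd_r == 0] = np.inf
    row_std = (X - mu_r) / sd_r
    mu_c = X.mean(axis=0, keepdims=True)
    sd_c = X.std(axis=0, keepdims=True)
    sd_c[sd_c == 0] = np.inf
    col_std = (X - mu_c) / sd_c
    return row_std, col_std


def nonconstant_mask(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean masks of non-constant rows and columns."""
    X = np.asarray(X, dtype=float)
    return X.std(axis=1) > 0, X.std(axis=0) > 0


def _threshold(z: np.ndarray, t: float, direction: str) -> np.ndarray:
    if direction == "up":
        return z > t
    return np.abs(z) > t


def _iterate_sets(
    row_std: np.ndarray,
    col_std: np.ndarray,
    gene_set: Optional[np.ndarray],
    sample_set: Optional[np.ndarray],
    params: IsaParams,
):
    """Alternating threshold updates; returns (genes, samples, gz, sz, converged) or None."""
    n_genes, n_samples = row_std.shape
    if gene_set is None:
        # start from a sample seed: first derive gene scores
        sv = _zscore(row_std[:, sample_set].mean(axis=1))
        gene_set = _threshold(sv, params.t_gene, params.direction)
        if not gene_set.any():
            return None
    gz = np.zeros(n_genes)
    sz = np.zeros(n_samples)
    prev2_g = prev2_s = None
    for _ in range(params.max_iter):
        prev_g, prev_s = gene_set, sample_set
        sz = _zscore(col_std[gene_set, :].mean(axis=0))
        sample_set = _threshold(sz, params.t_sample, params.direction)
        if not sample_set.any():
            return None
        gz = _zscore(row_std[:, sample_set].mean(axis=1))
        gene_set = _threshold(gz, params.t_gene, params.direction)
        if not gene_set.any():
            return None
        if (
            prev_s is not None
            and np.array_equal(gene_set, prev_g)
            and np.array_equal(sample_set, prev_s)
        ):
            return gene_set, sample_set, gz, sz, True
        if (
            prev2_s is not None
            and np.array_equal(gene_set, prev2_g)
            and np.array_equal(sample_set, prev2_s)
        ):
            # period-2 limit cycle: converge on the stable core shared by
            # the two alternating states
            core_g = gene_set & prev_g
            core_s = sample_set & prev_s
            if not core_g.any() or not core_s.any():
                return None
            sz = _zscore(col_std[core_g, :].mean(axis=0))
            gz = _zscore(row_std[:, core_s].mean(axis=1))
            return core_g, core_s, gz, sz, True
        prev2_g, prev2_s = prev_g, prev_s
    return gene_set, sample_set, gz, sz, False


def isa_iterate(
    row_std: np.ndarray,
    col_std: np.ndarray,
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
    gene_seed: Optional[Sequence[int]] = None,
    sample_seed: Optional[Sequence[int]] = None,
    params: IsaParams = IsaParams(),
) -> Optional[Bicluster]:
    """Run ISA from a single gene- or sample-index seed.

    Returns the fixed-point bi-cluster, a non-converged bi-cluster flagged
    ``converged=False`` when ``max_iter`` is exhausted, or None when a
    threshold step empties either set.
    """
    if (gene_seed is None) == (sample_seed is None):
        raise ValueError("provide exactly one of gene_seed or sample_seed")
    n_genes, n_samples = row_std.shape
    gene_set = sample_set = None
    if gene_seed is not None:
        if len(gene_seed) == 0:
            raise ValueError("empty seed")
        gene_set = np.zeros(n_genes, dtype=bool)
        gene_set[np.asarray(gene_seed, dtype=int)] = True
    else:
        if len(sample_seed) == 0:
            raise ValueError("empty seed")
        sample_set = np.zeros(n_samples, dtype=bool)
        sample_set[np.asarray(sample_seed, dtype=int)] = True

    out = _iterate_sets(row_std, col_std, gene_set, sample_set, params)
    if out is None:
        return None
    genes, samples, gz, sz, converged = out
    return Bicluster(
        gene_set=frozenset(np.asarray(gene_ids)[genes]),
        sample_set=frozenset(np.asarray(sample_ids)[samples]),
        gene_scores={g: float(z) for g, z in zip(np.asarray(gene_ids)[genes], gz[genes])},
        sample_scores={s: float(z) for s, z in zip(np.asarray(sample_ids)[samples], sz[samples])},
        support=1.0,
        converged=converged,
    )


def make_seeds(
    gene_partition: Sequence[int],
    sample_partition: Sequence[int],
    seeds_per_cluster: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[str, np.ndarray]]:
    """Random member seeds from Ward partitions.

    For every sample cluster, one seed of ``seeds_per_cluster`` uniformly
    drawn members (all members when the cluster is smaller, with a
    warning); likewise for every gene cluster.  Returns ``("gene"|"sample",
    index_array)`` pairs, gene seeds first.
    """
    rng = rng or np.random.default_rng()
    gene_partition = np.asarray(gene_partition)
    sample_partition = np.asarray(sample_partition)
    if gene_partition.size == 0 or sample_partition.size == 0:
        raise ValueError("empty partition")
    seeds: List[Tuple[str, np.ndarray]] = []
    for kind, part in (("gene", gene_partition), ("sample", sample_partition)):
        for c in np.unique(part):
            members = np.flatnonzero(part == c)
            if members.size < seeds_per_cluster:
                warn(f"{kind} cluster {c} has only {members.size} members; using all")
                chosen = members
            else:
                chosen = rng.choice(members, size=seeds_per_cluster, replace=False)
            seeds.append((kind, np.sort(chosen)))
    return seeds


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def consensus_from_instances(
    instances: Sequence[Tuple[int, frozenset, frozenset]],
    n_runs: int,
    params: IsaParams = IsaParams(),
) -> List[Bicluster]:
    """Greedy largest-first matching of per-run bi-clusters into consensus sets.

    ``instances`` are ``(run_id, gene_set, sample_set)`` triples from
    converged runs.  A match group is emitted iff the distinct runs it
    spans strictly exceed ``consensus_frac * n_runs``; consensus membership
    is items present in at least half of the matched instances.  Output is
    sorted by gene-set size descending.
    """

    def sort_key(inst):
        return (-len(inst[1]), tuple(sorted(inst[1])), inst[0])

    remaining = sorted(instances, key=sort_key)
    consensus = []
    while remaining:
        exemplar = remaining[0]
        group = [inst for inst in remaining if _jaccard(exemplar[1], inst[1]) >= params.match_jaccard]
        remaining = [inst for inst in remaining if inst not in group]
        runs_spanned = len({run for run, _, _ in group})
        if runs_spanned <= params.consensus_frac * n_runs:
            continue
        gene_counts: dict = {}
        sample_counts: dict = {}
        for _, gs, ss in group:
            for g in gs:
                gene_counts[g] = gene_counts.get(g, 0) + 1
            for s in ss:
                sample_counts[s] = sample_counts.get(s, 0) + 1
        half = len(group) / 2.0
        genes = frozenset(g for g, c in gene_counts.items() if c >= half)
        samples = frozenset(s for s, c in sample_counts.items() if c >= half)
        if not genes or not samples:
            continue
        consensus.append(
            Bicluster(
                gene_set=genes,
                sample_set=samples,
                support=runs_spanned / n_runs,
            )
        )
    consensus.sort(key=lambda b: (-len(b.gene_set), tuple(sorted(b.gene_set))))
    return consensus


def isa_consensus(
    X: np.ndarray,
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
    params: IsaParams = IsaParams(),
) -> List[Bicluster]:
    """Full seeded consensus ISA on an expression matrix (genes x samples).

    Constant rows/columns are dropped first.  Ward partitions of the
    standardized matrix (``n_gene_clusters`` x ``n_sample_clusters``) are
    computed once; each of the ``n_runs`` repetitions draws fresh random
    seeds from those partitions via an independent RNG stream derived from
    ``params.rng_seed``, runs ISA from every seed, and contributes its
    converged modules to the cross-run match.
    """
    X = np.asarray(X, dtype=float)
    gene_ids = np.asarray([str(g) for g in gene_ids])
    sample_ids = np.asarray([str(s) for s in sample_ids])
    row_ok, col_ok = nonconstant_mask(X)
    if row_ok.sum() < 2 or col_ok.sum() < 2:
        raise ValueError("fewer than 2 non-constant rows or columns")
    if (~row_ok).any() or (~col_ok).any():
        warn(
            f"dropping {int((~row_ok).sum())} constant genes and "
            f"{int((~col_ok).sum())} constant samples before ISA"
        )
    Xs = X[np.ix_(row_ok, col_ok)]
    gids = gene_ids[row_ok]
    sids = sample_ids[col_ok]

    row_std, col_std = isa_normalize(Xs)
    n_gc = min(params.n_gene_clusters, row_std.shape[0])
    n_sc = min(params.n_sample_clusters, row_std.shape[1])
    gene_part, sample_part = ward_clusters(row_std, n_gc, n_sc)

    streams = np.random.SeedSequence(params.rng_seed).spawn(params.n_runs)
    instances = []
    for run_id, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        seen_in_run = set()
        for kind, idx in make_seeds(gene_part, sample_part, params.seeds_per_cluster, rng):
            bc = isa_iterate(
                row_std,
                col_std,
                gids,
                sids,
                gene_seed=idx if kind == "gene" else None,
                sample_seed=idx if kind == "sample" else None,
                params=params,
            )
            if bc is None or not bc.converged:
                continue
            key = (bc.gene_set, bc.sample_set)
            if key in seen_in_run:
                continue
            seen_in_run.add(key)
            instances.append((run_id, bc.gene_set, bc.sample_set))
    result = consensus_from_instances(instances, params.n_runs, params)
    log.info(
        "isa_consensus: %d converged instances over %d runs -> %d consensus bi-clusters",
        len(instances),
        params.n_runs,
        len(result),
    )
    return result
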