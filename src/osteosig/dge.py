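"""Precision-weighted differential expression with empirical-Bayes moderation.

The voom idea: model log2-CPM per gene, estimate the mean-variance trend of
sqrt residual standard deviations by lowess, and convert predicted SDs into
inverse-variance^2 observation weights.  Gene-wise weighted least squares
then yields moderated t-statistics by shrinking residual variances toward a
prior estimated by moment-matching of log-variances (digamma/trigamma),
with Benjamini-Hochberg control across genes.  This mirrors the canonical
published estimator; no installed Python package provides it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .preprocess import NormFactors, logcpm as _logcpm
from .types import ExpressionMatrix, GeneSignature, warn

log = logging.getLogger(__name__)

__all__ = [
    "DegThresholds",
    "voom_transform",
    "fit_moderated",
    "select_degs",
    "bh_adjust",
]


@dataclass(frozen=True)
class DegThresholds:
    """DEG selection cutoffs: linear fold change and BH-adjusted p, both strict."""

    fc_min: float = 3.0
    fdr_max: float = 0.05

    def __post_init__(self):
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1 (linear scale)")
        if not (0.0 < self.fdr_max < 1.0):
            raise ValueError("fdr_max must lie in (0, 1)")


def _two_groups(labels: Sequence) -> Tuple[np.ndarray, list]:
    """Split two-group labels; the contrast is lexicographically-first label
    minus the second, so swapping group labels negates every log2FC."""
    labels = [str(x) for x in labels]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    in_a = np.array([lab == uniq[0] for lab in labels])
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    return in_a, uniq


def voom_transform(
    counts: ExpressionMatrix,
    factors: Optional[NormFactors],
    labels: Sequence,
    span: float = 0.5,
    prior: float = 0.5,
) -> Tuple[ExpressionMatrix, np.ndarray]:
    """log2-CPM plus per-observation precision weights.

    Gene-wise sqrt residual SDs from an ordinary two-group fit are
    regressed on average log2-CPM by lowess (span 0.5); the predicted
    sqrt-SD at each observation's fitted value gives weight
    ``predicted**-4``, clipped to [1e-6, 1e6].
    """
    if counts.n_genes < 10:
        raise ValueError("need >= 10 genes to estimate the mean-variance trend")
    in_a, _ = _two_groups(labels)
    lcpm = _logcpm(counts, factors, prior=prior)
    Y = lcpm.values
    n = Y.shape[1]
    mean_a = Y[:, in_a].mean(axis=1)
    mean_b = Y[:, ~in_a].mean(axis=1)
    fitted = np.where(in_a[None, :], mean_a[:, None], mean_b[:, None])
    resid = Y - fitted
    s2 = (resid**2).sum(axis=1) / (n - 2)
    sqrt_sd = np.sqrt(np.sqrt(s2))
    if np.all(s2 == 0):
        warn("all residual SDs are zero; weights hit the clip ceiling")
        return lcpm, np.full_like(Y, 1e6)

    ave = Y.mean(axis=1)
    trend = sm_lowess(sqrt_sd, ave, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # constant extrapolation beyond the fitted range
    pred = np.interp(fitted, tx, ty)
    pred = np.maximum(pred, 0.0)
    with np.errstate(divide="ignore"):
        weights = pred**-4.0
    weights = np.clip(weights, 1e-6, 1e6)
    return lcpm, weights


def _trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y by the standard Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < tol:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment-match log variances to a scaled F distribution: (d0, s0^2)."""
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    if not np.isfinite(s0_sq) or s0_sq <= 0:
        warn("prior variance estimate degenerate; falling back to pooled variance")
        d0, s0_sq = np.inf, float(s2.mean())
    return d0, s0_sq


def fit_moderated(
    lcpm: ExpressionMatrix,
    weights: np.ndarray,
    labels: Sequence,
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Gene-wise weighted least squares with moderated t-statistics.

    The contrast is first-seen group minus second group, so a label swap
    negates every log2FC.  ``prior_df`` overrides the estimated prior
    degrees of freedom d0 (0 recovers the ordinary weighted t; ``inf``
    pools variances).  Returns a DataFrame indexed by gene with columns
    ``log2fc``, ``ave_logcpm``, ``t``, ``p``, ``adj_p``; the fitted prior
    is stored in ``.attrs``.
    """
    in_a, uniq = _two_groups(labels)
    Y = lcpm.values
    W = np.asarray(weights, dtype=float)
    if W.shape != Y.shape:
        raise ValueError("weights shape must match the expression matrix")
    n = Y.shape[1]
    df_resid = n - 2

    sw_a = W[:, in_a].sum(axis=1)
    sw_b = W[:, ~in_a].sum(axis=1)
    mean_a = (W[:, in_a] * Y[:, in_a]).sum(axis=1) / sw_a
    mean_b = (W[:, ~in_a] * Y[:, ~in_a]).sum(axis=1) / sw_b
    beta = mean_a - mean_b
    fitted = np.where(in_a[None, :], mean_a[:, None], mean_b[:, None])
    s2 = (W * (Y - fitted) ** 2).sum(axis=1) / df_resid
    se_unit = np.sqrt(1.0 / sw_a + 1.0 / sw_b)

    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(s2.mean())
    elif np.isinf(prior_df):
        d0, s0_sq = np.inf, float(s2.mean())
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2, df_resid)

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_mod = s2
        df_total = df_resid
    else:
        s2_mod = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = beta / (np.sqrt(s2_mod) * se_unit)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)

    table = pd.DataFrame(
        {
            "log2fc": beta,
            "ave_logcpm": Y.mean(axis=1),
            "t": t_stat,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=pd.Index(lcpm.gene_ids, name="gene"),
    )
    table.attrs["d0"] = d0
    table.attrs["s0_sq"] = s0_sq
    table.attrs["contrast"] = f"{uniq[0]} - {uniq[1]}"
    return table


def select_degs(table: pd.DataFrame, th: DegThresholds = DegThresholds(),
                name: str = "degs") -> Optional[GeneSignature]:
    """Genes with linear |fold change| > fc_min AND adjusted p < fdr_max (strict).

    Returns None when nothing passes.
    """
    fc_pass = 2.0 ** np.abs(table["log2fc"].to_numpy()) > th.fc_min
    p_pass = table["adj_p"].to_numpy() < th.fdr_max
    genes = table.index[fc_pass & p_pass]
    if len(genes) == 0:
        return None
    return GeneSignature(name, frozenset(genes))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
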