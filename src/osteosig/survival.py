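"""Survival estimation and the hypothesis tests used across the pipeline.

Product-limit estimation, the two-group log-rank test and univariate Cox
regression are delegated to lifelines; the chi-square goodness-of-fit and
Mann-Whitney U tests use scipy.  Median survival follows the convention
"smallest time with S(t) <= 0.5" and is undefined (None) when the curve
never reaches 0.5.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .types import KMCurve, TestResult

log = logging.getLogger(__name__)

__all__ = ["km_estimate", "logrank_test", "cox_univariate", "chisq_gof", "mannwhitney_u"]


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored subjects leave the risk set after their time; at tied times
    events are processed before censorings (the standard convention).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one subject")
    if np.any(time < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    median = float(times[below[0]]) if below.size else None
    return KMCurve(times=times, survival=surv, at_risk=at_risk, median=median)


def logrank_test(
    time: Sequence[float], event: Sequence[int], groups: Sequence
) -> TestResult:
    """Standard two-group log-rank test (chi-square with 1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray([str(g) for g in groups])
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {uniq}")
    if event.sum() == 0:
        raise ValueError("no events in either group")
    a = groups == uniq[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return TestResult(
        name="logrank_chi2",
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=1,
    )


def cox_univariate(
    time: Sequence[float],
    event: Sequence[int],
    covariate: Sequence[float],
) -> TestResult:
    """Univariate Cox proportional-hazards fit (Breslow tie handling).

    Returns the Wald test with the hazard ratio as effect; ``extras`` holds
    ``beta``, ``se`` and a ``converged`` flag (False under monotone
    likelihood / perfect separation).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    covariate = np.asarray(covariate, dtype=float)
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant")
    if event.sum() < 5:
        raise ValueError("need at least 5 events for a stable fit")
    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        return TestResult(
            name="cox_wald", statistic=0.0, p=1.0, df=1, effect=None,
            extras={"converged": False, "diagnostic": str(exc)},
        )
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        name="cox_wald",
        statistic=float(z**2),
        p=float(p),
        df=1,
        effect=float(np.exp(beta)),
        extras={"beta": beta, "se": se, "converged": True},
    )


def chisq_gof(observed: Sequence[float], expected: Sequence[float]) -> TestResult:
    """Pearson chi-square goodness of fit with k-1 degrees of freedom."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.size < 2:
        raise ValueError("observed and expected must share a length >= 2")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    k = observed.size
    p = float(stats.chi2.sf(stat, k - 1))
    return TestResult(name="pearson_chi2", statistic=stat, p=p, df=k - 1)


def mannwhitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U with mid-rank ties.

    Exact enumeration for small untied samples, normal approximation with
    tie correction otherwise (scipy's automatic method selection).  The
    effect estimate is the rank-biserial correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    u = float(res.statistic)
    rank_biserial = 2.0 * u / (x.size * y.size) - 1.0
    return TestResult(
        name="mannwhitney_U",
        statistic=u,
        p=float(min(res.pvalue, 1.0)),
        effect=float(rank_biserial),
    )
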