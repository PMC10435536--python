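"""Core data containers for expression matrices, gene sets, clinical tables and results.

Gene identity throughout the package is by uppercase gene symbol: prognostic
signatures are transferred between cohorts (and species) by shared symbols,
so all containers harmonize symbols to uppercase at construction or at the
point of comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "GeneSetCollection",
    "ClinicalTable",
    "EnrichmentProfile",
    "ClusteringResult",
    "Bicluster",
    "KMCurve",
    "TestResult",
    "ENDPOINTS",
    "SCALES",
]

SCALES = ("counts", "tpm", "logcpm", "quantile_normalized")
ENDPOINTS = ("DFI", "OSv", "PFS")


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with a scale tag.

    Parameters
    ----------
    gene_ids
        Gene symbols, one per row.  Duplicates are permitted (collapsing
        duplicate symbols is an explicit preprocessing step).
    sample_ids
        Unique sample identifiers, one per column.
    values
        Dense float array of shape ``(len(gene_ids), len(sample_ids))``.
    scale
        One of ``counts``, ``tpm``, ``logcpm``, ``quantile_normalized``.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    scale: str

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.scale in ("counts", "tpm") and np.any(self.values < 0):
            raise ValueError(f"negative values not allowed on scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene"), columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset to ``genes`` (order of appearance in the matrix kept)."""
        wanted = {str(g).upper() for g in genes}
        mask = [g.upper() in wanted for g in self.gene_ids]
        return ExpressionMatrix(
            [g for g, m in zip(self.gene_ids, mask) if m],
            list(self.sample_ids),
            self.values[np.asarray(mask, bool), :],
            self.scale,
        )

    def with_values(self, values: np.ndarray, scale: Optional[str] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), values, scale or self.scale
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named set of gene symbols (uppercase-harmonized)."""

    name: str
    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(str(g).upper() for g in self.genes))
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GMT-style)."""

    name: str
    sets: dict

    def __post_init__(self):
        clean = {}
        for set_name, genes in self.sets.items():
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")
            if set_name in clean:
                raise ValueError(f"duplicate gene-set name {set_name!r}")
            clean[str(set_name)] = genes
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class ClinicalTable:
    """Per-sample time-to-event outcomes.

    One row per sample per endpoint; ``time_days >= 0``; ``event`` is 1 for an
    observed event and 0 for right-censoring.  Endpoints follow the field's
    conventions: DFI (disease-free interval), OSv (overall survival), PFS
    (progression-free survival), all in days from diagnosis.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "time_days", "event", "endpoint")

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if "metastatic_at_dx" not in df.columns:
            df["metastatic_at_dx"] = pd.NA
        df["sample_id"] = df["sample_id"].astype(str)
        df["time_days"] = pd.to_numeric(df["time_days"])
        df["event"] = pd.to_numeric(df["event"]).astype(int)
        if df["time_days"].isna().any() or (df["time_days"] < 0).any():
            raise ValueError("time_days must be non-negative and non-missing")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be coded 1=event, 0=censored")
        bad = set(df["endpoint"]) - set(ENDPOINTS)
        if bad:
            raise ValueError(f"unknown endpoints {sorted(bad)}; expected {ENDPOINTS}")
        if df.duplicated(["sample_id", "endpoint"]).any():
            raise ValueError("duplicate (sample_id, endpoint) rows")
        self.data = df.reset_index(drop=True)

    def endpoints(self) -> list:
        return sorted(set(self.data["endpoint"]))

    def for_endpoint(self, endpoint: str) -> pd.DataFrame:
        sub = self.data[self.data["endpoint"] == endpoint]
        if sub.empty:
            raise ValueError(f"no rows for endpoint {endpoint!r}")
        return sub.set_index("sample_id")


@dataclass
class EnrichmentProfile:
    """Per-sample gene-set enrichment scores (samples x sets)."""

    sample_ids: list
    set_names: list
    scores: np.ndarray
    alpha: float
    normalized: bool

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.set_names)):
            raise ValueError("scores shape does not match sample/set labels")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite enrichment scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.set_names)


@dataclass
class ClusteringResult:
    """K-means partition with the silhouette trace used for model selection."""

    labels: pd.Series  # sample_id -> integer cluster (0-based, sized descending)
    k_selected: int
    silhouette_by_k: dict
    feature_space: str
    prognosis_labels: Optional[dict] = None  # cluster -> "FP" | "PP"

    def cluster_samples(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


@dataclass(frozen=True)
class Bicluster:
    """A gene-set / sample-set pair with its threshold z-scores and run support."""

    gene_set: frozenset
    sample_set: frozenset
    gene_scores: Mapping = field(default_factory=dict)
    sample_scores: Mapping = field(default_factory=dict)
    support: float = 1.0
    converged: bool = True

    def __post_init__(self):
        if not self.gene_set or not self.sample_set:
            raise ValueError("bicluster gene and sample sets must be non-empty")
        if not (0.0 < self.support <= 1.0):
            raise ValueError("support must lie in (0, 1]")


@dataclass
class KMCurve:
    """Product-limit survival curve: step times, S(t), and at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: Optional[float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")
        if self.survival.size and (self.survival.max() > 1 + 1e-12 or self.survival.min() < -1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass
class TestResult:
    """A named test statistic with its p-value and optional effect size."""

    name: str
    statistic: float
    p: float
    df: Optional[float] = None
    effect: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value out of [0, 1]")


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=2)
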