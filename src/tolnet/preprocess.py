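"""Reporter-intensity preprocessing: complete-case filter, reference ratios,
quantile normalization, and advisory outlier flagging.

The protein layer arrives as nonnegative reporter intensities p_{j,s} with a
pooled reference-channel intensity r_j per protein.  Proteins with any missing
value are removed (complete-case analysis), each value is expressed relative
to the reference as (1 + p_{j,s}) / (1 + r_j), and sample columns are quantile
normalized to a common distribution.  Outlying samples are flagged by low
median correlation to the other samples but never dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinIntensityTable",
    "RatioTable",
    "filter_complete",
    "compute_ratios",
    "quantile_normalize",
    "QuantileNormalizer",
    "flag_outlier_samples",
    "preprocess_proteins",
]


@dataclass
class ProteinIntensityTable:
    """Proteins x samples reporter intensities plus the reference channel."""

    intensities: pd.DataFrame  # NaN = missing
    reference: pd.Series  # r_j, indexed like intensities

    def __post_init__(self):
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.reference.index.equals(self.intensities.index):
            self.reference = self.reference.reindex(self.intensities.index)
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or (self.reference.to_numpy(dtype=float) < 0).any():
            raise ValueError("reporter intensities must be nonnegative")

    @classmethod
    def from_raw(cls, raw: pd.DataFrame, ref_column: str = "REF") -> "ProteinIntensityTable":
        if ref_column not in raw.columns:
            raise ValueError(f"reference column {ref_column!r} not found")
        return cls(intensities=raw.drop(columns=[ref_column]), reference=raw[ref_column])


@dataclass
class RatioTable:
    """Strictly positive reference ratios with filtering provenance."""

    ratios: pd.DataFrame
    n_filtered: int = 0
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        vals = self.ratios.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("ratio table must be complete")
        if (vals <= 0).any():
            raise ValueError("ratios must be strictly positive")


def filter_complete(table: ProteinIntensityTable) -> ProteinIntensityTable:
    """Keep only proteins observed in every sample.

    Raises if nothing survives, reporting the counts in the message.
    """
    if table.intensities.empty:
        raise ValueError("empty intensity table")
    keep = table.intensities.notna().all(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"no protein is complete across all {table.intensities.shape[1]} samples "
            f"({n_removed} removed)"
        )
    logger.info("complete-case filter: kept %d proteins, removed %d", int(keep.sum()), n_removed)
    out = ProteinIntensityTable(table.intensities.loc[keep], table.reference.loc[keep])
    out.n_removed = n_removed  # type: ignore[attr-defined]
    return out


def compute_ratios(table: ProteinIntensityTable) -> RatioTable:
    """ratio[j, s] = (1 + p_{j,s}) / (1 + r_j)."""
    p = table.intensities.to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("compute_ratios requires a complete-case table")
    r = table.reference.to_numpy(dtype=float)
    ratios = (1.0 + p) / (1.0 + r[:, None])
    return RatioTable(
        ratios=pd.DataFrame(ratios, index=table.intensities.index, columns=table.intensities.columns),
        n_filtered=getattr(table, "n_removed", 0),
    )


def quantile_normalize(ratios: RatioTable) -> RatioTable:
    """Rank-mean quantile normalization.

    After normalization every sample column carries the identical multiset of
    values — the per-rank mean of the sorted columns — while the (non-strict)
    rank order within each column is preserved.  Ties are broken by original
    row order, which keeps the output multisets exactly identical across
    columns.  Idempotent; a single-sample table is returned unchanged with a
    warning.
    """
    df = ratios.ratios
    if df.shape[1] < 2:
        logger.warning("quantile normalization skipped: single sample")
        return RatioTable(df.copy(), ratios.n_filtered, list(ratios.flagged_samples))
    x = df.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for k in range(x.shape[1]):
        out[order[:, k], k] = ref
    return RatioTable(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        ratios.n_filtered,
        list(ratios.flagged_samples),
    )


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization as a scikit-learn transformer.

    ``fit`` learns the per-rank reference distribution from the training
    columns (samples as columns, features as rows when ``axis=0``); ``transform``
    maps each column's ranks onto it.  With default usage on the same matrix
    this reproduces :func:`quantile_normalize`.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.reference_.size:
            raise ValueError("feature count differs from the fitted reference")
        out = np.empty_like(X)
        for k in range(X.shape[1]):
            order = np.argsort(X[:, k], kind="stable")
            out[order, k] = self.reference_
        return out


def flag_outlier_samples(ratios: RatioTable, min_median_correlation: float = 0.0) -> list[str]:
    """Samples whose median Pearson correlation to the others is low.

    Advisory only — callers decide whether to drop flagged samples.  Requires
    at least three samples; an empty list is a valid outcome.
    """
    df = ratios.ratios
    if df.shape[1] < 3:
        raise ValueError("outlier flagging needs at least 3 samples")
    corr = np.corrcoef(df.to_numpy(dtype=float).T)
    np.fill_diagonal(corr, np.nan)
    med = np.nanmedian(corr, axis=1)
    flagged = [s for s, m in zip(df.columns, med) if m < min_median_correlation]
    if flagged:
        logger.warning("flagged %d low-correlation samples: %s", len(flagged), flagged)
    return flagged


def preprocess_proteins(
    raw: pd.DataFrame,
    ref_column: str = "REF",
    min_median_correlation: float = -1.0,
    drop_flagged: bool = False,
    log2_output: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full protein preprocessing: filter -> ratio -> quantile normalize -> flag.

    Returns the normalized matrix (log2 ratios by default) and a report dict
    with the counts at each step.
    """
    table = ProteinIntensityTable.from_raw(raw, ref_column)
    complete = filter_complete(table)
    ratios = quantile_normalize(compute_ratios(complete))
    flagged = flag_outlier_samples(ratios, min_median_correlation)
    out = ratios.ratios
    if drop_flagged and flagged:
        out = out.drop(columns=flagged)
    if log2_output:
        out = np.log2(out)
    report = {
        "n_proteins_in": int(table.intensities.shape[0]),
        "n_proteins_complete": int(complete.intensities.shape[0]),
        "n_proteins_removed": getattr(complete, "n_removed", 0),
        "flagged_samples": flagged,
        "dropped_samples": flagged if drop_flagged else [],
        "scale": "log2_ratio" if log2_output else "ratio",
    }
    return out, report
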