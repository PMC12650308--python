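"""Temporal preprocessing: intensity filter, TIC normalization, LOESS
injection-order correction, gap filling, and per-feature standardization.

All steps take and return :class:`~strokemap.containers.FeatureTable` (copies;
inputs are never mutated) and append themselves to ``transform_log``.
Intensities are treated as multiplicative signals: the TIC and drift
corrections are divisive, and gap filling uses the half-minimum
limit-of-detection convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import FeatureTable


@dataclass
class ProcessedMatrix:
    """Standardized feature x sample matrix ready for shape clustering."""

    values: pd.DataFrame
    transform_log: list = field(default_factory=list)
    excluded_constant: list = field(default_factory=list)


def filter_intensity(table: FeatureTable, threshold: float = 500.0) -> FeatureTable:
    """Keep features whose maximum observed intensity strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = table.copy()
    maxima = out.intensities.max(axis=1, skipna=True)
    keep = maxima > threshold
    if not keep.any():
        raise ValueError(
            f"every feature falls at or below the {threshold}-count threshold; "
            "the filtered table would be empty"
        )
    out.intensities = out.intensities.loc[keep]
    out.feature_meta = out.feature_meta.loc[keep]
    out.log_step("filter_intensity", threshold=threshold,
                 retained=int(keep.sum()), dropped=int((~keep).sum()))
    return out


def tic_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so its total signal equals the median raw total."""
    out = table.copy()
    totals = out.intensities.sum(axis=0, skipna=True)
    zero = totals <= 0
    if zero.any():
        raise ValueError(
            f"sample(s) with non-positive total signal: {list(totals.index[zero])}"
        )
    target = float(np.median(totals))
    out.intensities = out.intensities * (target / totals)
    out.log_step("tic_normalize", target=target)
    return out


def loess_batch_correct(
    table: FeatureTable, injection_order=None, span: float = 0.75
) -> FeatureTable:
    """Divide each feature by its LOESS trend over injection order.

    The trend is fitted per feature on observed values against the injection
    order of all samples pooled, then rescaled to mean one so the correction
    is purely divisive and preserves each feature's average level.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    out = table.copy()
    if injection_order is None:
        injection_order = out.sample_meta["injection_order"]
    order = np.asarray(injection_order, dtype=float)
    if sorted(order.astype(int)) != list(range(len(order))):
        raise ValueError("injection_order must be a permutation of sample indices")
    if span * len(order) < 3:
        raise ValueError(
            f"span {span} covers fewer than 3 of {len(order)} samples; "
            "use a larger span"
        )

    values = out.intensities.to_numpy(dtype=float)
    corrected = values.copy()
    for i in range(values.shape[0]):
        row = values[i]
        obs = np.isfinite(row)
        if obs.sum() < 3:
            continue  # too sparse to fit a trend; left unchanged
        trend = lowess(row[obs], order[obs], frac=span, return_sorted=False)
        trend = np.maximum(trend, 1e-12 * np.nanmean(row[obs]))
        corrected[i, obs] = row[obs] * (trend.mean() / trend)
    out.intensities = pd.DataFrame(
        corrected, index=out.intensities.index, columns=out.intensities.columns
    )
    out.log_step("loess_batch_correct", span=span)
    return out


def gap_fill(table: FeatureTable) -> FeatureTable:
    """Replace missing values with half the feature's minimum observed value.

    Features with no observed value at all cannot be filled; they are dropped
    with a warning and recorded in the transform log.
    """
    out = table.copy()
    values = out.intensities
    n_obs = values.notna().sum(axis=1)
    dead = n_obs == 0
    if dead.any():
        dropped = list(values.index[dead])
        warnings.warn(f"dropping {len(dropped)} feature(s) with no observed values")
        values = values.loc[~dead]
        out.feature_meta = out.feature_meta.loc[~dead]
    else:
        dropped = []
    fill = 0.5 * values.min(axis=1, skipna=True)
    n_filled = int(values.isna().to_numpy().sum())
    out.intensities = values.T.fillna(fill).T
    out.log_step("gap_fill", filled=n_filled, dropped_all_missing=dropped)
    return out


def standardize(table: FeatureTable) -> ProcessedMatrix:
    """Z-score each feature trajectory; constant features are excluded.

    Clustering operates on trajectory *shape*: without standardization a
    Euclidean metric would group features by abundance instead.
    """
    values = table.intensities.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("standardize requires a gap-filled table (no missing values)")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] < 1e-12
    z = (values[~constant] - mean[~constant]) / sd[~constant]
    log = list(table.transform_log)
    log.append({"step": "standardize",
                "excluded_constant": list(table.intensities.index[constant])})
    return ProcessedMatrix(
        values=pd.DataFrame(z, index=table.intensities.index[~constant],
                            columns=table.intensities.columns),
        transform_log=log,
        excluded_constant=list(table.intensities.index[constant]),
    )


def pool_and_standardize(table: FeatureTable) -> ProcessedMatrix:
    """Per-collection subject pooling followed by per-feature z-scoring.

    Averaging the subjects' series collection-by-collection removes
    between-subject scale differences before shape clustering, so the
    cluster space is the consensus trajectory over the collection grid.
    """
    from .phasestats import pool_subjects

    pooled = pool_subjects(table)
    if pooled.isna().to_numpy().any():
        raise ValueError("pooling requires a gap-filled table")
    values = pooled.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] < 1e-12
    z = (values[~constant] - mean[~constant]) / sd[~constant]
    log = list(table.transform_log)
    log.append({"step": "pool_and_standardize",
                "excluded_constant": list(pooled.index[constant])})
    return ProcessedMatrix(
        values=pd.DataFrame(z, index=pooled.index[~constant], columns=pooled.columns),
        transform_log=log,
        excluded_constant=list(pooled.index[constant]),
    )


def run_chain(
    table: FeatureTable,
    intensity_threshold: float = 500.0,
    span: float = 0.75,
) -> tuple[FeatureTable, ProcessedMatrix]:
    """Full chain: filter -> TIC -> LOESS -> gap fill, then standardize.

    Returns the gap-filled intensity table (used for fold-change statistics,
    which need the original scale) and the standardized matrix (used for
    clustering).
    """
    t = filter_intensity(table, intensity_threshold)
    t = tic_normalize(t)
    t = loess_batch_correct(t, span=span)
    t = gap_fill(t)
    return t, standardize(t)
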