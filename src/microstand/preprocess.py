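"""Rarefaction, rare-feature filtering, proportions, and annotation roll-ups."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("microstand")

#: default rare-feature threshold: 0.005% of the grand total
DEFAULT_FILTER_FRACTION = 0.00005


def rarefy(table: pd.DataFrame, depth: int, seed: int, prune: bool = False) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement.

    Each retained column is a multivariate-hypergeometric draw from its
    own reads, so the result sums exactly to ``depth`` and no cell can
    exceed its original count. Samples with fewer than ``depth`` total
    reads are dropped (listed in ``result.attrs["dropped_samples"]`` and
    logged). Features that become all-zero are retained unless ``prune``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    totals = table.sum(axis=0)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [str(s) for s in table.columns[~keep]]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.columns[keep]:
        out[s] = rng.multivariate_hypergeometric(
            table[s].to_numpy(dtype=np.int64), int(depth))
    result = pd.DataFrame(out, index=table.index)
    if prune:
        result = result.loc[result.sum(axis=1) > 0]
    result.attrs["dropped_samples"] = dropped
    result.attrs["rarefaction"] = {"depth": int(depth), "seed": int(seed)}
    return result


def filter_rare_asvs(table: pd.DataFrame,
                     fraction: float = DEFAULT_FILTER_FRACTION) -> pd.DataFrame:
    """Drop features whose grand total is strictly below ``fraction`` of all reads.

    The boundary is inclusive on the keep side: a feature sitting exactly
    at the threshold stays. Removed-feature count is reported in
    ``result.attrs["n_removed"]``.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    grand = table.to_numpy().sum()
    threshold = fraction * grand
    totals = table.sum(axis=1)
    kept = table.loc[totals >= threshold]
    kept.attrs["n_removed"] = int(table.shape[0] - kept.shape[0])
    kept.attrs["filter_threshold_reads"] = float(threshold)
    return kept


def to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise proportions; all-zero samples are flagged, not divided.

    Flagged sample ids live in ``result.attrs["zero_samples"]``.
    """
    sums = table.sum(axis=0).astype(float)
    zero = sums == 0
    safe = sums.where(~zero, 1.0)
    rel = table.astype(float).div(safe, axis=1)
    rel.attrs["zero_samples"] = [str(s) for s in table.columns[zero]]
    if zero.any():
        logger.warning("to_relative: all-zero sample(s) %s left as zeros",
                       rel.attrs["zero_samples"])
    return rel


def aggregate_by_annotation(rel: pd.DataFrame, mapping: pd.Series,
                            unassigned: str = "Unassigned") -> pd.DataFrame:
    """Sum feature proportions into annotation categories.

    Features absent from ``mapping`` are pooled under ``unassigned`` so
    per-sample mass is conserved exactly.
    """
    labels = mapping.reindex(rel.index).fillna(unassigned)
    out = rel.groupby(labels.to_numpy()).sum()
    out.index.name = "annotation"
    return out
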