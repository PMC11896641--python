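"""Alpha diversity (observed richness, Shannon) and Bray-Curtis beta diversity."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("microstand")


def observed_species(counts) -> int:
    """Number of features with a positive count in one sample."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return int((counts > 0).sum())


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over positive proportions.

    Natural log by default (nats); pass ``base`` to change the unit.
    An all-zero sample has no defined entropy and raises ``ValueError``.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("Shannon entropy undefined for an all-zero sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity(table: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Per-sample observed richness and Shannon entropy.

    Returns a frame indexed by sample id with columns
    ``observed_species`` and ``shannon`` (NaN for all-zero samples).
    """
    rows = {}
    for s in table.columns:
        counts = table[s].to_numpy()
        obs = observed_species(counts)
        rows[s] = {
            "observed_species": obs,
            "shannon": shannon(counts, base=base) if obs else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i), on whatever scale the
    table is in (rarefied counts by default in this pipeline). A pair of
    all-zero samples has an undefined dissimilarity; it is recorded as
    NaN with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = table.to_numpy(dtype=float).T
    zero = X.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(X, metric="braycurtis"))
    if zero.any():
        ij = np.ix_(zero, zero)
        dm[ij] = np.nan
        np.fill_diagonal(dm, 0.0)
        logger.warning("bray_curtis: %d all-zero sample(s); their mutual "
                       "dissimilarities are undefined (NaN)", int(zero.sum()))
    ids = list(table.columns)
    return pd.DataFrame(dm, index=ids, columns=ids)


def within_group_dissimilarities(dm: pd.DataFrame, groups: pd.Series) -> dict[str, np.ndarray]:
    """Within-group pairwise values feeding the per-age beta-diversity boxes.

    For each group of size k the k(k-1)/2 upper-triangle values are
    returned; singleton groups yield an empty array with a warning.
    Every sample in ``dm`` must be grouped.
    """
    groups = groups.reindex(dm.index)
    if groups.isna().any():
        missing = list(dm.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    out: dict[str, np.ndarray] = {}
    for g, members in groups.groupby(groups).groups.items():
        idx = [dm.index.get_loc(s) for s in members]
        if len(idx) < 2:
            logger.warning("group %r has a single sample; no within-group pairs", g)
            out[str(g)] = np.empty(0)
            continue
        sub = dm.to_numpy()[np.ix_(idx, idx)]
        out[str(g)] = sub[np.triu_indices(len(idx), k=1)]
    return out
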