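"""Average variation degree (AVD): a per-group community-stability index.

For each sample group (k samples) and each ASV i with group mean x̄_i and
group sample standard deviation δ_i (denominator k-1), the per-sample
variation degree is a_i(s) = |x_i(s) - x̄_i| / δ_i. The per-sample AVD is
the mean of a_i(s) over the n usable ASVs, and the group AVD averages
that over the k samples — identically the double sum over ASVs and
samples divided by k·n. Lower AVD is read as higher community stability.

ASVs whose group SD is zero (including ASVs absent from the group) carry
an undefined 0/0 term and are excluded from n; the exclusion count is
reported. Because each ASV is standardized by its own group SD, AVD is
invariant to per-ASV linear rescaling — counts at a common rarefied
depth and relative abundances give the same value — but it is *not*
invariant to per-sample renormalization with unequal depths, so the
input form is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posthoc import anova_oneway, duncan_letters

logger = logging.getLogger("microstand")

__all__ = ["StabilityResult", "avd", "compare_avd"]


@dataclass
class StabilityResult:
    group: str
    k: int                      # samples in the group
    n: int                      # ASVs entering the sum
    n_excluded: int             # ASVs dropped for zero group SD
    per_sample_avd: pd.Series   # indexed by sample id
    group_avd: float            # mean of per-sample values == Eq. double sum / (k n)


def avd(table: pd.DataFrame, groups: pd.Series,
        restrict_to_present: bool = True) -> dict[str, StabilityResult]:
    """Average variation degree per group of samples.

    Parameters
    ----------
    table
        Features x samples; rarefied counts by default in this pipeline
        (relative abundances give identical values at equal depth).
    groups
        Sample id -> group label, covering every column of ``table``.
    restrict_to_present
        When True (default) n counts only ASVs present in the group
        (nonzero somewhere) that survive the zero-SD exclusion; when
        False, n is the full table's feature count (excluded ASVs still
        contribute nothing to the numerator).

    A group where every ASV has zero SD has no defined AVD and is
    reported with ``group_avd = NaN``.
    """
    groups = groups.reindex(table.columns)
    if groups.isna().any():
        missing = list(table.columns[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    results: dict[str, StabilityResult] = {}
    for g, members in groups.groupby(groups).groups.items():
        sub = table[list(members)].to_numpy(dtype=float)
        k = sub.shape[1]
        if k < 2:
            raise ValueError(f"group {g!r} has {k} sample(s); AVD needs k >= 2")
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        usable = sd > 0
        n_excluded = int((~usable).sum())
        # zero-SD ASVs never enter the numerator; the flag only decides
        # whether they are also dropped from the divisor n (default) or n
        # stays the full feature count of the table
        n = int(usable.sum()) if restrict_to_present else int(table.shape[0])
        if n == 0:
            logger.warning("group %r: every ASV has zero within-group SD; "
                           "AVD undefined", g)
            per_sample = pd.Series(np.nan, index=list(members))
            results[str(g)] = StabilityResult(str(g), k, 0, n_excluded,
                                              per_sample, float("nan"))
            continue
        a = np.abs(sub[usable] - mean[usable, None]) / sd[usable, None]
        per_sample = pd.Series(a.sum(axis=0) / n, index=list(members))
        results[str(g)] = StabilityResult(str(g), k, n, n_excluded,
                                          per_sample, float(per_sample.mean()))
    return results


def compare_avd(results: dict[str, StabilityResult], alpha: float = 0.05):
    """One-way ANOVA + Duncan letters over the per-sample AVD values.

    Returns ``(F, p, letters)`` where ``letters`` is the frame produced
    by :func:`microstand.posthoc.duncan_letters`.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 groups to compare AVD")
    values, labels = [], []
    for g, res in results.items():
        vals = res.per_sample_avd.dropna()
        values.extend(vals.to_numpy())
        labels.extend([g] * len(vals))
    values = np.asarray(values)
    labels = np.asarray(labels)
    F, p = anova_oneway(values, labels)
    letters = duncan_letters(values, labels, alpha=alpha)
    return F, p, letters
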