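"""One-way ANOVA and Duncan's multiple range test with compact letter display.

The letter output follows the convention of the figures these tests feed:
groups sharing any letter are not significantly different at the chosen
alpha; distinct letters mark significant separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = ["anova_oneway", "duncan_letters"]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _split(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = pd.unique(groups)
    parts = [values[groups == g] for g in labels]
    return labels, parts


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p.

    Degenerate inputs are reported rather than hidden: zero within-group
    variance with unequal means gives ``(inf, 0.0)``; zero variance with
    equal means gives ``(nan, nan)``.
    """
    labels, parts = _split(values, groups)
    if len(labels) < 2 or any(len(p) < 2 for p in parts):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(len(p) for p in parts)
    grand = np.concatenate(parts).mean()
    ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df_b, df_w = len(labels) - 1, n - len(labels)
    if ssw == 0:
        return (np.inf, 0.0) if ssb > 0 else (np.nan, np.nan)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(f_dist.sf(F, df_b, df_w))
    return float(F), p


@lru_cache(maxsize=None)
def _duncan_q(span: int, df: int, alpha: float) -> float:
    # special protection level: the range over `span` ordered means is
    # tested at 1 - (1-alpha)^(span-1)
    return float(studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df))


def duncan_letters(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's multiple range test summarized as letter groupings.

    Group means are ranked; the range spanning ``p`` ordered means is
    declared homogeneous when it does not exceed the least significant
    range ``LSR_p = q'(p, df_error, alpha) * sqrt(MS_error / n_h)``,
    where ``q'`` is the studentized-range quantile at the protection
    level ``1 - (1-alpha)^(p-1)`` and ``n_h`` the harmonic mean group
    size. Testing is step-down: a range inside a homogeneous range is
    never re-tested. Letters are the maximal homogeneous runs of the
    ordered means, so two groups share a letter iff their comparison is
    non-significant.

    Returns a frame with columns ``group``, ``n``, ``mean``, ``letters``
    ordered by descending mean.
    """
    labels, parts = _split(values, groups)
    a = len(labels)
    if a < 2 or any(len(p) < 2 for p in parts):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(len(p) for p in parts)
    df_w = n_total - a
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    mse = ssw / df_w
    n_h = a / sum(1.0 / len(p) for p in parts)
    se = np.sqrt(mse / n_h)

    means = np.array([p.mean() for p in parts])
    order = np.argsort(-means, kind="stable")  # descending
    m = means[order]

    # homog[i][j]: the ordered range i..j was declared homogeneous
    homog: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(lo <= i and j <= hi for lo, hi in homog)

    for span in range(a, 1, -1):
        for i in range(a - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            lsr = _duncan_q(span, df_w, alpha) * se
            if m[i] - m[j] <= lsr:
                homog.append((i, j))

    intervals = [(lo, hi) for lo, hi in homog
                 if not any((lo2 <= lo and hi <= hi2) and (lo2, hi2) != (lo, hi)
                            for lo2, hi2 in homog)]
    # singletons for groups in no homogeneous interval
    for i in range(a):
        if not any(lo <= i <= hi for lo, hi in intervals):
            intervals.append((i, i))
    intervals.sort()

    letter_sets = ["" for _ in range(a)]
    for li, (lo, hi) in enumerate(intervals):
        for i in range(lo, hi + 1):
            letter_sets[i] += _LETTERS[li]

    out = pd.DataFrame({
        "group": [labels[i] for i in order],
        "n": [len(parts[i]) for i in order],
        "mean": m,
        "letters": letter_sets,
    })
    return out


def letters_share(result: pd.DataFrame, g1, g2) -> bool:
    """True when two groups share at least one letter (non-significant pair)."""
    s1 = set(result.loc[result["group"] == g1, "letters"].item())
    s2 = set(result.loc[result["group"] == g2, "letters"].item())
    return bool(s1 & s2)
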