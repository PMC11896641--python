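"""Independent reference implementation of Duncan's multiple range test.

Deliberately structured differently from the package code: recursive
top-down range testing over every (i, j) pair, followed by a greedy
clique cover of the non-significance graph to build letters. Used only
as a cross-check oracle.
"""

import numpy as np
from scipy.stats import studentized_range


def duncan_reference(values, groups, alpha=0.05):
    """Return {group: frozenset of letter indices} and the set of significant pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    data = {g: values[groups == g] for g in labels}
    a = len(labels)
    n_total = len(values)
    df = n_total - a
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df
    n_h = a / sum(1.0 / len(v) for v in data.values())
    se = np.sqrt(mse / n_h)
    means = {g: v.mean() for g, v in data.items()}
    ranked = sorted(labels, key=lambda g: means[g])  # ascending

    nonsig = set()

    def declare_homogeneous(lo, hi):
        for x in range(lo, hi + 1):
            for y in range(x + 1, hi + 1):
                nonsig.add(frozenset((ranked[x], ranked[y])))

    def test_range(lo, hi):
        if hi <= lo:
            return
        span = hi - lo + 1
        q = studentized_range.ppf((1 - alpha) ** (span - 1), span, df)
        diff = means[ranked[hi]] - means[ranked[lo]]
        if diff <= q * se:
            declare_homogeneous(lo, hi)
        else:
            test_range(lo + 1, hi)
            test_range(lo, hi - 1)

    test_range(0, a - 1)
    sig = {frozenset((g1, g2)) for i, g1 in enumerate(labels)
           for g2 in labels[i + 1:]} - nonsig

    # greedy clique cover of the non-significance graph, scanning the
    # ranked means so cliques are contiguous runs
    cliques = []
    for i, g in enumerate(ranked):
        placed = False
        for cl in cliques:
            if all(frozenset((g, h)) in nonsig for h in cl):
                cl.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    letters = {g: frozenset(ci for ci, cl in enumerate(cliques) if g in cl)
               for g in labels}
    return letters, sig
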