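"""Principal coordinates analysis and one-way PERMANOVA on a distance matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCoAResult", "pcoa", "PermanovaResult", "permanova"]


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame        # samples x retained axes
    eigenvalues: np.ndarray          # retained (positive), non-increasing
    proportion_explained: np.ndarray # over the positive eigenvalues


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int


def _check_square(dm: pd.DataFrame) -> np.ndarray:
    D = dm.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def pcoa(dm: pd.DataFrame, correction: str | None = None) -> PCoAResult:
    """Classical metric scaling (Gower double-centering of -D^2/2).

    Axes with eigenvalues at or below numerical tolerance are dropped;
    proportions explained are taken over the positive eigenvalues only.
    Negative eigenvalues from a semi-metric such as Bray-Curtis are
    discarded by default; ``correction="lingoes"`` adds the constant
    -2*lambda_min to every squared off-diagonal distance first, which
    makes the configuration Euclidean-embeddable.
    """
    D = _check_square(dm)
    n = D.shape[0]
    if correction not in (None, "lingoes"):
        raise ValueError(f"unknown correction: {correction!r}")
    if correction == "lingoes":
        evals0 = _gower_eigenvalues(D)
        lam_min = evals0.min()
        if lam_min < 0:
            D2 = D ** 2 - 2.0 * lam_min
            np.fill_diagonal(D2, 0.0)
            D = np.sqrt(D2)
    B = _gower_center(D)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), abs(evals[-1]), 1.0) * 1e-10 if n else 0.0
    keep = evals > tol
    pos = evals[keep]
    coords = evecs[:, keep] * np.sqrt(pos)
    axes = [f"PCo{i + 1}" for i in range(keep.sum())]
    coordinates = pd.DataFrame(coords, index=dm.index, columns=axes)
    prop = pos / pos.sum() if pos.size else pos
    return PCoAResult(coordinates=coordinates, eigenvalues=pos, proportion_explained=prop)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _gower_eigenvalues(D: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(_gower_center(D))


def _group_codes(dm: pd.DataFrame, groups: pd.Series) -> np.ndarray:
    groups = groups.reindex(dm.index)
    if groups.isna().any():
        missing = list(dm.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    codes, _ = pd.factorize(groups.to_numpy())
    return codes


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def permanova(dm: pd.DataFrame, groups: pd.Series, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Distance-based one-way PERMANOVA (Anderson's pseudo-F).

    SS_total = sum_{i<j} d_ij^2 / N; SS_within sums the analogous term
    inside each group; F = (SS_between/(a-1)) / (SS_within/(N-a)). The
    p-value permutes group labels over samples with a seeded generator:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    D = _check_square(dm)
    codes = _group_codes(dm, groups)
    n = D.shape[0]
    a = codes.max() + 1
    sizes = np.bincount(codes)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (sizes < 2).any():
        small = [i for i, s in enumerate(sizes) if s < 2]
        raise ValueError(f"every group needs >= 2 samples (group index {small})")
    d2 = D ** 2
    ss_total = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, codes, a)
    ssb = ss_total - ssw
    df_b, df_w = a - 1, n - a
    if ssw <= 0:
        f_obs = np.inf if ssb > 0 else np.nan
    else:
        f_obs = (ssb / df_b) / (ssw / df_w)
    r2 = ssb / ss_total if ss_total > 0 else np.nan

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(n)]
        ssw_p = _ss_within(d2, perm_codes, a)
        ssb_p = ss_total - ssw_p
        f_p = np.inf if ssw_p <= 0 and ssb_p > 0 else (
            (ssb_p / df_b) / (ssw_p / df_w) if ssw_p > 0 else np.nan)
        if f_p >= f_obs or (np.isnan(f_p) and np.isnan(f_obs)):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p_value=float(p),
                           n_permutations=int(n_perm), seed=int(seed))
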