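import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import microstand as ms


def euclidean_dm(points, ids=None):
    ids = ids or [f"P{i}" for i in range(len(points))]
    D = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(D, index=ids, columns=ids)


def reconstructed_distances(coords):
    return squareform(pdist(coords.to_numpy()))


class TestPCoA:
    def test_identical_points_give_no_axes(self):
        dm = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        res = ms.pcoa(dm)
        assert res.eigenvalues.size == 0
        assert res.coordinates.shape == (4, 0)

    def test_unit_square_distances_reconstructed(self):
        dm = euclidean_dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        res = ms.pcoa(dm)
        assert np.abs(reconstructed_distances(res.coordinates) - dm.to_numpy()).max() < 1e-9

    def test_collinear_points_need_one_axis(self):
        dm = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                          index=list("abc"), columns=list("abc"), dtype=float)
        res = ms.pcoa(dm)
        assert res.eigenvalues.size == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_eigenvalues_sorted_and_proportions(self, rng):
        dm = euclidean_dm(rng.normal(size=(8, 4)))
        res = ms.pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)
        assert (res.eigenvalues > 0).all()

    def test_non_symmetric_rejected(self):
        dm = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"),
                          dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            ms.pcoa(dm)

    def test_agrees_with_skbio_on_bray_curtis(self, community):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        table, _, _ = community
        dm = ms.bray_curtis(table)
        mine = ms.pcoa(dm)
        theirs = skbio_ord.pcoa(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
        k = mine.eigenvalues.size
        ev_theirs = np.sort(theirs.eigvals.to_numpy())[::-1][:k]
        assert np.allclose(mine.eigenvalues, ev_theirs, atol=1e-8)

    def test_lingoes_correction_removes_negativity(self, community):
        table, _, _ = community
        dm = ms.bray_curtis(table)
        res = ms.pcoa(dm, correction="lingoes")
        # corrected configuration is Euclidean: distances reconstruct the
        # corrected matrix, and all retained eigenvalues are positive
        assert (res.eigenvalues > 0).all()
        assert res.coordinates.shape[0] == 20


class TestPermanova:
    def test_separated_groups_reject_strongly(self):
        # two tight, distant clusters with mild jitter
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(10, 0.01, (5, 2))])
        dm = euclidean_dm(pts)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.index)
        res = ms.permanova(dm, groups, n_perm=999, seed=1)
        assert res.pseudo_F > 100
        assert res.R2 > 0.9
        # only permutations reproducing the exact split can tie the
        # observed F; p stays near its floor of 1/(n_perm+1)
        assert res.p_value <= 0.02
        assert abs(res.p_value * 1000 - round(res.p_value * 1000)) < 1e-9

    def test_all_equal_distances_give_p_one(self):
        n = 6
        D = np.ones((n, n)) - np.eye(n)
        dm = pd.DataFrame(D, index=[f"s{i}" for i in range(n)],
                          columns=[f"s{i}" for i in range(n)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=dm.index)
        res = ms.permanova(dm, groups, n_perm=199, seed=2)
        assert res.p_value == 1.0

    def test_seeded_reproducibility(self, community):
        table, metadata, _ = community
        dm = ms.bray_curtis(table)
        r1 = ms.permanova(dm, metadata["stand_age"], seed=5)
        r2 = ms.permanova(dm, metadata["stand_age"], seed=5)
        assert r1 == r2

    def test_pseudo_F_matches_skbio(self, community):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        table, metadata, _ = community
        dm = ms.bray_curtis(table)
        mine = ms.permanova(dm, metadata["stand_age"], n_perm=99, seed=0)
        theirs = skbio_dist.permanova(
            DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            grouping=metadata["stand_age"].to_list(), permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_group_size_validation(self):
        dm = euclidean_dm(np.arange(6)[:, None])
        bad = pd.Series(["a"] * 5 + ["b"], index=dm.index)
        with pytest.raises(ValueError, match=">= 2 samples"):
            ms.permanova(dm, bad)
        one = pd.Series(["a"] * 6, index=dm.index)
        with pytest.raises(ValueError, match="two groups"):
            ms.permanova(dm, one)

    def test_null_p_values_roughly_uniform(self):
        # labels carry no information: p should not pile up near zero
        rng = np.random.default_rng(99)
        ps = []
        for rep in range(60):
            pts = rng.normal(size=(10, 3))
            dm = euclidean_dm(pts)
            groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.index)
            ps.append(ms.permanova(dm, groups, n_perm=199, seed=rep).p_value)
        assert 0.25 < np.mean(ps) < 0.75
        assert np.mean(np.array(ps) <= 0.05) < 0.2
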