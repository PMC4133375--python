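import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from phylobeta_forest.inference import (
    InferenceError,
    mantel,
    pairwise_contrasts,
    perm_anova,
    permanova,
)


def _euclidean(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestPermAnova:
    def test_perfect_separation_gives_minimal_p(self):
        # no within-group noise: observed F is infinite and (almost) no
        # permutation can reproduce the partition
        y = np.repeat([0.0, 5.0, 9.0], 6)
        groups = np.repeat(["a", "b", "c"], 6)
        res = perm_anova(y, groups, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert np.isinf(res.observed)

    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=14)
        groups = ["a"] * 6 + ["b"] * 8
        res = perm_anova(y, groups, n_perm=9, seed=0)
        t = stats.ttest_ind(y[:6], y[6:], equal_var=True).statistic
        assert res.observed == pytest.approx(t**2, abs=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=18)
        groups = np.repeat(["a", "b", "c"], 6)
        res = perm_anova(y, groups, n_perm=9, seed=0)
        expected = stats.f_oneway(y[:6], y[6:12], y[12:]).statistic
        assert res.observed == pytest.approx(expected, abs=1e-10)
        assert res.df == (2, 15)

    def test_requires_two_groups_of_two(self):
        with pytest.raises(InferenceError):
            perm_anova([1.0, 2.0, 3.0], ["a", "a", "b"], n_perm=9)

    def test_seeded_and_order_invariant(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        r1 = perm_anova(y, groups, n_perm=199, seed=11)
        r2 = perm_anova(y, groups, n_perm=199, seed=11)
        assert r1.p_value == r2.p_value and r1.observed == r2.observed


class TestPermanova:
    def test_univariate_euclidean_equals_classical_f(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=15)
        groups = np.repeat(["a", "b", "c"], 5)
        dm = _euclidean(y[:, None])
        res = permanova(dm, groups, n_perm=9, seed=0)
        expected = stats.f_oneway(y[:5], y[5:10], y[10:]).statistic
        assert res.observed == pytest.approx(expected, abs=1e-9)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(16, 4))
        groups = np.repeat(["a", "b"], 8)
        dm = _euclidean(points)
        ours = permanova(dm, groups, n_perm=9, seed=0)
        theirs = skbio_permanova(dm, grouping=list(groups), permutations=9)
        assert ours.observed == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_r2_decomposition_sums_to_one(self):
        rng = np.random.default_rng(6)
        points = rng.normal(size=(12, 3))
        groups = np.repeat(["a", "b", "c"], 4)
        dm = _euclidean(points)
        res = permanova(dm, groups, n_perm=9, seed=0)
        n, g = 12, 3
        # R2 = SS_A/SS_T and F = (SS_A/(g-1))/(SS_W/(n-g)) must cohere
        implied_f = (res.r_squared / (g - 1)) / ((1 - res.r_squared) / (n - g))
        assert implied_f == pytest.approx(res.observed, abs=1e-10)
        assert 0 <= res.r_squared <= 1

    def test_identical_groups_separated_in_space_give_max_f(self):
        points = np.array([[0.0, 0]] * 7 + [[10.0, 0]] * 7)
        dm = _euclidean(points)
        groups = ["a"] * 7 + ["b"] * 7
        res = permanova(dm, groups, n_perm=99, seed=0)
        assert np.isinf(res.observed)
        assert res.p_value == pytest.approx(1 / 100)

    def test_groups_as_mapping_aligned_by_id(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(8, 2))
        ids = [f"s{i}" for i in range(8)]
        dm = _euclidean(points, ids)
        mapping = pd.Series(["a", "b"] * 4, index=ids)
        shuffled = mapping.sample(frac=1, random_state=0)
        r1 = permanova(dm, mapping, n_perm=49, seed=1)
        r2 = permanova(dm, shuffled, n_perm=49, seed=1)
        assert r1.observed == pytest.approx(r2.observed)
        assert r1.p_value == r2.p_value

    def test_singleton_group_rejected(self):
        dm = _euclidean(np.arange(5, dtype=float)[:, None])
        with pytest.raises(InferenceError):
            permanova(dm, ["a", "a", "a", "a", "b"], n_perm=9)


class TestContrasts:
    def test_emits_all_unordered_pairs(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=20)
        groups = np.repeat(["a", "b", "c", "d"], 5)
        contrasts = pairwise_contrasts(y, groups, n_perm=49, seed=0, kind="anova")
        assert len(contrasts) == 6
        assert {(c.group1, c.group2) for c in contrasts} == {
            ("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")
        }

    def test_contrast_equals_two_group_rerun(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(15, 3))
        groups = np.repeat(["a", "b", "c"], 5)
        dm = _euclidean(points)
        contrasts = pairwise_contrasts(dm, groups, n_perm=99, seed=3, kind="permanova")
        ab = next(c for c in contrasts if (c.group1, c.group2) == ("a", "b"))
        sub = dm.filter([f"s{i}" for i in range(10)])
        direct = permanova(sub, groups[:10], n_perm=99, seed=3)
        assert ab.observed == pytest.approx(direct.observed, abs=1e-12)
        assert ab.p_value == direct.p_value

    def test_divergent_group_shows_larger_f(self):
        rng = np.random.default_rng(10)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(0.2, 1, 8),
                            rng.normal(6, 1, 8)])
        groups = np.repeat(["a", "b", "far"], 8)
        contrasts = {(c.group1, c.group2): c.observed
                     for c in pairwise_contrasts(y, groups, n_perm=9, seed=0, kind="anova")}
        assert contrasts[("a", "far")] > contrasts[("a", "b")]
        assert contrasts[("b", "far")] > contrasts[("a", "b")]

    def test_holm_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=18)
        groups = np.repeat(["a", "b", "c"], 6)
        raw = pairwise_contrasts(y, groups, n_perm=199, seed=5, kind="anova")
        adj = pairwise_contrasts(y, groups, n_perm=199, seed=5, kind="anova",
                                 p_adjust="holm")
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-12
            assert a.p_value <= 1.0


class TestMantel:
    def test_proportional_matrices_give_rho_one(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(9, 2))
        d1 = _euclidean(points)
        d2 = DistanceMatrix(3.0 * d1.data, ids=list(d1.ids))
        res = mantel(d1, d2, n_perm=99, seed=0)
        assert res.rho == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_rho_equals_pearson_on_triangles(self):
        rng = np.random.default_rng(13)
        d1 = _euclidean(rng.normal(size=(8, 3)))
        d2 = _euclidean(rng.normal(size=(8, 3)), ids=list(d1.ids))
        res = mantel(d1, d2, n_perm=9, seed=0)
        tri = np.tril_indices(8, k=-1)
        expected = stats.pearsonr(d1.data[tri], d2.data[tri]).statistic
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio_mantel_statistic(self):
        rng = np.random.default_rng(14)
        d1 = _euclidean(rng.normal(size=(10, 3)))
        d2 = _euclidean(rng.normal(size=(10, 3)), ids=list(d1.ids))
        ours = mantel(d1, d2, n_perm=9, seed=0)
        theirs_r, _, _ = skbio_mantel(d1, d2, method="pearson", permutations=9)
        assert ours.rho == pytest.approx(theirs_r, abs=1e-10)

    def test_alignment_by_ids_not_order(self):
        rng = np.random.default_rng(15)
        d1 = _euclidean(rng.normal(size=(7, 2)))
        d2 = _euclidean(rng.normal(size=(7, 2)), ids=list(d1.ids))
        shuffled = d2.filter(list(d1.ids)[::-1])
        r1 = mantel(d1, d2, n_perm=49, seed=2)
        r2 = mantel(d1, shuffled, n_perm=49, seed=2)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_zero_variance_rejected(self):
        d1 = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        d2 = _euclidean(np.random.default_rng(0).normal(size=(4, 2)), ids=list("abcd"))
        with pytest.raises(InferenceError, match="variance"):
            mantel(d1, d2, n_perm=9)
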