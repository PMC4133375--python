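import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylobeta_forest.community import CommunityMatrix
from phylobeta_forest.phylobeta import (
    METHODS,
    PhyloBetaError,
    comdist,
    comdistnt,
    fuzzy_composition,
    fuzzy_dissimilarity,
    jaccard,
    matrix_p,
    phylo_weights,
    phylobeta_matrix,
    rao_h,
    unifrac,
)
from phylobeta_forest.trees import parse_newick, patristic_distances

from conftest import random_community, random_tree, star_tree
from oracles import (
    braycurtis_sqrt_oracle,
    comdist_oracle,
    comdistnt_oracle,
    jaccard_oracle,
    matrix_p_oracle,
    rao_between_oracle,
    rao_h_oracle,
    unifrac_oracle,
)


class TestPhyloWeights:
    def test_two_species_give_identity(self):
        tree = parse_newick("(A:5,B:5);")
        q = phylo_weights(patristic_distances(tree))
        np.testing.assert_allclose(q.to_numpy(), np.eye(2), atol=1e-12)

    def test_three_equidistant_species_symmetric_rows(self):
        q = phylo_weights(patristic_distances(star_tree(3)))
        off = q.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_computed_row(self, small_tree):
        q = phylo_weights(patristic_distances(small_tree))
        np.testing.assert_allclose(
            q.loc["A", ["A", "B", "C"]], [2 / 3, 1 / 3, 0.0], atol=1e-12
        )

    def test_degenerate_tree_rejected(self):
        d = patristic_distances(parse_newick("(A:0,B:0);"))
        with pytest.raises(PhyloBetaError, match="degenerate"):
            phylo_weights(d)


class TestMatrixP:
    def test_singleton_plot_keeps_all_weight(self, small_tree):
        inc = pd.DataFrame([[1, 0, 0], [1, 1, 1]], index=["s1", "s2"],
                           columns=["A", "B", "C"])
        q = phylo_weights(patristic_distances(small_tree))
        P = matrix_p(CommunityMatrix(inc), q)
        assert P.values.loc["A", "s1"] == pytest.approx(1.0)
        assert P.values["s1"].sum() == pytest.approx(1.0)

    def test_equidistant_full_plot_is_uniform(self):
        inc = pd.DataFrame([[1, 1, 1]], index=["s"], columns=["t1", "t2", "t3"])
        q = phylo_weights(patristic_distances(star_tree(3)))
        P = matrix_p(CommunityMatrix(inc), q)
        np.testing.assert_allclose(P.values["s"], 1.0, atol=1e-12)

    def test_two_species_plot_hand_computation(self, small_tree):
        inc = pd.DataFrame([[1, 1, 0]], index=["s"], columns=["A", "B", "C"])
        q = phylo_weights(patristic_distances(small_tree))
        P = matrix_p(CommunityMatrix(inc), q)
        assert P.values.loc["A", "s"] == pytest.approx(1.0)
        assert P.values.loc["B", "s"] == pytest.approx(1.0)
        assert P.values["s"].sum() == pytest.approx(2.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_columns_conserve_plot_richness(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 12))
        tree = random_tree(n_tips, rng)
        species = [f"t{i + 1}" for i in range(n_tips)]
        community = random_community(int(rng.integers(2, 7)), species, rng)
        P = fuzzy_composition(community, tree)
        totals = P.values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(
            totals, community.richness().to_numpy(), atol=1e-10
        )
        # positive weight only for species present in the plot
        present = community.incidence.T.to_numpy() > 0
        assert ((P.values.to_numpy() > 0) <= present).all()

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(17)
        tree = random_tree(8, rng)
        species = [f"t{i + 1}" for i in range(8)]
        community = random_community(5, species, rng)
        d = patristic_distances(tree).filter(species)
        s = 1.0 - d.data / d.data.max()
        expected = matrix_p_oracle(community.to_array(), s)
        P = fuzzy_composition(community, tree)
        np.testing.assert_allclose(
            P.values.loc[species].to_numpy(), expected, atol=1e-12
        )


class TestPairwiseMeasures:
    def test_trivial_identities(self, small_tree):
        d = patristic_distances(small_tree)
        assert comdist(d, ["A"], ["A"]) == 0.0
        assert comdist(d, ["A"], ["B", "C"]) == pytest.approx(3.0)
        assert comdistnt(d, ["A", "B"], ["C"]) == pytest.approx(4.0)
        assert rao_h(d, ["A", "B"], ["A", "B"]) == pytest.approx(1.0)
        assert unifrac(small_tree, ["A", "B"], ["A", "B"]) == 0.0
        assert unifrac(small_tree, ["A", "B"], ["C"]) == pytest.approx(1.0)
        assert jaccard(["A", "B"], ["B", "C"]) == pytest.approx(2 / 3)

    def test_shared_species_contribute_zero_nearest_distance(self, small_tree):
        d = patristic_distances(small_tree)
        # A is shared: its nearest-taxon term vanishes in both directions
        value = comdistnt(d, ["A", "B"], ["A", "C"])
        assert value == pytest.approx(0.5 * ((0 + 2) / 2 + (0 + 4) / 2))

    def test_rao_h_star_tree_closed_form(self):
        # disjoint equal-size plots on a star tree: every cross pair is 2L,
        # within-plot mean (ordered pairs incl. self) is 2L(n-1)/n
        n = 4
        tree = star_tree(2 * n, length=3.0)
        d = patristic_distances(tree)
        site1 = [f"t{i + 1}" for i in range(n)]
        site2 = [f"t{i + 1}" for i in range(n, 2 * n)]
        assert rao_h(d, site1, site2) == pytest.approx(n / (n - 1))

    def test_monospecific_pair_rao_h_undefined(self, small_tree):
        d = patristic_distances(small_tree)
        with pytest.raises(PhyloBetaError, match="undefined"):
            rao_h(d, ["A"], ["C"])

    def test_empty_site_rejected(self, small_tree):
        d = patristic_distances(small_tree)
        for fn in (lambda: comdist(d, [], ["A"]), lambda: unifrac(small_tree, [], ["A"])):
            with pytest.raises(PhyloBetaError, match="empty"):
                fn()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_pairs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(10, rng)
        d = patristic_distances(tree)
        ids = list(d.ids)
        for _ in range(10):
            s1 = list(rng.choice(ids, size=int(rng.integers(2, 6)), replace=False))
            s2 = list(rng.choice(ids, size=int(rng.integers(2, 6)), replace=False))
            i1 = [ids.index(s) for s in s1]
            i2 = [ids.index(s) for s in s2]
            assert comdist(d, s1, s2) == pytest.approx(
                comdist_oracle(d.data, i1, i2), abs=1e-12
            )
            assert comdistnt(d, s1, s2) == pytest.approx(
                comdistnt_oracle(d.data, i1, i2), abs=1e-12
            )
            assert rao_h(d, s1, s2) == pytest.approx(
                rao_h_oracle(d.data, i1, i2), abs=1e-12
            )
            assert unifrac(tree, s1, s2) == pytest.approx(
                unifrac_oracle(tree, s1, s2), abs=1e-12
            )


class TestBatchMatrices:
    def _setup(self, seed, n_tips=9, n_sites=6):
        rng = np.random.default_rng(seed)
        tree = random_tree(n_tips, rng)
        species = [f"t{i + 1}" for i in range(n_tips)]
        community = random_community(n_sites, species, rng, min_rich=2)
        return tree, community

    @pytest.mark.parametrize("method", METHODS)
    def test_matrix_agrees_with_pairwise_functions(self, method):
        tree, community = self._setup(23)
        d = patristic_distances(tree).filter(community.species)
        result = phylobeta_matrix(method, community, tree=tree)
        sites = community.sites
        fns = {
            "comdist": lambda a, b: comdist(d, a, b),
            "comdistnt": lambda a, b: comdistnt(d, a, b),
            "rao_h": lambda a, b: rao_h(d, a, b),
            "unifrac": lambda a, b: unifrac(tree, a, b),
            "jaccard": lambda a, b: jaccard(a, b),
        }
        if method == "fuzzy":
            P = fuzzy_composition(community, tree)
            X = P.values
            for i, s1 in enumerate(sites):
                for s2 in sites[i + 1:]:
                    expected = braycurtis_sqrt_oracle(
                        X[s1].to_numpy(), X[s2].to_numpy()
                    )
                    assert result.dm[s1, s2] == pytest.approx(expected, abs=1e-12)
        else:
            for i, s1 in enumerate(sites):
                for s2 in sites[i + 1:]:
                    expected = fns[method](
                        community.site_species(s1), community.site_species(s2)
                    )
                    assert result.dm[s1, s2] == pytest.approx(expected, abs=1e-10)

    def test_unifrac_equals_jaccard_on_star_phylogeny(self):
        tree = star_tree(12)
        rng = np.random.default_rng(4)
        community = random_community(8, [f"t{i + 1}" for i in range(12)], rng)
        uf = phylobeta_matrix("unifrac", community, tree=tree).dm
        jc = phylobeta_matrix("jaccard", community, tree=tree).dm
        assert np.max(np.abs(uf.data - jc.data)) < 1e-12

    def test_comdist_equals_between_plot_rao_d(self):
        tree, community = self._setup(31)
        d = patristic_distances(tree).filter(community.species)
        result = phylobeta_matrix("comdist", community, tree=tree).dm
        W = community.to_array()
        for i in range(community.n_sites):
            for j in range(i + 1, community.n_sites):
                expected = rao_between_oracle(
                    d.data,
                    list(np.flatnonzero(W[i])),
                    list(np.flatnonzero(W[j])),
                )
                assert result.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_fuzzy_identical_and_disjoint_plots(self):
        tree = star_tree(4)
        inc = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=[f"t{i + 1}" for i in range(4)],
        )
        dm = phylobeta_matrix("fuzzy", CommunityMatrix(inc), tree=tree).dm
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)
        assert dm["s1", "s3"] == pytest.approx(1.0)

    def test_invariant_to_site_order(self):
        tree, community = self._setup(57)
        shuffled = CommunityMatrix(
            community.incidence.iloc[::-1].copy(), groups=community.groups
        )
        for method in ("comdistnt", "fuzzy", "unifrac"):
            a = phylobeta_matrix(method, community, tree=tree).dm
            b = phylobeta_matrix(method, shuffled, tree=tree).dm
            np.testing.assert_allclose(
                a.data, b.filter(list(a.ids)).data, atol=1e-12
            )

    def test_invariant_to_structure_preserving_relabeling(self):
        # renaming species consistently in tree + matrix leaves values fixed
        tree, community = self._setup(71)
        mapping = {s: f"x_{s}" for s in community.species}
        renamed_tree = parse_newick(
            "".join(tree.as_string(schema="newick", unquoted_underscores=True))
        )
        for leaf in renamed_tree.leaf_node_iter():
            leaf.taxon.label = mapping[leaf.taxon.label]
        renamed = CommunityMatrix(
            community.incidence.rename(columns=mapping), groups=community.groups
        )
        for method in METHODS:
            a = phylobeta_matrix(method, community, tree=tree).dm
            b = phylobeta_matrix(method, renamed, tree=renamed_tree).dm
            np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_unknown_method_rejected(self):
        tree, community = self._setup(3)
        with pytest.raises(PhyloBetaError, match="unknown method"):
            phylobeta_matrix("phylosor", community, tree=tree)
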