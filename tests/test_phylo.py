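import numpy as np
import pytest
from conftest import dendropy_splits, oracle_consensus_splits

from magprov.phylo import (
    Alignment,
    Tree,
    bipartitions,
    concatenate,
    consensus,
    placement_congruence,
    rf_distance,
    rf_distance_normalized,
    select_consensus_splits,
    split_frequencies,
    trim_columns,
)

T = Tree.from_newick


class TestTrimColumns:
    def test_exactly_ten_percent_gaps_removed(self):
        # 10 taxa, second column has exactly one gap (10%): strict < drops it
        rows = {f"t{i}": ("A-C" if i == 0 else "AAC") for i in range(10)}
        result = trim_columns(Alignment(rows))
        assert result.alignment.n_cols == 2
        assert result.removed_columns == [1]

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment({"a": "MKV", "b": "MRV"})
        result = trim_columns(aln)
        assert result.alignment.rows == aln.rows and result.removed_columns == []

    def test_five_percent_gaps_retained(self):
        rows = {f"t{i}": ("-AC" if i == 0 else "AAC") for i in range(20)}
        assert trim_columns(Alignment(rows)).alignment.n_cols == 3

    def test_all_columns_removed_suggests_threshold(self):
        aln = Alignment({"a": "--", "b": "AA"})
        with pytest.raises(ValueError, match="max_gap_frac"):
            trim_columns(aln)


class TestConcatenate:
    def test_subunit_lengths_sum(self):
        taxa = ["t1", "t2", "t3"]
        alns = [
            Alignment({t: "A" * n for t in taxa}) for n in (400, 500, 484)
        ]
        result = concatenate(alns)
        assert result.alignment.n_cols == 1384
        assert result.offsets == [0, 400, 900]

    def test_single_input_identity(self):
        aln = Alignment({"a": "MKV", "b": "MRV"})
        assert concatenate([aln]).alignment.rows == aln.rows

    def test_missing_taxon_error_unless_padded(self):
        a1 = Alignment({"a": "MK", "b": "MR"})
        a2 = Alignment({"a": "VV"})
        with pytest.raises(ValueError, match="pad_missing"):
            concatenate([a1, a2])
        result = concatenate([a1, a2], pad_missing=True)
        assert result.alignment.rows["b"] == "MR--"
        assert result.padded_taxa == ["b"]

    def test_trim_then_concat_commutes_with_concat_then_trim(self):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(12)]
        blocks = []
        for n_cols in (30, 40):
            rows = {}
            for t in taxa:
                chars = rng.choice(list("MKVR-"), size=n_cols, p=[0.24, 0.24, 0.24, 0.24, 0.04])
                rows[t] = "".join(chars)
            blocks.append(Alignment(rows))
        a = trim_columns(concatenate(blocks).alignment).alignment
        b = concatenate([trim_columns(x).alignment for x in blocks]).alignment
        assert a.rows == b.rows


class TestBipartitions:
    def test_four_leaf_single_split(self):
        assert bipartitions(T("((A,B),(C,D));")) == {frozenset("CD")}

    def test_star_has_none(self):
        assert bipartitions(T("(A,B,C,D);")) == set()

    def test_resolved_five_leaf_has_two(self):
        assert len(bipartitions(T("((A,B),((C,D),E));"))) == 2

    def test_fewer_than_four_leaves_empty(self):
        assert bipartitions(T("(A,B,C);")) == set()

    def test_matches_dendropy_encoding(self, resolved_trees_6):
        for tree in resolved_trees_6[::10]:
            assert bipartitions(tree) == dendropy_splits(tree.to_newick())


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = T("((A,B),((C,D),E));")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        assert rf_distance(T("((A,B),(C,D));"), T("((A,C),(B,D));")) == 2

    def test_symmetric(self):
        t1, t2 = T("((A,B),((C,D),E));"), T("((A,C),((B,D),E));")
        assert rf_distance(t1, t2) == rf_distance(t2, t1)

    def test_leaf_mismatch_error_lists_difference(self):
        with pytest.raises(ValueError, match="E"):
            rf_distance(T("((A,B),(C,D));"), T("((A,B),(C,E));"))

    def test_normalized_bounds(self, resolved_trees_6):
        rng = np.random.default_rng(3)
        idx = rng.integers(0, len(resolved_trees_6), size=(20, 2))
        for i, j in idx:
            v = rf_distance_normalized(resolved_trees_6[i], resolved_trees_6[j])
            assert 0.0 <= v <= 1.0


class TestConsensus:
    def test_three_identical_trees(self):
        trees = [T("((A,B),((C,D),E));") for _ in range(3)]
        c = consensus(trees)
        assert bipartitions(c) == bipartitions(trees[0])
        freqs = split_frequencies(trees)
        assert all(f == 1.0 for f in freqs.values())

    def test_two_of_three_split_included_with_frequency(self):
        trees = [T("((A,B),((C,D),E));")] * 2 + [T("((A,C),((B,D),E));")]
        accepted = select_consensus_splits(
            split_frequencies(trees), trees[0].leaves
        )
        assert accepted[frozenset("CD")] == pytest.approx(2 / 3)

    def test_tie_break_is_lexicographic(self):
        # maximally conflicting quartets: both splits at 0.5; the extended
        # rule admits the lexicographically first (AB|CD beats AC|BD)
        trees = [T("((A,B),(C,D));"), T("((A,C),(B,D));")]
        c = consensus(trees)
        assert bipartitions(c) == {frozenset("CD")}
        strict = consensus(trees, rule="majority")
        assert bipartitions(strict) == set()  # star under strict majority

    def test_consensus_edges_carry_frequencies(self):
        trees = [T("((A,B),((C,D),E));")] * 2 + [T("((A,C),((B,D),E));")]
        c = consensus(trees)
        supports = sorted(
            n.support for n in c._postorder() if not n.is_leaf and n.support
        )
        assert supports == [pytest.approx(2 / 3), pytest.approx(2 / 3)]

    def test_matches_brute_force_on_sampled_six_leaf_triples(self, resolved_trees_6):
        rng = np.random.default_rng(17)
        leaves = resolved_trees_6[0].leaves
        cached = [bipartitions(t) for t in resolved_trees_6]
        for _ in range(60):
            i, j, k = rng.integers(0, len(resolved_trees_6), size=3)
            trees = [resolved_trees_6[x] for x in (i, j, k)]
            mine = select_consensus_splits(split_frequencies(trees), leaves)
            oracle = oracle_consensus_splits([cached[x] for x in (i, j, k)], leaves)
            assert mine == oracle

    def test_consensus_tree_reproduces_selected_splits(self, resolved_trees_5):
        rng = np.random.default_rng(19)
        leaves = resolved_trees_5[0].leaves
        for _ in range(40):
            i, j, k = rng.integers(0, len(resolved_trees_5), size=3)
            trees = [resolved_trees_5[x] for x in (i, j, k)]
            accepted = select_consensus_splits(split_frequencies(trees), leaves)
            assert bipartitions(consensus(trees)) == set(accepted)


class TestPlacementCongruence:
    GENOME = "(((F1,F2),(X1,X2)),((Y1,Y2),(Z1,Z2)));"

    def test_identical_trees_congruent(self):
        t = T(self.GENOME)
        assert placement_congruence(t, T(self.GENOME), ["F1", "F2"]) == "congruent"

    def test_regrafted_clade_incongruent(self):
        # focal sister to {X1,X2} in the genome tree, nested inside the
        # distant Z lineage in the gene tree
        gene = "((X1,X2),((Y1,Y2),(Z1,(Z2,(F1,F2)))));"
        assert (
            placement_congruence(T(gene), T(self.GENOME), ["F1", "F2"])
            == "incongruent"
        )

    def test_non_monophyletic_focal_unresolvable(self):
        gene = "(((F1,X1),(F2,X2)),((Y1,Y2),(Z1,Z2)));"
        assert (
            placement_congruence(T(gene), T(self.GENOME), ["F1", "F2"])
            == "unresolvable"
        )

    def test_missing_focal_leaves_error(self):
        with pytest.raises(ValueError, match="absent"):
            placement_congruence(T(self.GENOME), T(self.GENOME), ["F1", "NOPE"])

    def test_lineage_map_coarsens_sisters(self):
        # swapping X1/X2 within the same mapped lineage stays congruent
        gene = "(((F1,F2),(X2,X1)),((Y1,Y2),(Z1,Z2)));"
        lineage = {"X1": "X", "X2": "X", "Y1": "Y", "Y2": "Y", "Z1": "Z", "Z2": "Z"}
        assert (
            placement_congruence(T(gene), T(self.GENOME), ["F1", "F2"], lineage)
            == "congruent"
        )
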