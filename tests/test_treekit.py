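"""Bipartition algebra, RF, NJ, support tables, maxdiff, pruning."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

import phylocurate as pc
from phylocurate.treekit import (
    Bipartition,
    bipartition_frequencies,
    split_supports,
    terminal_labels,
)


def random_tree(n, seed):
    return pc.simulate_species_tree(n, seed)


class TestNewickIO:
    def test_single_internal_edge(self):
        t = pc.parse_newick("(A,B,(C,D));")
        (bp,) = pc.bipartitions(t)
        assert bp == Bipartition({"C", "D"}, {"A", "B", "C", "D"})

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = random_tree(int(rng.integers(4, 12)), int(rng.integers(2**31)))
            back = pc.parse_newick(pc.write_newick(t))
            assert pc.rf_distance(t, back) == 0
            a = sorted(e.length for e in t.preorder_edge_iter() if e.length)
            b = sorted(e.length for e in back.preorder_edge_iter() if e.length)
            assert np.allclose(a, b, atol=1e-9)

    def test_support_as_percent_normalized(self):
        t = pc.parse_newick("((A,B)95,(C,D));")
        sup = split_supports(t)
        bp = Bipartition({"A", "B"}, {"A", "B", "C", "D"})
        assert sup[bp] == pytest.approx(0.95)

    def test_support_as_proportion_kept(self):
        t = pc.parse_newick("((A,B)0.87,(C,D));")
        sup = split_supports(t)
        assert list(sup.values())[0] == pytest.approx(0.87)

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            pc.parse_newick("((A,B,(C,D));")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pc.parse_newick("((A,B),(A,C));")


class TestBipartitions:
    def test_binary_unrooted_has_n_minus_3_splits(self):
        for n in (5, 8, 12):
            t = random_tree(n, seed=n)
            assert len(pc.bipartitions(t)) == n - 3

    def test_star_tree_has_none(self):
        assert pc.bipartitions(pc.parse_newick("(A,B,C,D,E);")) == set()

    def test_rooted_input_treated_as_unrooted(self):
        rooted = pc.parse_newick("((A,B),(C,D));")
        unrooted = pc.parse_newick("(A,B,(C,D));")
        assert pc.bipartitions(rooted) == pc.bipartitions(unrooted)

    def test_canonicalization_complement_equal(self):
        rng = np.random.default_rng(1)
        taxa = frozenset(f"t{i}" for i in range(12))
        for _ in range(1000):
            k = int(rng.integers(2, 11))
            side = frozenset(
                sorted(taxa)[i] for i in rng.choice(12, size=k, replace=False)
            )
            a = Bipartition(side, taxa)
            b = Bipartition(taxa - side, taxa)
            assert a == b and hash(a) == hash(b)


class TestRFDistance:
    def test_identical_trees(self):
        t = random_tree(9, seed=3)
        assert pc.rf_distance(t, t.clone(depth=1)) == 0

    def test_one_nni_gives_two(self):
        t = random_tree(5, seed=4)
        t2 = t.clone(depth=1)
        from phylocurate.simulate import random_nni

        random_nni(t2, np.random.default_rng(0))
        assert pc.rf_distance(t, t2) == 2

    def test_mismatched_taxa_rejected(self):
        a = pc.parse_newick("(A,B,(C,D));")
        b = pc.parse_newick("(A,B,(C,E));")
        with pytest.raises(ValueError, match="terminal sets differ"):
            pc.rf_distance(a, b)

    def test_against_dendropy_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            n = int(rng.integers(4, 9))
            s1 = pc.write_newick(random_tree(n, int(rng.integers(2**31))))
            s2 = pc.write_newick(random_tree(n, int(rng.integers(2**31))))
            ours = pc.rf_distance(pc.parse_newick(s1), pc.parse_newick(s2))
            tns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(data=s1, schema="newick", taxon_namespace=tns)
            b = dendropy.Tree.get(data=s2, schema="newick", taxon_namespace=tns)
            a.encode_bipartitions()
            b.encode_bipartitions()
            oracle = treecompare.symmetric_difference(a, b)
            assert ours == oracle


class TestNJTree:
    def test_additive_four_taxon_recovery(self):
        # additive distances on ((A,B),(C,D)) with internal branch 3
        d = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 3],
                [10, 11, 3, 0],
            ],
            float,
        )
        t = pc.nj_tree(d, ["A", "B", "C", "D"])
        assert Bipartition({"A", "B"}, {"A", "B", "C", "D"}) in pc.bipartitions(t)

    def test_three_taxa_three_point_solution(self):
        d = np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]], float)
        t = pc.nj_tree(d, ["A", "B", "C"])
        lengths = {
            l.taxon.label: l.edge.length for l in t.leaf_node_iter()
        }
        # a = (dAB + dAC - dBC)/2 etc.
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(5.0)

    def test_ultrametric_matches_nested_clusters(self):
        # hierarchy (((A,B),C),((D,E),F)) with ultrametric heights
        labels = list("ABCDEF")
        h = {
            frozenset("AB"): 1, frozenset("ABC"): 2,
            frozenset("DE"): 1, frozenset("DEF"): 2,
        }
        d = np.zeros((6, 6))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    continue
                for grp, height in sorted(h.items(), key=lambda kv: kv[1]):
                    if x in grp and y in grp:
                        d[i, j] = 2 * height
                        break
                else:
                    d[i, j] = 6
        t = pc.nj_tree(d, labels)
        splits = pc.bipartitions(t)
        taxa = frozenset(labels)
        assert Bipartition(frozenset("AB"), taxa) in splits
        assert Bipartition(frozenset("DE"), taxa) in splits
        assert Bipartition(frozenset("ABC"), taxa) in splits

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            pc.nj_tree(np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]]), "ABC")
        with pytest.raises(ValueError, match="negative"):
            pc.nj_tree(np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]]), "ABC")
        with pytest.raises(ValueError, match="symmetric"):
            pc.nj_tree(np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]]), "ABC")


class TestSplitSupportTable:
    def test_reference_against_itself_all_full(self):
        t = pc.parse_newick("((A,B)100,((C,D)100,E)100,F);")
        table = pc.split_support_table(t, [("self", t)])
        assert (table.table["self"] == 1.0).all()
        assert table.all_full_support.all()

    def test_absent_split_is_nan(self):
        ref = pc.parse_newick("((A,B),(C,D),E);")
        other = pc.parse_newick("((A,C),(B,D),E);")
        table = pc.split_support_table(ref, [("alt", other)])
        assert table.table["alt"].isna().all()

    def test_seventeen_analyses_make_seventeen_columns(self):
        from phylocurate.simulate import random_nni

        ref = random_tree(12, seed=8)
        rng = np.random.default_rng(9)
        analyses = []
        for i in range(17):
            t = ref.clone(depth=1)
            if i % 2:
                random_nni(t, rng)
            analyses.append((f"a{i:02d}", t))
        table = pc.split_support_table(ref, analyses)
        assert table.table.shape == (12 - 3, 17)

    def test_row_count_is_n_minus_3(self):
        ref = random_tree(10, seed=11)
        table = pc.split_support_table(ref, [("x", ref.clone(depth=1))])
        assert len(table.table) == 7

    def test_terminal_mismatch_rejected(self):
        ref = pc.parse_newick("((A,B),(C,D),E);")
        other = pc.parse_newick("((A,B),(C,F),E);")
        with pytest.raises(ValueError, match="mismatch"):
            pc.split_support_table(ref, [("bad", other)])

    def test_tsv_uses_na_marker(self, tmp_path):
        ref = pc.parse_newick("((A,B),(C,D),E);")
        other = pc.parse_newick("((A,C),(B,D),E);")
        table = pc.split_support_table(ref, [("alt", other)])
        out = tmp_path / "supports.tsv"
        table.to_tsv(out)
        assert "NA" in out.read_text()


def rogue_chains(n_trees=100):
    """Two chains identical except one terminal sits at different positions."""
    base = "((((A,B),(C,D)),((E,F),(G,H))),(I,J));"
    chain_a = [
        pc.parse_newick(base.replace("(A,B)", "((A,R),B)"))
        for _ in range(n_trees)
    ]
    chain_b = [
        pc.parse_newick(base.replace("(I,J)", "((I,R),J)"))
        for _ in range(n_trees)
    ]
    return chain_a, chain_b


class TestBipartitionFrequencies:
    def test_identical_trees_all_one(self):
        t = random_tree(8, seed=12)
        freqs = bipartition_frequencies([t.clone(depth=1) for _ in range(5)])
        assert set(freqs.values()) == {1.0}
        assert len(freqs) == 8 - 3

    def test_three_of_four(self):
        t1 = pc.parse_newick("((A,B),(C,D),E);")
        t2 = pc.parse_newick("((A,C),(B,D),E);")
        freqs = bipartition_frequencies([t1, t1, t1, t2])
        bp = Bipartition({"A", "B"}, terminal_labels(t1))
        assert freqs[bp] == pytest.approx(0.75)

    def test_absent_splits_never_appear(self):
        t1 = pc.parse_newick("((A,B),(C,D),E);")
        freqs = bipartition_frequencies([t1])
        assert all(0.0 < v <= 1.0 for v in freqs.values())


class TestMaxdiff:
    def test_identical_chains_zero(self):
        t = random_tree(8, seed=13)
        chain = [t.clone(depth=1) for _ in range(10)]
        assert pc.maxdiff(chain, chain) == 0.0

    def test_rogue_terminal_gives_one(self):
        a, b = rogue_chains()
        assert pc.maxdiff(a, b) == 1.0

    def test_pruning_the_rogue_restores_convergence(self):
        a, b = rogue_chains()
        assert pc.maxdiff(pc.prune_terminal(a, "R"), pc.prune_terminal(b, "R")) == 0.0

    def test_hand_computed_partial_disagreement(self):
        t1 = pc.parse_newick("((A,B),(C,D),E);")
        t2 = pc.parse_newick("((A,C),(B,D),E);")
        chain_a = [t1] * 6 + [t2] * 4
        chain_b = [t1] * 2 + [t2] * 8
        assert pc.maxdiff(chain_a, chain_b) == pytest.approx(0.4)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(14)
        base = random_tree(10, seed=15)
        from phylocurate.simulate import random_nni

        def chain(seed):
            r = np.random.default_rng(seed)
            out = []
            for _ in range(20):
                t = base.clone(depth=1)
                if r.random() < 0.5:
                    random_nni(t, r)
                out.append(t)
            return out

        a, b = chain(1), chain(2)
        d_ab, d_ba = pc.maxdiff(a, b), pc.maxdiff(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        assert pc.maxdiff(a, a) == 0.0

    def test_burnin_discard(self):
        t1 = pc.parse_newick("((A,B),(C,D),E);")
        t2 = pc.parse_newick("((A,C),(B,D),E);")
        # chains differ only in their first halves
        a = [t2] * 5 + [t1] * 5
        b = [t1] * 10
        assert pc.maxdiff(a, b, burnin_fraction=0.5) == 0.0
        assert pc.maxdiff(a, b) == 0.5


class TestPruneTerminal:
    def test_cherry_prune_leaves_no_internal_split(self):
        t = pc.parse_newick("((A,B),(C,D));")
        (out,) = pc.prune_terminal([t], "A")
        assert pc.bipartitions(out) == set()
        assert terminal_labels(out) == {"B", "C", "D"}

    def test_path_lengths_preserved(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            t = random_tree(8, int(rng.integers(2**31)))
            labels = sorted(terminal_labels(t))
            victim = labels[int(rng.integers(len(labels)))]
            keep = [l for l in labels if l != victim]
            pdm_before = _path_lengths(t, keep)
            (pruned,) = pc.prune_terminal([t], victim)
            pdm_after = _path_lengths(pruned, keep)
            for pair in pdm_before:
                assert pdm_after[pair] == pytest.approx(pdm_before[pair])

    def test_prune_commutes(self):
        t = random_tree(9, seed=17)
        ab = pc.prune_terminal(pc.prune_terminal([t.clone(depth=1)], "T001"), "T002")
        ba = pc.prune_terminal(pc.prune_terminal([t.clone(depth=1)], "T002"), "T001")
        assert pc.rf_distance(ab[0], ba[0]) == 0

    def test_absent_taxon_names_tree_index(self):
        t1 = pc.parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="tree 0"):
            pc.prune_terminal([t1], "Z")

    def test_tree_count_unchanged(self):
        t = pc.parse_newick("((A,B),(C,D),E);")
        assert len(pc.prune_terminal([t.clone(depth=1)] * 7, "E")) == 7


def _path_lengths(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in labels}
    out = {}
    for i, x in enumerate(labels):
        for y in labels[i + 1 :]:
            out[(x, y)] = pdm.patristic_distance(taxa[x], taxa[y])
    return out
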