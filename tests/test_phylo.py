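import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trcensus import phylo
from trcensus import synthetic_data as sd
from trcensus.box_motifs import MSA
from trcensus.errors import ValidationError
from trcensus.tree import TreeNode, parse_newick


def toy_block_msa():
    """4 rows, 10 columns; column 3 conserved but isolated, columns 6-7
    conserved as an adjacent pair, all other columns fully variable."""
    letters = "ACDE"
    rows = []
    for i in range(4):
        u = letters[i]
        rows.append(u * 3 + "G" + u * 2 + "GG" + u * 2)
    return MSA([f"r{i}" for i in range(4)], rows)


class TestSelectBlocks:
    def test_isolated_column_dropped_pair_kept(self):
        selection = phylo.select_blocks(toy_block_msa())
        assert selection.kept_columns == [6, 7]
        assert min(end - start + 1
                   for start, end in selection.runs()) == 2

    def test_adjacent_pair_boundary(self):
        msa = MSA(["a", "b", "c"], ["AGGC", "CGGD", "DGGE"])
        selection = phylo.select_blocks(msa)
        assert selection.kept_columns == [1, 2]

    def test_fully_invariant_keeps_all(self):
        msa = MSA(["a", "b"], ["MKVA", "MKVA"])
        assert phylo.select_blocks(msa).kept_columns == [0, 1, 2, 3]

    def test_row_order_invariance(self):
        msa = toy_block_msa()
        reordered = MSA(msa.member_ids[::-1], msa.rows[::-1])
        assert phylo.select_blocks(msa).kept_columns == \
            phylo.select_blocks(reordered).kept_columns

    def test_no_run_shorter_than_minimum(self):
        msa = toy_block_msa()
        for min_len in (1, 2, 3):
            params = phylo.BlockParameters(min_block_length=min_len)
            selection = phylo.select_blocks(msa, params)
            for start, end in selection.runs():
                assert end - start + 1 >= min_len

    def test_gaps_disallowed_drops_gap_columns(self):
        msa = MSA(["a", "b", "c"], ["GG-G", "GGGG", "GGGG"])
        strict = phylo.select_blocks(
            msa, phylo.BlockParameters(gaps_allowed=False))
        assert 2 not in strict.kept_columns
        permissive = phylo.select_blocks(msa)
        assert 2 in permissive.kept_columns


class TestProteinDistance:
    def test_identical_rows(self):
        assert phylo.protein_distance("MKVA", "MKVA", range(4)) == 0.0

    def test_closed_form_ten_percent(self):
        row_a = "A" * 10
        row_b = "C" + "A" * 9
        d = phylo.protein_distance(row_a, row_b, range(10))
        assert d == pytest.approx(-math.log(0.9))

    def test_saturation_capped_with_warning(self, caplog):
        row_a = "A" * 100
        row_b = "C" * 99 + "A"
        with caplog.at_level(logging.WARNING):
            d = phylo.protein_distance(row_a, row_b, range(100))
        assert d == pytest.approx(-math.log(1 - phylo.SATURATION_P))
        assert any("saturated" in r.message for r in caplog.records)

    def test_gap_columns_excluded(self):
        d = phylo.protein_distance("MK-A", "MKC-", range(4))
        assert d == 0.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValidationError):
            phylo.protein_distance("--", "AB", range(2))


from tests_helpers_phylo import (leaf_distances, matrix_from_tree,  # noqa: E402
                                 random_additive_tree)


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # ((A:1,B:2):1.5,(C:3,D:4)) as an unrooted additive matrix
        ids = ["A", "B", "C", "D"]
        m = np.array([
            [0.0, 3.0, 5.5, 6.5],
            [3.0, 0.0, 6.5, 7.5],
            [5.5, 6.5, 0.0, 7.0],
            [6.5, 7.5, 7.0, 0.0]])
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, m))
        splits = phylo._bipartitions(tree)
        assert splits == {frozenset({"A", "B"})}
        recovered = leaf_distances(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                assert recovered[frozenset((ids[i], ids[j]))] == \
                    pytest.approx(m[i, j])

    def test_four_taxon_brute_force_topology(self):
        # oracle: the additive matrix fits exactly one unrooted topology
        ids = ["A", "B", "C", "D"]
        m = np.array([
            [0.0, 3.0, 5.5, 6.5],
            [3.0, 0.0, 6.5, 7.5],
            [5.5, 6.5, 0.0, 7.0],
            [6.5, 7.5, 7.0, 0.0]])
        # four-point condition: the cherry pairing minimizes the sum
        sums = {("A", "B"): m[0, 1] + m[2, 3],
                ("A", "C"): m[0, 2] + m[1, 3],
                ("A", "D"): m[0, 3] + m[1, 2]}
        assert min(sums, key=sums.get) == ("A", "B")

    def test_three_leaves_closed_form(self):
        ids = ["A", "B", "C"]
        m = np.array([[0.0, 2.0, 3.0],
                      [2.0, 0.0, 4.0],
                      [3.0, 4.0, 0.0]])
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, m))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((2 + 3 - 4) / 2)
        assert lengths["B"] == pytest.approx((2 + 4 - 3) / 2)
        assert lengths["C"] == pytest.approx((3 + 4 - 2) / 2)

    @given(st.integers(0, 10_000), st.integers(4, 12))
    @settings(max_examples=30, deadline=None)
    def test_recovers_random_additive_trees(self, seed, n_leaves):
        rng = np.random.default_rng(seed)
        truth = random_additive_tree(rng, n_leaves)
        dm = matrix_from_tree(truth)
        rebuilt = phylo.nj_tree(dm)
        assert phylo.robinson_foulds(truth, rebuilt) == 0
        truth_d = leaf_distances(truth)
        rebuilt_d = leaf_distances(rebuilt)
        for pair, value in truth_d.items():
            assert rebuilt_d[pair] == pytest.approx(value, abs=1e-9)

    def test_ultrametric_matches_upgma(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            # build an ultrametric (clock-like) tree, then compare
            n = 6
            heights = sorted(rng.uniform(1, 10, size=n - 1))
            clusters = [({f"L{i}"}, 0.0, TreeNode(f"L{i}"))
                        for i in range(n)]
            order = list(range(n))
            rng.shuffle(order)
            work = [clusters[i] for i in order]
            for h in heights:
                (sa, _ha, na), (sb, _hb, nb) = work[0], work[1]
                parent = TreeNode()
                na.length = h - _ha
                nb.length = h - _hb
                parent.add_child(na)
                parent.add_child(nb)
                work = work[2:] + [(sa | sb, h, parent)]
            truth = work[0][2]
            dm = matrix_from_tree(truth)
            nj = phylo.nj_tree(dm)
            upgma = _upgma(dm)
            assert phylo.robinson_foulds(nj, upgma) == 0

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValidationError):
            phylo.nj_tree(phylo.DistanceMatrix(
                ["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))


def _upgma(dm):
    """Tiny independent UPGMA (average linkage) oracle."""
    clusters = {i: ({dm.ids[i]}, TreeNode(dm.ids[i])) for i in
                range(len(dm.ids))}
    d = {frozenset((i, j)): dm.matrix[i, j]
         for i in clusters for j in clusters if i < j}
    nxt = len(dm.ids)
    while len(clusters) > 1:
        (i, j) = min(d, key=lambda k: (d[k], sorted(k)))
        si, ni = clusters.pop(i)
        sj, nj = clusters.pop(j)
        parent = TreeNode()
        parent.add_child(ni)
        parent.add_child(nj)
        for k in list(clusters):
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((nxt, k))] = \
                (dik * len(si) + djk * len(sj)) / (len(si) + len(sj))
        d.pop(frozenset((i, j)))
        clusters[nxt] = (si | sj, parent)
        nxt += 1
    return clusters.popitem()[1][1]


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        a = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = parse_newick("((C:2,D:2):1,(A:1,B:3):1);")
        assert phylo.robinson_foulds(a, a) == 0
        assert phylo.robinson_foulds(a, b) == 0

    def test_alternative_quartets_distance_two(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert phylo.robinson_foulds(a, b) == 2

    def test_symmetry(self):
        a = parse_newick("(((A,B),C),(D,E));")
        b = parse_newick("(((A,C),B),(D,E));")
        assert phylo.robinson_foulds(a, b) == phylo.robinson_foulds(b, a)

    def test_triangle_inequality_spot_check(self):
        a = parse_newick("(((A,B),C),(D,E));")
        b = parse_newick("(((A,C),B),(D,E));")
        c = parse_newick("(((D,B),C),(A,E));")
        assert phylo.robinson_foulds(a, c) <= \
            phylo.robinson_foulds(a, b) + phylo.robinson_foulds(b, c)

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            phylo.robinson_foulds(parse_newick("((A,B),(C,D));"),
                                  parse_newick("((A,B),(C,E));"))


class TestRootWithOutgroup:
    def test_root_on_pendant_edge(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:2):1);")
        rooted = phylo.root_with_outgroup(tree, ["D"])
        top_level = {frozenset(c.leaf_names()) for c in rooted.children}
        assert frozenset({"D"}) in top_level
        d_child = next(c for c in rooted.children if c.leaf_names() == ["D"])
        assert d_child.length == pytest.approx(1.0)

    def test_outgroup_clade(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:2):1,E:1);")
        rooted = phylo.root_with_outgroup(tree, ["C", "D"])
        top_level = {frozenset(c.leaf_names()) for c in rooted.children}
        assert frozenset({"C", "D"}) in top_level

    def test_all_leaves_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError):
            phylo.root_with_outgroup(tree, ["A", "B", "C", "D"])

    def test_non_monophyletic_lists_violators(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValidationError, match="intruding"):
            phylo.root_with_outgroup(tree, ["A", "C"])

    def test_rooting_preserves_bipartitions(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        rooted = phylo.root_with_outgroup(tree, ["D", "E"])
        assert phylo.robinson_foulds(tree, rooted) == 0

    def test_synthetic_classes_monophyletic(self, seed_panel):
        # at mutation 0 the per-class divergence model makes every class
        # clade exact, so outgroup rooting succeeds on family trees
        ds = sd.make_dataset(9, {"TR1": 1}, n_background=0,
                             mutation_rate=0.0, seed=31)
        from trcensus import box_motifs as bm
        rng = np.random.default_rng(0)
        anchor = sd.make_protein("TR1", 0.0, rng, "anchor")
        members = [p for g in ds.genomes for p in g.proteins]
        msa = bm.align_group(members, anchor)
        msa = MSA(msa.member_ids[1:], msa.rows[1:])
        selection = phylo.select_blocks(msa)
        tree = phylo.nj_tree(phylo.distance_matrix(msa, selection))
        class_of = {p.protein_id: g.taxon_class
                    for g in ds.genomes for p in g.proteins}
        outgroup = [p for p, c in class_of.items()
                    if c == sd.OUTGROUP_CLASS]
        rooted = phylo.root_with_outgroup(tree, outgroup)
        for cls in sd.INGROUP_CLASSES:
            members_of_class = frozenset(
                p for p, c in class_of.items() if c == cls)
            assert members_of_class in phylo._bipartitions(rooted) or \
                any(frozenset(child.leaf_names()) == members_of_class
                    for node in rooted.preorder()
                    for child in node.children)


class TestFlagIncongruentLeaves:
    def test_planted_transfer_flagged_exactly(self):
        tree, class_map, transferred = sd.hgt_fixture()
        flags = phylo.flag_incongruent_leaves(tree, class_map)
        assert [f[0] for f in flags] == [transferred]
        leaf, own, surrounding = flags[0]
        assert own == "Deltaproteobacteria_like"
        assert surrounding == "Clostridia_like"

    def test_class_pure_tree_no_flags(self):
        ds = sd.make_dataset(9, {"TR1": 1}, seed=1)
        class_map = ds.class_map()
        assert phylo.flag_incongruent_leaves(
            ds.reference_tree, class_map) == []

    def test_min_clade_size_exceeds_tree(self, caplog):
        tree, class_map, _ = sd.hgt_fixture()
        with caplog.at_level(logging.WARNING):
            flags = phylo.flag_incongruent_leaves(tree, class_map,
                                                  min_clade_size=50)
        assert flags == []
        assert any("exceeds" in r.message for r in caplog.records)

    def test_unlabeled_leaf_rejected(self):
        tree, class_map, _ = sd.hgt_fixture()
        class_map = dict(class_map)
        class_map.pop("c1")
        with pytest.raises(ValidationError):
            phylo.flag_incongruent_leaves(tree, class_map)


class TestDetectDuplications:
    def test_cherry_duplication(self):
        tree = parse_newick("((p1:1,p2:1):1,(p3:1,p4:1):1);")
        organism_of = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g3"}
        reports = phylo.detect_duplications(tree, organism_of)
        assert len(reports) == 1
        assert reports[0].organism_id == "g1"
        assert reports[0].mrca_leaf_ids == ["p1", "p2"]

    def test_single_copy_genomes_empty(self):
        tree = parse_newick("((p1,p2),(p3,p4));")
        organism_of = {f"p{i}": f"g{i}" for i in range(1, 5)}
        assert phylo.detect_duplications(tree, organism_of) == []

    def test_split_family_duplication_mrca(self):
        tree = parse_newick("((p1:1,x1:1):1,(p2:1,x2:1):1);")
        organism_of = {"p1": "g1", "p2": "g1", "x1": "g2", "x2": "g3"}
        reports = phylo.detect_duplications(tree, organism_of)
        assert reports[0].mrca_leaf_ids == ["p1", "p2", "x1", "x2"]


def test_prune_to_suppresses_unary_nodes():
    tree = parse_newick("(((A:1,B:1):2,C:1):1,D:1);")
    pruned = phylo.prune_to(tree, ["A", "C", "D"])
    assert sorted(pruned.leaf_names()) == ["A", "C", "D"]
    a = pruned.find("A")
    assert a.length == pytest.approx(3.0)  # 1 + suppressed 2


def test_bootstrap_support_full_confidence_on_clean_signal():
    msa = MSA(["a", "b", "c", "d"],
              ["AAAAAAAACC", "AAAAAAAADD", "CCCCCCCCEE", "CCCCCCCCFF"])
    selection = phylo.BlockSelection(list(range(10)),
                                     phylo.BlockParameters())
    support = phylo.bootstrap_support(msa, selection, n_replicates=20,
                                      seed=1)
    ab = frozenset({"a", "b"})
    assert support.get(ab, 0.0) > 0.9
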