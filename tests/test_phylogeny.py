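import dendropy
import numpy as np
import pytest

from barcode_eval.data_model import LocusAlignment
from barcode_eval.distances import DistanceMatrix, DistanceModelParams
from barcode_eval.phylogeny import (
    MonophylyConfig,
    bootstrap_support,
    fitch_length,
    monophyly_percent,
    neighbor_joining,
    parsimony_search,
    read_newick,
    reference_clade_congruence,
    split_set,
    write_newick,
)

from conftest import enumerate_unrooted_topologies, make_label, random_additive_matrix


def _dm(ids, d):
    return DistanceMatrix(ids, np.asarray(d, dtype=float), DistanceModelParams())


def _tree(nwk: str) -> dendropy.Tree:
    return read_newick(nwk, from_path=False)


def path_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        # d(ab)=3, d(ac)=5, d(bc)=6 -> la=1, lb=2, lc=4
        m = _dm(["a", "b", "c"], [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        tree = neighbor_joining(m)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) with internal edge 1
        d = [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ]
        tree = neighbor_joining(_dm(list("abcd"), d))
        assert split_set(tree) == {frozenset({"c", "d"})}
        pd_ = path_distances(tree)
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                assert pd_[(x, y)] == pytest.approx(d[i][j], abs=1e-9)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(25):
            taxa, D, true_splits = random_additive_matrix(8, rng)
            tree = neighbor_joining(_dm(taxa, D))
            assert split_set(tree) == true_splits
            pd_ = path_distances(tree)
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    assert abs(pd_[(x, y)] - D[i, j]) < 1e-9

    def test_undefined_entries_are_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(_dm(["a", "b", "c"], d))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(_dm(["a", "b"], [[0, 1], [1, 0]]))


class TestBootstrap:
    ALN = LocusAlignment(
        "x",
        [
            ("a1", "AAAAAAAACC"),
            ("a2", "AAAAAAAACC"),
            ("b1", "TTTTTTTTGG"),
            ("b2", "TTTTTTTTGG"),
        ],
    )

    def test_separating_bipartition_gets_full_support(self):
        tree = bootstrap_support(self.ALN, DistanceModelParams(model="p"),
                                 n_replicates=100, seed=7)
        supports = {
            frozenset(l.taxon.label for l in node.leaf_iter()): float(node.label)
            for node in tree.preorder_internal_node_iter()
            if node.label is not None
        }
        key = frozenset({"a1", "a2"}) if frozenset({"a1", "a2"}) in supports else frozenset({"b1", "b2"})
        assert supports[key] == 100.0

    def test_supports_within_range_and_deterministic(self, rng):
        chars = np.array(list("ACGT"))
        members = [(f"s{i}", "".join(rng.choice(chars, size=60))) for i in range(6)]
        aln = LocusAlignment("x", members)
        t1 = bootstrap_support(aln, DistanceModelParams(model="p"), 50, seed=3)
        t2 = bootstrap_support(aln, DistanceModelParams(model="p"), 50, seed=3)
        assert write_newick(t1) == write_newick(t2)
        for node in t1.preorder_internal_node_iter():
            if node.label is not None:
                assert 0.0 <= float(node.label) <= 100.0


class TestFitch:
    def test_identical_sequences_have_zero_length(self):
        aln = LocusAlignment("x", [(s, "ACGTT") for s in "abcd"])
        assert fitch_length(_tree("((a,b),(c,d));"), aln) == 0

    def test_four_taxon_pattern_enumeration(self):
        aln = LocusAlignment("x", [("1", "A"), ("2", "A"), ("3", "C"), ("4", "C")])
        assert fitch_length(_tree("((1,2),(3,4));"), aln) == 1
        assert fitch_length(_tree("((1,3),(2,4));"), aln) == 2
        assert fitch_length(_tree("((1,4),(2,3));"), aln) == 2

    def test_gap_and_missing_are_fully_ambiguous(self):
        aln = LocusAlignment("x", [("1", "A-"), ("2", "AN"), ("3", "C?"), ("4", "CT")])
        assert fitch_length(_tree("((1,2),(3,4));"), aln) == 1

    def test_invariant_under_rerooting(self, rng):
        chars = np.array(list("ACGT-N"))
        members = [(f"s{i}", "".join(rng.choice(chars, size=40))) for i in range(7)]
        aln = LocusAlignment("x", members)
        base = _tree("((s0,s1),(s2,(s3,s4)),(s5,s6));")
        L0 = fitch_length(base, aln)
        for node in list(base.preorder_internal_node_iter())[1:3]:
            t = base.clone(depth=1)
            t.reroot_at_edge(t.seed_node.child_nodes()[0].edge)
            assert fitch_length(t, aln) == L0

    def test_agrees_with_dendropy_fitch(self, rng):
        from dendropy.model import parsimony as dparsimony

        chars = np.array(list("ACGT"))
        for rep in range(10):
            n = int(rng.integers(4, 9))
            members = [(f"s{i}", "".join(rng.choice(chars, size=30))) for i in range(n)]
            aln = LocusAlignment("x", members)
            fasta = "".join(f">{sid}\n{seq}\n" for sid, seq in members)
            cm = dendropy.DnaCharacterMatrix.get(data=fasta, schema="fasta")
            nwk = enumerate_unrooted_topologies([f"s{i}" for i in range(n)])[
                int(rng.integers(0, 3))
            ]
            dtree = dendropy.Tree.get(data=nwk, schema="newick",
                                      taxon_namespace=cm.taxon_namespace)
            expected = dparsimony.fitch_down_pass(
                dtree.postorder_node_iter(),
                taxon_state_sets_map=cm.taxon_state_sets_map(gaps_as_missing=True),
            )
            assert fitch_length(_tree(nwk), aln) == expected

    def test_leaf_without_sequence_is_an_error(self):
        aln = LocusAlignment("x", [("1", "A"), ("2", "A"), ("3", "C")])
        with pytest.raises(ValueError, match="4"):
            fitch_length(_tree("((1,2),(3,4));"), aln)


class TestParsimonySearch:
    def _random_alignment(self, taxa, rng, L=40):
        chars = np.array(list("ACGT"))
        return LocusAlignment(
            "x", [(t, "".join(rng.choice(chars, size=L))) for t in taxa]
        )

    def test_already_optimal_four_taxon_start_unchanged(self):
        aln = LocusAlignment("x", [("1", "AA"), ("2", "AA"), ("3", "CC"), ("4", "CC")])
        start = _tree("((1,2),(3,4));")
        tree, L = parsimony_search(aln, start)
        assert L == 2
        assert split_set(tree) == {frozenset({"3", "4"})}

    def test_reaches_exhaustive_optimum_on_six_taxa(self, rng):
        from conftest import simulated_alignment_on_random_tree

        taxa = [f"s{i}" for i in range(6)]
        topologies = enumerate_unrooted_topologies(taxa)
        assert len(topologies) == 105
        for rep in range(5):
            aln = simulated_alignment_on_random_tree(taxa, rng, L=200)
            best = min(fitch_length(_tree(t), aln) for t in topologies)
            scrambled = _tree(topologies[int(rng.integers(0, 105))])
            _, L = parsimony_search(aln, scrambled)
            assert L == best

    def test_length_never_exceeds_start(self, rng):
        taxa = [f"s{i}" for i in range(7)]
        aln = self._random_alignment(taxa, rng)
        start = _tree("((s0,s1),(s2,s3),(s4,(s5,s6)));")
        L_start = fitch_length(start, aln)
        _, L = parsimony_search(aln, start)
        assert L <= L_start


class TestMonophyly:
    LABELS = {
        "A1": make_label("A", "gA", "fA"),
        "A2": make_label("A", "gA", "fA"),
        "B1": make_label("B", "gB", "fB"),
        "B2": make_label("B", "gB", "fB"),
    }

    def test_clean_supported_clades_score_100(self):
        tree = _tree("((A1:1,A2:1)100:1,(B1:1,B2:1)100:1);")
        rep = monophyly_percent(tree, self.LABELS, MonophylyConfig(rank="species"))
        assert rep.percent == 100.0

    def test_interleaved_species_score_zero(self):
        tree = _tree("((A1:1,B1:1)90:1,(A2:1,B2:1)90:1);")
        rep = monophyly_percent(tree, self.LABELS, MonophylyConfig(rank="species"))
        assert rep.percent == 0.0
        assert set(rep.per_taxon.values()) == {"non_monophyletic"}

    def test_low_support_counts_as_unsupported(self):
        tree = _tree("((A1:1,A2:1)65:1,(B1:1,B2:1)80:1);")
        rep = monophyly_percent(
            tree, self.LABELS, MonophylyConfig(rank="species", support_min=70)
        )
        assert rep.per_taxon["A"] == "monophyletic_unsupported"
        assert rep.per_taxon["B"] == "monophyletic_supported"
        assert rep.percent == 50.0

    def test_support_exactly_at_threshold_is_not_enough(self):
        tree = _tree("((A1:1,A2:1)70:1,(B1:1,B2:1)71:1);")
        rep = monophyly_percent(tree, self.LABELS, MonophylyConfig(rank="species"))
        assert rep.per_taxon["A"] == "monophyletic_unsupported"
        assert rep.per_taxon["B"] == "monophyletic_supported"

    def test_singletons_excluded_from_percentage(self):
        labels = dict(self.LABELS)
        labels["C1"] = make_label("C", "gC", "fC")
        tree = _tree("((A1,A2)100,(B1,B2)100,C1);")
        rep = monophyly_percent(tree, labels, MonophylyConfig(rank="species"))
        assert rep.per_taxon["C"] == "excluded_singleton"
        assert rep.n_assessable == 2
        assert rep.percent == 100.0

    def test_rooting_independent(self, rng):
        nwk = "((A1:1,B1:1)40:1,((A2:1,B2:1)55:1,(C1:1,C2:1)90:2)80:1,(D1:1,D2:1)85:1);"
        labels = {
            sid: make_label(sid[0], f"g{sid[0]}", f"f{sid[0]}")
            for sid in ("A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2")
        }
        base = _tree(nwk)
        ref = monophyly_percent(base, labels, MonophylyConfig(rank="species")).per_taxon
        edges = [e for e in _tree(nwk).preorder_edge_iter() if e.head_node.parent_node]
        for k in range(5):
            t = _tree(nwk)
            edges_t = [e for e in t.preorder_edge_iter() if e.head_node.parent_node]
            t.reroot_at_edge(edges_t[k % len(edges_t)])
            got = monophyly_percent(t, labels, MonophylyConfig(rank="species")).per_taxon
            assert got == ref

    def test_unlabeled_leaf_is_an_error(self):
        tree = _tree("((A1,A2),(B1,B2));")
        labels = dict(self.LABELS)
        del labels["B2"]
        with pytest.raises(ValueError, match="B2"):
            monophyly_percent(tree, labels, MonophylyConfig(rank="species"))

    def test_genus_rank_uses_genus_labels(self):
        labels = {
            "A1": make_label("A", "gX", "fX"),
            "A2": make_label("A", "gX", "fX"),
            "B1": make_label("B", "gX", "fX"),
            "B2": make_label("B", "gX", "fX"),
        }
        tree = _tree("((A1,B1)99,(A2,B2)99);")
        rep = monophyly_percent(
            tree, labels, MonophylyConfig(rank="genus", require_support=False)
        )
        # the single genus covers all leaves -> trivially monophyletic
        assert rep.percent == 100.0


class TestReferenceCladeCongruence:
    LABELS = {
        "x1": make_label("s1", "g1", "f1", order="Laurales"),
        "x2": make_label("s2", "g2", "f2", order="Laurales"),
        "y1": make_label("s3", "g3", "f3", order="Magnoliales"),
        "y2": make_label("s4", "g4", "f4", order="Magnoliales"),
        "z1": make_label("s5", "g5", "f5", order="Myrtales"),
        "z2": make_label("s6", "g6", "f6", order="Myrtales"),
    }

    def test_single_monophyletic_order_recovered(self):
        tree = _tree("((x1,x2),(y1,y2),(z1,z2));")
        out = reference_clade_congruence(tree, self.LABELS, {"Laurales": ["Laurales"]})
        assert out == {"Laurales": "recovered"}

    def test_interdigitated_orders_not_recovered(self):
        # Laurales and Magnoliales interleave with Myrtales between them
        tree = _tree("((x1,y1),(x2,z1),(y2,z2));")
        out = reference_clade_congruence(
            tree, self.LABELS, {"Magnoliids": ["Laurales", "Magnoliales"]}
        )
        assert out == {"Magnoliids": "not_recovered"}

    def test_all_orders_group_always_recovered(self):
        tree = _tree("((x1,y1),(x2,z1),(y2,z2));")
        out = reference_clade_congruence(
            tree, self.LABELS, {"All": ["Laurales", "Magnoliales", "Myrtales"]}
        )
        assert out == {"All": "recovered"}

    def test_group_with_absent_order_is_skipped(self):
        tree = _tree("((x1,x2),(y1,y2),(z1,z2));")
        out = reference_clade_congruence(
            tree, self.LABELS, {"Ghost": ["Rosales"], "Ok": ["Myrtales"]}
        )
        assert out == {"Ok": "recovered"}


class TestNewickIO:
    def test_round_trip_preserves_labels_lengths_and_support(self):
        nwk = "((Sp01_01-1:0.1,Sp01_01-2:0.2)87:0.05,(B1:0.3,B2:0.4)92:0.06);"
        tree = read_newick(nwk, from_path=False)
        text = write_newick(tree)
        tree2 = read_newick(text, from_path=False)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {
            l.taxon.label for l in tree2.leaf_node_iter()
        }
        assert split_set(tree) == split_set(tree2)
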