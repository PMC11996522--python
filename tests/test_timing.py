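"""Duplication dating: LCA mapping, consensus rule, classification."""

import numpy as np
import pytest

import apes
from conftest import make_tdec_table


class TestLcaMapping:
    def test_textbook_root_duplication(self):
        sp = apes.tree_from_string("(A:10,B:10);")
        gt = apes.tree_from_string(
            "((A_g1:10,B_g2:10):5,(A_g3:10,B_g4:10):5);"
        )
        pairs = apes.lca_map_duplications(gt, sp)
        assert len(pairs) == 4  # all cross-child leaf pairs
        node = pairs[0][1]
        assert node.species_set == frozenset({"A", "B"})
        assert node.age == pytest.approx(10.0)
        assert node.support == 1.0  # both species retain both copies

    def test_congruent_tree_no_duplications(self):
        sp = apes.tree_from_string("((A:5,B:5):5,C:10);")
        gt = apes.tree_from_string("((A_g1:5,B_g2:5):5,C_g3:10);")
        assert apes.lca_map_duplications(gt, sp) == []

    def test_partial_retention_lowers_support(self):
        sp = apes.tree_from_string("((A:5,B:5):5,C:10);")
        # duplication before the A-B split; B lost the second copy
        gt = apes.tree_from_string(
            "(((A_g1:5,B_g2:5):2,A_g3:7):3,C_g4:10);"
        )
        pairs = apes.lca_map_duplications(gt, sp)
        dup_nodes = {p[1] for p in pairs}
        assert len(dup_nodes) == 1
        node = dup_nodes.pop()
        assert node.species_set == frozenset({"A", "B"})
        assert node.support == pytest.approx(0.5)  # only A retains both

    def test_unknown_species_rejected(self):
        sp = apes.tree_from_string("(A:10,B:10);")
        gt = apes.tree_from_string("((A_g1:10,Z_g2:10):5,A_g3:15);")
        with pytest.raises(apes.ValidationError):
            apes.lca_map_duplications(gt, sp)

    def test_planted_duplication_mapped_to_planted_clade(
            self, planted_dataset):
        truth = planted_dataset.truth[0]
        og = truth.orthogroups[0]
        pairs = apes.lca_map_duplications(planted_dataset.gene_trees[og],
                                          planted_dataset.species_tree)
        assert pairs
        node = pairs[0][1]
        # LCA mapping places the duplication at the crown of the clade
        # that inherited it
        assert node.species_set == frozenset(truth.species_with_copy)
        assert node.support == 1.0


class TestBestSupportedNode:
    def _node(self, age, support):
        return apes.DuplicationNode(species_set=frozenset({"A"}), age=age,
                                    method="gene_tree", support=support)

    def test_support_gate_before_age(self):
        pairs = [(("x", "y"), self._node(80, 0.6)),
                 (("x", "z"), self._node(95, 0.3))]
        assert apes.best_supported_node(pairs).age == 80

    def test_fallback_to_oldest(self):
        pairs = [(("x", "y"), self._node(40, 0.2)),
                 (("x", "z"), self._node(60, 0.1))]
        assert apes.best_supported_node(pairs).age == 60

    def test_matches_two_stage_argmax(self, rng):
        for _ in range(50):
            pairs = [((f"x{i}", f"y{i}"),
                      self._node(float(rng.uniform(0, 100)),
                                 float(rng.uniform(0, 1))))
                     for i in range(int(rng.integers(1, 8)))]
            got = apes.best_supported_node(pairs)
            nodes = [n for _, n in pairs]
            well = [n for n in nodes if n.support >= 0.5]
            brute = max(well or nodes, key=lambda n: n.age)
            assert got.age == brute.age


class TestMultiCopyMrca:
    def test_only_focal_species_terminal_node(self):
        sp_tree = apes.tree_from_string("((A:10,B:10):10,C:20);")
        tables = {
            "A": make_tdec_table("A", {"chr1": ["x", "y", "z", "q",
                                                "x", "y", "z", "r"]}),
            "B": make_tdec_table("B", {"chr1": ["x", "y", "z", "q", "r"]}),
            "C": make_tdec_table("C", {"chr1": ["x", "y", "z", "q", "r"]}),
        }
        ev = apes.find_within_genome_duplications(
            [apes.SyntenyBlock(kind="micro", species_a="A", species_b="A",
                               chrom_a="chr1", chrom_b="chr1",
                               pairs=((0, 4), (1, 5), (2, 6)), orientation=1)],
            tables["A"],
        )[0]
        node = apes.multi_copy_mrca(ev, tables, sp_tree)
        assert node.species_set == frozenset({"A"})
        assert node.age == 0.0

    def test_two_sisters_map_to_ancestor(self):
        sp_tree = apes.tree_from_string("((A:10,B:10):10,C:20);")
        dup = ["x", "y", "z", "q", "x", "y", "z", "r"]
        tables = {
            "A": make_tdec_table("A", {"chr1": dup}),
            "B": make_tdec_table("B", {"chr1": dup}),
            "C": make_tdec_table("C", {"chr1": ["x", "y", "z", "q", "r"]}),
        }
        ev = apes.find_within_genome_duplications(
            [apes.SyntenyBlock(kind="micro", species_a="A", species_b="A",
                               chrom_a="chr1", chrom_b="chr1",
                               pairs=((0, 4), (1, 5), (2, 6)), orientation=1)],
            tables["A"],
        )[0]
        node = apes.multi_copy_mrca(ev, tables, sp_tree)
        assert node.species_set == frozenset({"A", "B"})
        assert node.age == pytest.approx(10.0)

    def test_planted_clade_recovered(self, planted_dataset, planted_condensed):
        truth = planted_dataset.truth[0]
        focal = truth.species_with_copy[0]
        ct = planted_condensed[focal]
        _, micro_self = apes.compare_genomes(ct, ct)
        ev = apes.find_within_genome_duplications(micro_self, ct)[0]
        node = apes.multi_copy_mrca(ev, planted_condensed,
                                    planted_dataset.species_tree)
        assert node.species_set == frozenset(truth.species_with_copy)


class TestConsensus:
    def _node(self, species, age, method="gene_tree", support=None):
        return apes.DuplicationNode(species_set=frozenset(species), age=age,
                                    method=method, support=support)

    def test_midpoint_rule(self):
        sp = apes.tree_from_string("((A:50,B:50):30,C:80);")
        node = self._node({"A", "B"}, 50.0)
        consensus, t_dup = apes.consensus_time(node, None, sp)
        assert t_dup == pytest.approx(65.0)

    def test_older_node_wins(self):
        sp = apes.tree_from_string("((A:50,B:50):30,C:80);")
        younger = self._node({"A", "B"}, 50.0)
        older = self._node({"A", "B", "C"}, 80.0)
        consensus, t_dup = apes.consensus_time(younger, older, sp)
        assert consensus.age == 80.0
        assert consensus.age >= younger.age and consensus.age >= older.age

    def test_root_has_no_parent(self):
        sp = apes.tree_from_string("((A:50,B:50):30,C:80);")
        root = self._node({"A", "B", "C"}, 80.0)
        _, t_dup = apes.consensus_time(root, None, sp)
        assert t_dup == pytest.approx(80.0)

    def test_both_missing_rejected(self):
        sp = apes.tree_from_string("(A:10,B:10);")
        with pytest.raises(apes.ValidationError):
            apes.consensus_time(None, None, sp)

    def test_midpoint_within_branch_interval(self, rng):
        for trial in range(20):
            t = apes.random_species_tree(6, 100.0, rng)
            clades = {}
            for node in t.postorder_node_iter():
                leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
                clades[leaves] = (node.age,
                                  node.parent_node.age if node.parent_node
                                  else None)
            for clade, (age, p_age) in clades.items():
                node = self._node(clade, age)
                _, t_dup = apes.consensus_time(node, None, t)
                hi = p_age if p_age is not None else age
                assert age <= t_dup <= hi


class TestClassification:
    def _timed(self, t_dup):
        ev = apes.DuplicationEvent(
            event_id="e", species="F",
            copy1=apes.Region("F", "chr1", ("a",), (0,), 1, 1000),
            copy2=apes.Region("F", "chr1", ("b",), (5,), 9001, 10000),
            orthogroup_sequence=("x", "y", "z"),
        )
        node = apes.DuplicationNode(frozenset({"F"}), t_dup, "consensus")
        return apes.TimedEvent(event=ev, node_gene_tree=None, node_mrca=None,
                               consensus_node=node, t_dup=t_dup)

    @pytest.fixture
    def times(self):
        return apes.TimeTable(pair_times={frozenset({"F", "R"}): 87.2})

    def test_young_duplication_after_speciation(self, times):
        assert apes.classify_event(self._timed(30.0), "F", "R", times) == \
            "after_speciation"

    def test_old_duplication_before_speciation(self, times):
        assert apes.classify_event(self._timed(100.0), "F", "R", times) == \
            "before_speciation"

    def test_equality_is_before(self, times):
        assert apes.classify_event(self._timed(87.2), "F", "R", times) == \
            "before_speciation"

    def test_missing_divergence_unclassified(self, times):
        assert apes.classify_event(self._timed(10.0), "F", "Z", times) == \
            "unclassified"

    def test_conservative_under_upward_biased_noise(self, rng):
        # the consensus takes the max of two noisy estimates, biasing t_dup
        # upward; false "after" calls must not exceed false "before" calls
        times = apes.TimeTable(pair_times={frozenset({"F", "R"}): 50.0})
        false_after = false_before = 0
        for _ in range(2000):
            t_true = float(rng.uniform(10, 90))
            est = max(t_true + rng.normal(0, 10), t_true + rng.normal(0, 10))
            cls = apes.classify_event(self._timed(est), "F", "R", times)
            truth = "after_speciation" if t_true < 50.0 else "before_speciation"
            if cls != truth:
                if cls == "after_speciation":
                    false_after += 1
                else:
                    false_before += 1
        assert false_after <= false_before
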