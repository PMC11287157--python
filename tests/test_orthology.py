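"""Gene-tree parsing, rooting, duplication labelling and classification."""

import numpy as np
import pytest

from amtoolkit import (
    classify_family,
    label_duplications,
    parse_gene_tree,
    root_tree,
    simulate_gene_tree,
    simulate_species_tree,
)
from amtoolkit.orthology import (
    ConfigurationError,
    GeneTreeError,
    ortholog_leaves,
)
from amtoolkit.phylo import PhyloError


def clade_sets(gt):
    out = set()
    for nd in gt.tree.preorder_node_iter():
        if not nd.is_leaf():
            out.add(frozenset(gt.leaf_gene[lf] for lf in nd.leaf_iter()))
    return out


class TestParse:
    def test_direct_parse(self):
        gt = parse_gene_tree("((A|g1,B|g2),C|g3);")
        assert len(gt.leaves()) == 3
        assert gt.species_set == {"A", "B", "C"}
        assert gt.rooted

    def test_missing_delimiter_names_leaf(self):
        with pytest.raises(GeneTreeError, match="Xg9"):
            parse_gene_tree("((A|g1,B|g2),Xg9);")

    def test_malformed_newick(self):
        with pytest.raises(PhyloError, match="malformed"):
            parse_gene_tree("((A|g1,B|g2;")

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(GeneTreeError, match="duplicate"):
            parse_gene_tree("((A|g1,B|g1),C|g3);")

    def test_round_trip_preserves_topology_and_labels(self):
        """parse -> write -> parse is the identity on 500 random trees."""
        rng = np.random.default_rng(0)
        for i in range(500):
            stree = simulate_species_tree(
                int(rng.integers(4, 10)), seed=1000 + i)
            nwk, _ = simulate_gene_tree(stree, 0.3, 0.0, seed=2000 + i)
            gt = parse_gene_tree(nwk)
            gt2 = parse_gene_tree(gt.as_newick())
            assert clade_sets(gt) == clade_sets(gt2)
            assert set(gt.leaf_gene.values()) == set(gt2.leaf_gene.values())


class TestRooting:
    def test_three_taxon_outgroup(self):
        gt = parse_gene_tree("(A|g1,B|g2,C|g3);")
        rooted = root_tree(gt, outgroup_species=["C"])
        sides = [
            {rooted.leaf_species[lf] for lf in ch.leaf_iter()}
            for ch in rooted.tree.seed_node.child_nodes()
        ]
        assert {"C"} in sides
        assert {"A", "B"} in sides

    def test_missing_outgroup_lists_available(self):
        gt = parse_gene_tree("((A|g1,B|g2),C|g3);")
        with pytest.raises(ConfigurationError, match="available"):
            root_tree(gt, outgroup_species=["Z"])

    def test_midpoint_on_symmetric_ultrametric_tree(self):
        gt = parse_gene_tree("((A|g1:1,B|g2:1):1,(C|g3:1,D|g4:1):1);")
        rooted = root_tree(gt, midpoint=True)
        depths = rooted.tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert max(depths) == pytest.approx(2.0)

    def test_midpoint_minimises_maximum_root_to_tip(self):
        """Midpoint root-to-tip maximum equals half the tree diameter."""
        for i in range(40):
            stree = simulate_species_tree(6 + i % 6, seed=500 + i)
            nwk, _ = simulate_gene_tree(stree, 0.2, 0.0, seed=600 + i)
            gt = parse_gene_tree(nwk)
            if len(gt.leaves()) < 3 or len(gt.leaves()) > 20:
                continue
            # unit branch lengths: diameter by brute-force leaf-pair paths
            for nd in gt.tree.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length = 1.0
            pdm = gt.tree.phylogenetic_distance_matrix()
            taxa = list(gt.tree.taxon_namespace)
            diameter = max(
                pdm.distance(a, b)
                for i_, a in enumerate(taxa) for b in taxa[i_ + 1:]
            )
            rooted = root_tree(gt, midpoint=True)
            depths = rooted.tree.calc_node_root_distances(
                return_leaf_distances_only=True)
            assert max(depths) == pytest.approx(diameter / 2.0)


class TestLabelDuplications:
    def test_overlap_forces_duplication(self):
        gt = label_duplications(parse_gene_tree("((A|g1,A|g2),B|g3);"))
        root = gt.tree.seed_node
        inner = [c for c in root.child_nodes() if not c.is_leaf()][0]
        assert gt.events[inner] == "duplication"
        assert gt.events[root] == "speciation"

    def test_congruent_tree_has_no_duplications(self, species_tree_20):
        nwk, _ = simulate_gene_tree(species_tree_20, 0.0, 0.0, seed=11)
        gt = label_duplications(parse_gene_tree(nwk))
        assert set(gt.events.values()) == {"speciation"}

    def test_polytomy_duplication_iff_any_pair_overlaps(self):
        gt = label_duplications(
            parse_gene_tree("(A|g1,B|g2,(C|g3,C|g4),D|g5);", rooted=True))
        root = gt.tree.seed_node
        assert gt.events[root] == "speciation"
        gt2 = label_duplications(parse_gene_tree("(A|g1,B|g2,A|g3);", rooted=True))
        assert gt2.events[gt2.tree.seed_node] == "duplication"

    def test_unrooted_input_rejected(self):
        gt = parse_gene_tree("(A|g1,B|g2,C|g3);")
        with pytest.raises(GeneTreeError, match="rooted"):
            label_duplications(gt)


class TestCollapseSupport:
    def test_low_support_branch_becomes_polytomy(self):
        from amtoolkit.orthology import collapse_low_support

        gt = parse_gene_tree("(((A|g1,B|g2)40,C|g3)95,D|g4);")
        collapsed = collapse_low_support(gt, min_support=70)
        root_kids = collapsed.tree.seed_node.child_nodes()
        inner = [c for c in root_kids if not c.is_leaf()][0]
        assert len(inner.child_nodes()) == 3  # A, B, C now a polytomy
        # default behaviour (threshold 0) collapses nothing
        kept = collapse_low_support(gt, min_support=0)
        assert len(kept.leaves()) == 4
        assert sum(1 for nd in kept.tree.preorder_node_iter()
                   if not nd.is_leaf()) == 3


class TestClassifyFamily:
    PANEL = ["F", "G", "R1", "R2", "R3"]

    def classify(self, newick, **kw):
        gt = label_duplications(parse_gene_tree(newick))
        args = dict(family_id="fam", focal_species="F",
                    genus_partner_species="G",
                    reference_clades={"ref": ["R1", "R2", "R3"]},
                    panel_species=self.PANEL)
        args.update(kw)
        return classify_family(gt, **args)

    def test_one_to_one(self):
        rec = self.classify("((F|f1,G|g1),(R1|r1,(R2|r2,R3|r3)));")
        assert rec.focal_status == "one_to_one"
        assert rec.one_to_one and not rec.proto_ortholog
        assert rec.reference_ortholog_gene_ids == {
            "R1": ["r1"], "R2": ["r2"], "R3": ["r3"]}
        assert rec.presence == {s: "present" for s in self.PANEL}

    def test_proto_ortholog_from_reference_side_duplication(self):
        rec = self.classify("(F|f1,(R1|r1a,(R1|r1b,R1|r1c)));")
        assert rec.focal_status == "proto_ortholog"
        assert rec.proto_ortholog and not rec.one_to_one
        assert rec.reference_ortholog_gene_ids == {"R1": ["r1a", "r1b", "r1c"]}

    def test_both_flags_can_coexist(self):
        rec = self.classify("(F|f1,((R1|r1a,R1|r1b),R2|r2));")
        assert rec.one_to_one and rec.proto_ortholog
        assert rec.focal_status == "proto_ortholog"

    def test_absent_family(self):
        rec = self.classify("((G|g1,R1|r1),R2|r2);")
        assert rec.focal_status == "absent"
        assert rec.absent_in_tree
        assert rec.focal_gene_ids == []
        assert rec.presence["F"] == "absent"

    def test_multi_copy(self):
        rec = self.classify("((F|f1,F|f2),R1|r1);")
        assert rec.focal_status == "multi_copy"

    def test_focal_not_in_panel_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="focal"):
            self.classify("(F|f1,R1|r1);", focal_species="Q",
                          panel_species=["F", "R1", "Q2"],
                          genus_partner_species=None,
                          reference_clades=["R1"])

    def test_ortholog_sets_are_symmetric(self):
        """r in orthologs(f) iff f in orthologs(r), across random trees."""
        for i in range(50):
            stree = simulate_species_tree(6, seed=700 + i)
            nwk, _ = simulate_gene_tree(stree, 0.4, 0.0, seed=800 + i)
            gt = label_duplications(parse_gene_tree(nwk))
            leaves = gt.leaves()
            orth = {lf: ortholog_leaves(gt, lf) for lf in leaves}
            for lf in leaves:
                for other in orth[lf]:
                    assert lf in orth[other]

    def test_relabeling_species_permutes_but_preserves_counts(self):
        """A consistent species permutation leaves classification unchanged."""
        statuses = []
        for perm in ({}, {"F": "R2", "R2": "F", "R1": "R3", "R3": "R1"}):
            def m(s):
                return perm.get(s, s)

            nwk = "((F|f1,G|g1),((R1|r1a,R1|r1b),R2|r2));"
            for a, b in [("F|", f"{m('F')}%"), ("G|", f"{m('G')}%"),
                         ("R1|", f"{m('R1')}%"), ("R2|", f"{m('R2')}%"),
                         ("R3|", f"{m('R3')}%")]:
                nwk = nwk.replace(a, b)
            nwk = nwk.replace("%", "|")
            gt = label_duplications(parse_gene_tree(nwk))
            rec = classify_family(
                gt, "fam", m("F"), m("G"),
                {"ref": [m("R1"), m("R2"), m("R3")]},
                [m(s) for s in self.PANEL])
            statuses.append((rec.focal_status, rec.one_to_one,
                             rec.proto_ortholog, len(rec.focal_gene_ids)))
        assert statuses[0] == statuses[1]

    def test_loss_free_neutral_trees_classify_one_to_one(self):
        """With no duplications or losses every family is one-to-one."""
        stree = simulate_species_tree(8, seed=31)
        from amtoolkit.phylo import SpeciesTreeIndex

        species = SpeciesTreeIndex(stree).species
        focal, rest = species[0], list(species[1:])
        for i in range(20):
            nwk, _ = simulate_gene_tree(stree, 0.0, 0.0, seed=900 + i)
            gt = label_duplications(parse_gene_tree(nwk))
            rec = classify_family(gt, "fam", focal, None,
                                  {"ref": rest}, list(species))
            assert rec.focal_status == "one_to_one"
            assert all(len(v) == 1
                       for v in rec.reference_ortholog_gene_ids.values())
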