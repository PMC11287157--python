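"""Duplication-aware ortholog classification from per-family gene trees.

Given a rooted gene tree whose leaves are labelled ``species|gene``, internal
nodes are labelled duplication or speciation with the species-overlap
criterion: a node is a duplication when the species sets of its child
subtrees intersect.  Two genes are orthologs when their last common ancestor
is a speciation node.  The focal species' relationship to a reference clade
(e.g. the angiosperms) is then summarised per family as

* ``one_to_one``      - single focal gene with exactly one orthologous gene
                        in at least one reference species;
* ``proto_ortholog``  - single focal gene whose ortholog set contains two or
                        more genes of some reference species, i.e. the
                        reference lineage duplicated after the split from the
                        focal lineage;
* ``multi_copy``      - two or more focal genes in the family tree;
* ``absent``          - no focal gene in the tree (recorded with a caveat
                        flag, since absence from a tree is evidence, not
                        proof, of absence from the genome).

The one-to-one and proto-ortholog conditions are not mutually exclusive
(different reference species may show different copy numbers), so both are
also stored as independent flags alongside the summary status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .phylo import PhyloError, parse_newick_tree, tree_to_newick

DUPLICATION = "duplication"
SPECIATION = "speciation"


class GeneTreeError(ValueError):
    """Malformed gene tree input."""


class ConfigurationError(ValueError):
    """Inconsistent panel / species declarations."""


class GeneTree:
    """A gene-family tree with leaves mapped to species.

    Parameters
    ----------
    tree:
        A dendropy tree whose leaf labels are ``species<delimiter>gene``.
    species_delimiter:
        Separator between the species and gene part of each leaf label.
    rooted:
        Whether the tree is to be treated as rooted.  When ``None`` the tree
        counts as rooted iff its root has exactly two children.
    """

    def __init__(self, tree: dendropy.Tree, species_delimiter: str = "|",
                 rooted: bool | None = None):
        self.tree = tree
        self.delimiter = species_delimiter
        self.leaf_species: dict = {}
        self.leaf_gene: dict = {}
        genes = set()
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if label is None or species_delimiter not in label:
                raise GeneTreeError(
                    f"leaf {label!r} does not contain the species delimiter "
                    f"{species_delimiter!r}"
                )
            sp, gene = label.split(species_delimiter, 1)
            if gene in genes:
                raise GeneTreeError(f"duplicate gene id {gene!r} in tree")
            genes.add(gene)
            self.leaf_species[leaf] = sp
            self.leaf_gene[leaf] = gene
        if not self.leaf_species:
            raise GeneTreeError("gene tree has no leaves")
        if rooted is None:
            rooted = len(tree.seed_node.child_nodes()) == 2
        self.rooted = bool(rooted)
        self.events: dict | None = None  # filled by label_duplications

    # -- basic views -----------------------------------------------------
    @property
    def species_set(self) -> set[str]:
        return set(self.leaf_species.values())

    def leaves(self):
        return list(self.leaf_species)

    def leaves_under(self, node) -> list:
        return [lf for lf in node.leaf_iter()]

    def as_newick(self, include_events: bool = False) -> str:
        if include_events and self.events is not None:
            for nd, ev in self.events.items():
                nd.annotations.drop(name="event")
                nd.annotations.add_new("event", ev)
        return tree_to_newick(self.tree)

    def clone(self) -> "GeneTree":
        return GeneTree(self.tree.clone(depth=1), self.delimiter, rooted=self.rooted)


def parse_gene_tree(newick_text: str, species_delimiter: str = "|",
                    rooted: bool | None = None) -> GeneTree:
    """Parse a Newick gene tree; polytomies are preserved.

    ``rooted`` overrides the default rootedness heuristic (bifurcating
    root), e.g. for trees rooted at a basal polytomy.  Raises
    :class:`~amtoolkit.phylo.PhyloError` on malformed Newick and
    :class:`GeneTreeError` when a leaf label lacks the delimiter.
    """
    tree = parse_newick_tree(newick_text)
    return GeneTree(tree, species_delimiter, rooted=rooted)


def _edge_length(node, default=1.0) -> float:
    return node.edge.length if node.edge.length is not None else default


def root_tree(gene_tree: GeneTree, outgroup_species: Iterable[str] | None = None,
              midpoint: bool = False) -> GeneTree:
    """Root a gene tree on an outgroup or at the midpoint.

    With an outgroup, the root is placed on the branch subtending the
    smallest side of any bipartition that separates all outgroup leaves from
    the rest.  With ``midpoint=True`` the root minimises the maximum
    root-to-tip path length (missing branch lengths count as 1).
    """
    if (outgroup_species is None) == (not midpoint):
        raise ConfigurationError("specify exactly one of outgroup_species or midpoint")
    gt = gene_tree.clone()
    tree = gt.tree
    if midpoint:
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 1.0
        _reroot_at_midpoint(gt)
    else:
        outgroup = set(outgroup_species)
        missing = outgroup - gt.species_set
        if missing:
            raise ConfigurationError(
                f"outgroup species {sorted(missing)} absent from tree; "
                f"available species: {sorted(gt.species_set)}"
            )
        og_leaves = {lf for lf, sp in gt.leaf_species.items() if sp in outgroup}
        n_leaves = len(gt.leaf_species)
        best = None
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            side = set(lf for lf in nd.leaf_iter())
            if og_leaves <= side:
                size = len(side)
            elif not (og_leaves & side):
                size = n_leaves - len(side)
            else:
                continue
            key = (size, min(gt.leaf_gene[lf] for lf in side))
            if best is None or key < best[0]:
                best = (key, nd)
        assert best is not None
        node = best[1]
        if node.edge.length is None:
            node.edge.length = 1.0
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    tree.is_rooted = True
    return GeneTree(tree, gene_tree.delimiter, rooted=True)


def _unrooted_distances(tree, start):
    """Path lengths from ``start`` to every node, ignoring root orientation."""
    dist = {start: 0.0}
    prev: dict = {}
    stack = [start]
    while stack:
        nd = stack.pop()
        neighbours = list(nd.child_nodes())
        if nd.parent_node is not None:
            neighbours.append(nd.parent_node)
        for nb in neighbours:
            if nb in dist:
                continue
            length = nb.edge.length if nb.parent_node is nd else nd.edge.length
            dist[nb] = dist[nd] + length
            prev[nb] = nd
            stack.append(nb)
    return dist, prev


def _reroot_at_midpoint(gt: GeneTree) -> None:
    """Root at the point minimising the maximum root-to-tip path length.

    Two-sweep diameter search; the midpoint lies halfway along the longest
    leaf-to-leaf path.  Ties between equally distant leaves are broken
    toward the lexicographically smallest gene id, for determinism.
    """
    tree = gt.tree
    leaves = gt.leaves()
    if len(leaves) < 2:
        return

    def farthest(dist):
        return min(leaves, key=lambda lf: (-dist[lf], gt.leaf_gene[lf]))

    d0, _ = _unrooted_distances(tree, min(leaves, key=lambda lf: gt.leaf_gene[lf]))
    a = farthest(d0)
    da, prev_a = _unrooted_distances(tree, a)
    b = farthest(da)
    target = da[b] / 2.0
    path = [b]
    while path[-1] is not a:
        path.append(prev_a[path[-1]])
    path.reverse()  # a ... b
    cum = 0.0
    for u, v in zip(path, path[1:]):
        step = v.edge.length if v.parent_node is u else u.edge.length
        if cum + step >= target - 1e-12:
            if abs(cum + step - target) <= 1e-12:
                tree.reroot_at_node(v, update_bipartitions=False)
            elif abs(cum - target) <= 1e-12:
                tree.reroot_at_node(u, update_bipartitions=False)
            elif v.parent_node is u:
                tree.reroot_at_edge(v.edge, length1=target - cum,
                                    length2=cum + step - target,
                                    update_bipartitions=False)
            else:
                tree.reroot_at_edge(u.edge, length1=cum + step - target,
                                    length2=target - cum,
                                    update_bipartitions=False)
            return
        cum += step
    raise AssertionError("midpoint not found on the diameter path")


def collapse_low_support(gene_tree: GeneTree, min_support: float) -> GeneTree:
    """Collapse internal branches with support below ``min_support``.

    Support values are read from numeric internal-node labels; branches
    below the threshold become polytomies before duplication labelling.
    Nodes without a numeric label are kept.  Returns a new tree.
    """
    gt = gene_tree.clone()
    to_collapse = []
    for nd in gt.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        try:
            support = float(nd.label) if nd.label is not None else None
        except ValueError:
            support = None
        if support is not None and support < min_support:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return GeneTree(gt.tree, gene_tree.delimiter, rooted=gene_tree.rooted)


def label_duplications(gene_tree: GeneTree) -> GeneTree:
    """Label every internal node duplication/speciation by species overlap.

    A node is a duplication iff the species sets of (any pair of) its child
    subtrees intersect.  Returns the same :class:`GeneTree` with ``.events``
    populated (node -> label).  Requires a rooted tree.
    """
    if not gene_tree.rooted:
        raise GeneTreeError("species-overlap labelling requires a rooted gene tree")
    events: dict = {}
    spset: dict = {}
    for nd in gene_tree.tree.postorder_node_iter():
        if nd.is_leaf():
            spset[nd] = {gene_tree.leaf_species[nd]}
            continue
        kids = nd.child_nodes()
        union: set = set()
        dup = False
        for ch in kids:
            if union & spset[ch]:
                dup = True
            union |= spset[ch]
        spset[nd] = union
        events[nd] = DUPLICATION if dup else SPECIATION
    gene_tree.events = events
    return gene_tree


def events_by_label(gene_tree: GeneTree) -> dict[str, str]:
    """Map internal-node labels (where present) to their event labels."""
    if gene_tree.events is None:
        raise GeneTreeError("tree has no event labels; run label_duplications first")
    out = {}
    for nd, ev in gene_tree.events.items():
        if nd.label is not None:
            out[nd.label] = ev
    return out


def ortholog_leaves(gene_tree: GeneTree, leaf) -> set:
    """All leaves whose LCA with ``leaf`` is a speciation node."""
    if gene_tree.events is None:
        raise GeneTreeError("run label_duplications before querying orthologs")
    out: set = set()
    prev = leaf
    anc = leaf.parent_node
    while anc is not None:
        if gene_tree.events[anc] == SPECIATION:
            for ch in anc.child_nodes():
                if ch is prev:
                    continue
                out.update(ch.leaf_iter())
        prev = anc
        anc = anc.parent_node
    return out


@dataclass
class FamilyConservationRecord:
    """Per-family summary of the focal species' orthology relationships."""

    family_id: str
    focal_status: str  # one_to_one | proto_ortholog | multi_copy | absent | unplaced
    one_to_one: bool
    proto_ortholog: bool
    focal_gene_ids: list[str]
    reference_ortholog_gene_ids: dict[str, list[str]] = field(default_factory=dict)
    presence: dict[str, str] = field(default_factory=dict)
    absent_in_tree: bool = False

    @property
    def focal_present(self) -> bool:
        return bool(self.focal_gene_ids)


def classify_family(
    labeled_tree: GeneTree,
    family_id: str,
    focal_species: str,
    genus_partner_species: str | None,
    reference_clades: Mapping[str, Iterable[str]] | Iterable[str],
    panel_species: Sequence[str],
) -> FamilyConservationRecord:
    """Classify the focal species' relationship to the reference clade(s).

    ``reference_clades`` may be a single species collection or a mapping of
    clade name -> species collection; flags are evaluated against the union.
    The presence vector covers every panel species, scored from the tree's
    leaf set (a species with no leaf is absent-in-tree).
    """
    if labeled_tree.events is None:
        labeled_tree = label_duplications(labeled_tree)
    panel = list(panel_species)
    if focal_species not in panel:
        raise ConfigurationError(f"focal species {focal_species!r} not in panel")
    if genus_partner_species is not None and genus_partner_species not in panel:
        raise ConfigurationError(
            f"genus partner {genus_partner_species!r} not in panel"
        )
    if isinstance(reference_clades, Mapping):
        ref_union: set[str] = set()
        for members in reference_clades.values():
            ref_union |= set(members)
    else:
        ref_union = set(reference_clades)
    unknown_ref = ref_union - set(panel)
    if unknown_ref:
        raise ConfigurationError(f"reference species not in panel: {sorted(unknown_ref)}")

    species_in_tree = labeled_tree.species_set
    presence = {sp: ("present" if sp in species_in_tree else "absent") for sp in panel}

    focal_leaves = [lf for lf, sp in labeled_tree.leaf_species.items()
                    if sp == focal_species]
    focal_genes = sorted(labeled_tree.leaf_gene[lf] for lf in focal_leaves)

    ref_orthologs: dict[str, list[str]] = {}
    if len(focal_leaves) == 1:
        orths = ortholog_leaves(labeled_tree, focal_leaves[0])
        for lf in orths:
            sp = labeled_tree.leaf_species[lf]
            if sp in ref_union:
                ref_orthologs.setdefault(sp, []).append(labeled_tree.leaf_gene[lf])
        for sp in ref_orthologs:
            ref_orthologs[sp].sort()

    if not focal_leaves:
        status, one_to_one, proto = "absent", False, False
    elif len(focal_leaves) >= 2:
        status, one_to_one, proto = "multi_copy", False, False
    else:
        counts = [len(g) for g in ref_orthologs.values()]
        one_to_one = any(c == 1 for c in counts)
        proto = any(c >= 2 for c in counts)
        if proto:
            status = "proto_ortholog"
        elif one_to_one:
            status = "one_to_one"
        else:
            status = "unplaced"  # focal gene present but no reference ortholog

    return FamilyConservationRecord(
        family_id=family_id,
        focal_status=status,
        one_to_one=one_to_one,
        proto_ortholog=proto,
        focal_gene_ids=focal_genes,
        reference_ortholog_gene_ids=ref_orthologs,
        presence=presence,
        absent_in_tree=not focal_leaves,
    )
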