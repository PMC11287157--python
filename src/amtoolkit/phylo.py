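"""Shared species-tree machinery.

A rooted species phylogeny is the substrate for trait-loss inference, for the
gene-family loss simulator and for the permutation null of the coelimination
test.  Branches are identified by the frozenset of species descending from
them, which is stable across serialisation round trips.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np


class PhyloError(ValueError):
    """Structurally invalid tree input."""


class InfeasiblePlacementError(PhyloError):
    """A requested set of mutually non-nested branches cannot be drawn."""


def parse_newick_tree(text: str) -> dendropy.Tree:
    """Parse a single Newick tree, preserving underscores in labels."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloError(f"malformed Newick: {exc}") from exc


def read_newick_tree(path) -> dendropy.Tree:
    return parse_newick_tree(Path(path).read_text())


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def write_newick_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_newick(tree))


class SpeciesTreeIndex:
    """Array view of a rooted species tree.

    Precomputes, for every branch (one per non-root node), the boolean mask of
    descendant species, the branch-vs-branch overlap matrix (in a tree two
    clades overlap iff one is nested in the other) and the clade <-> branch
    lookup used to translate loss events between set and index form.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        if len(labels) != len(set(labels)):
            raise PhyloError("species tree has duplicate leaf labels")
        if len(labels) < 2:
            raise PhyloError("species tree needs at least 2 leaves")
        self.species: tuple[str, ...] = tuple(sorted(labels))
        self.n_species = len(self.species)
        self._sp_index = {s: i for i, s in enumerate(self.species)}

        node_mask: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                m = np.zeros(self.n_species, dtype=bool)
                m[self._sp_index[nd.taxon.label]] = True
            else:
                m = np.zeros(self.n_species, dtype=bool)
                for ch in nd.child_nodes():
                    m |= node_mask[ch]
            node_mask[nd] = m

        self.edge_nodes = [
            nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
        ]
        E = len(self.edge_nodes)
        self.masks = np.zeros((E, self.n_species), dtype=bool)
        for e, nd in enumerate(self.edge_nodes):
            self.masks[e] = node_mask[nd]
        self.sizes = self.masks.sum(axis=1)
        ov = self.masks.astype(np.uint8) @ self.masks.T.astype(np.uint8)
        self.conflict = ov > 0  # overlap => nested or identical
        # complementary sibling branches also conflict: losses on both
        # children of a bifurcation are indistinguishable (under Dollo) from
        # a single loss on the parent branch, so they are not independent
        edge_id = {nd: e for e, nd in enumerate(self.edge_nodes)}
        for nd in tree.preorder_node_iter():
            kids = nd.child_nodes()
            if len(kids) == 2 and all(k in edge_id for k in kids):
                a, b = edge_id[kids[0]], edge_id[kids[1]]
                self.conflict[a, b] = self.conflict[b, a] = True
        self.clades = [
            frozenset(self.species[i] for i in np.flatnonzero(self.masks[e]))
            for e in range(E)
        ]
        self.edge_of_clade = {c: e for e, c in enumerate(self.clades)}

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    def species_index(self, species: str) -> int:
        try:
            return self._sp_index[species]
        except KeyError:
            raise PhyloError(f"species {species!r} not in tree") from None

    def presence_vector(self, mapping, states=("present",)) -> np.ndarray:
        """Boolean vector over ``self.species`` where the mapped state matches."""
        out = np.zeros(self.n_species, dtype=bool)
        for sp, val in mapping.items():
            if sp in self._sp_index and val in states:
                out[self._sp_index[sp]] = True
        return out

    def edges_for_clades(self, clades: Iterable[frozenset]) -> list[int]:
        out = []
        for c in clades:
            c = frozenset(c)
            if c not in self.edge_of_clade:
                raise PhyloError(f"clade {sorted(c)} is not a branch of the tree")
            out.append(self.edge_of_clade[c])
        return out

    def edges_within(self, edge_ids: Sequence[int]) -> np.ndarray:
        """Boolean over edges: nested within (or equal to) any listed edge."""
        out = np.zeros(self.n_edges, dtype=bool)
        for e in edge_ids:
            nested = (self.masks & self.masks[e]).sum(axis=1) == self.sizes
            out |= nested
        return out

    def sample_non_nested_sets(
        self,
        k: int,
        n_sets: int,
        rng: np.random.Generator,
        max_batches: int = 2000,
    ) -> np.ndarray:
        """Draw ``n_sets`` uniform samples of k mutually non-nested branches.

        Uniform over all feasible k-sets (rejection sampling); a set is
        feasible when no branch is nested in another and the union of their
        descendant species does not cover every leaf (at least one species
        keeps the ancestral state).
        """
        if k == 0:
            return np.zeros((n_sets, 0), dtype=np.intp)
        E = self.n_edges
        if k > E:
            raise InfeasiblePlacementError(
                f"cannot place {k} non-nested branches on a tree with {E} branches"
            )
        chunks: list[np.ndarray] = []
        got = 0
        for _ in range(max_batches):
            m = max(4 * (n_sets - got), 64)
            cand = rng.integers(0, E, size=(m, k))
            ok = np.ones(m, dtype=bool)
            for i in range(k):
                for j in range(i + 1, k):
                    ok &= ~self.conflict[cand[:, i], cand[:, j]]
            ok &= self.sizes[cand].sum(axis=1) < self.n_species
            good = cand[ok]
            if good.shape[0]:
                chunks.append(good)
                got += good.shape[0]
            if got >= n_sets:
                return np.concatenate(chunks, axis=0)[:n_sets]
        raise InfeasiblePlacementError(
            f"could not draw {n_sets} non-nested {k}-sets; placement infeasible"
        )
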