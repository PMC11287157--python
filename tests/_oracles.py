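"""Independent brute-force oracles used by the unit and acceptance suites."""

from itertools import combinations

import numpy as np


def brute_force_dollo(index, trait_map):
    """Exhaustive minimal-assignment search over all internal states.

    Enumerates every internal present/absent assignment with the root fixed
    to present, keeps assignments without regains (absent parent, present
    child) that match the leaf traits, and returns the minimal loss count
    plus the set of loss-branch solutions achieving it.
    """
    nodes = list(index.tree.preorder_node_iter())
    node_id = {nd: i for i, nd in enumerate(nodes)}
    internal = [nd for nd in nodes
                if not nd.is_leaf() and nd.parent_node is not None]
    n_free = len(internal)
    n_assign = 2 ** n_free
    states = np.ones((n_assign, len(nodes)), dtype=bool)
    bits = np.arange(n_assign)[:, None] >> np.arange(n_free)[None, :]
    for j, nd in enumerate(internal):
        states[:, node_id[nd]] = (bits[:, j] & 1).astype(bool)
    for nd in nodes:
        if nd.is_leaf():
            states[:, node_id[nd]] = trait_map[nd.taxon.label] == "host"
    parent = np.array([node_id[nd.parent_node] for nd in nodes[1:]])
    child = np.array([node_id[nd] for nd in nodes[1:]])
    regain = (~states[:, parent]) & states[:, child]
    valid = ~regain.any(axis=1)
    losses = states[:, parent] & ~states[:, child]
    counts = losses.sum(axis=1)
    counts = np.where(valid, counts, np.iinfo(np.int64).max)
    best = counts.min()
    solutions = set()
    for a in np.flatnonzero(counts == best):
        edges = np.flatnonzero(losses[a])
        clades = frozenset(
            frozenset(lf.taxon.label for lf in nodes[1:][e].leaf_iter())
            for e in edges
        )
        solutions.add(clades)
    return int(best), solutions


def lca_reconciliation_events(gene_tree, species_index):
    """LCA-mapping reconciliation labels for every internal gene-tree node.

    Each node maps to the smallest species-tree clade containing its leaf
    species; a node is a duplication iff it maps to the same clade as one of
    its children.
    """
    full = frozenset(species_index.species)
    candidates = sorted(
        list(species_index.clades) + [full], key=len)

    def smallest_clade(species):
        for c in candidates:
            if species <= c:
                return c
        raise AssertionError("species not covered by the tree")

    mapping = {}
    spset = {}
    events = {}
    for nd in gene_tree.tree.postorder_node_iter():
        if nd.is_leaf():
            spset[nd] = frozenset({gene_tree.leaf_species[nd]})
        else:
            spset[nd] = frozenset().union(*(spset[c] for c in nd.child_nodes()))
        mapping[nd] = smallest_clade(spset[nd])
        if not nd.is_leaf():
            dup = any(mapping[c] == mapping[nd] for c in nd.child_nodes())
            events[nd] = "duplication" if dup else "speciation"
    return events


def enumerate_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == pooled.size, "tie-free samples only"
    ranks = np.argsort(np.argsort(pooled)) + 1
    rx = ranks[: len(x)]
    obs = rx.sum()
    n = pooled.size
    expected = len(x) * (n + 1) / 2.0
    stats = [
        sum(comb)
        for comb in combinations(range(1, n + 1), len(x))
    ]
    dev = abs(obs - expected)
    extreme = sum(1 for s in stats if abs(s - expected) >= dev - 1e-9)
    return extreme / len(stats)


def check_cld(letters, different):
    """Both compact-letter-display guarantees, by direct inspection."""
    for (a, b), diff in different.items():
        shared = set(letters[a]) & set(letters[b])
        if diff:
            assert not shared, (letters, a, b)
        else:
            assert shared, (letters, a, b)
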