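"""Synthetic-data generators with known ground truth.

Every pipeline input can be simulated: a Yule species tree, independent
trait losses placed on non-nested branches (Dollo semantics: single origin
at the root, losses only), gene families whose per-branch loss probability
is multiplied in trait-less lineages when the family is symbiosis-linked,
gene trees evolving by birth-death inside the species tree, negative-
binomial count matrices emulating a mock-vs-colonized time course at 5, 8
and 11 weeks post-inoculation, and per-section colonization observations.

One global seed expands deterministically into per-component child seeds
(CRC-32 of the component tag mixed into a numpy SeedSequence), so partial
reruns of a single component reproduce the full run's output.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .coelimination import HOST, NONHOST, LossEventSet, infer_trait_losses
from .phylo import InfeasiblePlacementError, SpeciesTreeIndex, write_newick_tree

DEFAULT_TIMEPOINTS = ("5wpi", "8wpi", "11wpi")
MOCK = "mock"
COLONIZED = "colonized"


class EmptyGeneTreeError(RuntimeError):
    """All gene lineages went extinct; the caller may re-seed."""


def child_seed(seed: int, tag: str) -> np.random.SeedSequence:
    """Deterministic per-component child of a global seed."""
    return np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(tag.encode())])


def component_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, tag))


@dataclass
class SimulationConfig:
    """Study-design parameters for a full synthetic run.

    Defaults emulate the design of the study being modelled: a 59-genome
    land-plant panel with several independent losses of mycorrhizal
    competence, gene families lost preferentially in nonhost lineages when
    symbiosis-linked, and a replicated mock-vs-colonized NB count time
    course at 5, 8 and 11 weeks post-inoculation.
    """

    n_species: int = 59
    n_trait_losses: int = 4
    n_families: int = 1000
    frac_symbiotic: float = 0.3
    base_loss_prob: float = 0.02
    coupled_loss_multiplier: float = 25.0
    dup_rate: float = 0.2
    gloss_rate: float = 0.0
    n_genes: int = 2000
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    reps_per_group: int = 3
    frac_induced: float = 0.1
    lfc_location: float = 2.0
    lfc_scale: float = 0.5
    dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.n_trait_losses < 0:
            raise ValueError("n_trait_losses must be >= 0")
        if self.n_families < 1 or self.n_genes < 1:
            raise ValueError("n_families and n_genes must be positive")
        for name in ("frac_symbiotic", "base_loss_prob", "frac_induced"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coupled_loss_multiplier < 1.0:
            raise ValueError("coupled_loss_multiplier must be >= 1")
        if self.dup_rate < 0 or self.gloss_rate < 0:
            raise ValueError("dup_rate and gloss_rate must be >= 0")
        if self.reps_per_group < 1:
            raise ValueError("reps_per_group must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if len(self.timepoints) < 1:
            raise ValueError("at least one timepoint required")
        return self

    @property
    def coupled_loss_prob(self) -> float:
        if math.isinf(self.coupled_loss_multiplier):
            return 1.0
        return min(1.0, self.base_loss_prob * self.coupled_loss_multiplier)


def simulate_species_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) rooted binary species tree.

    Topology follows the equal-rates-Markov process (a uniformly chosen tip
    splits at each step); branch lengths are iid Exp(1) draws, which keeps
    all branches strictly positive.  Species are labelled sp01, sp02, ...
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = component_rng(seed, "species_tree")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    tips = []
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        tips.append(ch)
    while len(tips) < n_species:
        i = int(rng.integers(0, len(tips)))
        nd = tips.pop(i)
        for _ in range(2):
            ch = dendropy.Node()
            nd.add_child(ch)
            tips.append(ch)
    width = len(str(n_species))
    for k, nd in enumerate(tips, start=1):
        nd.taxon = taxa.new_taxon(label=f"sp{k:0{width}d}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.exponential(1.0))
    return tree


def simulate_trait_losses(
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    n_trait_losses: int,
    seed: int,
) -> tuple[dict[str, str], LossEventSet]:
    """Place independent trait losses on mutually non-nested branches.

    The trait is present at the root (single origin); every species below a
    loss branch is nonhost, all others host.  Placement is uniform over all
    feasible non-nested branch sets that leave at least one host.
    """
    index = species_tree if isinstance(species_tree, SpeciesTreeIndex) \
        else SpeciesTreeIndex(species_tree)
    rng = component_rng(seed, "trait_losses")
    if n_trait_losses == 0:
        return {sp: HOST for sp in index.species}, LossEventSet(())
    sets = index.sample_non_nested_sets(n_trait_losses, 1, rng)
    events = LossEventSet(tuple(index.clades[e] for e in sets[0]))
    nonhost = events.nonhost_species
    trait_map = {sp: (NONHOST if sp in nonhost else HOST) for sp in index.species}
    return trait_map, events


def simulate_gene_families(
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    trait_map: Mapping[str, str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve family presence/absence down the species tree.

    Presence starts at the root and is lost on each branch with probability
    ``base_loss_prob`` - multiplied by ``coupled_loss_multiplier`` (capped at
    probability 1) on branches inside nonhost lineages when the family is
    symbiosis-linked.  Once lost, a family is never regained in a lineage.

    Returns (presence matrix: families x species with present/absent tokens,
    truth table: family_id, symbiotic flag).
    """
    config.validate()
    index = species_tree if isinstance(species_tree, SpeciesTreeIndex) \
        else SpeciesTreeIndex(species_tree)
    if seed is None:
        seed = config.seed
    rng = component_rng(seed, "gene_families")
    events = infer_trait_losses(index, trait_map)
    coupled_edges = index.edges_within(index.edges_for_clades(events)) \
        if len(events) else np.zeros(index.n_edges, dtype=bool)

    F = config.n_families
    symbiotic = rng.random(F) < config.frac_symbiotic
    p_base, p_coup = config.base_loss_prob, config.coupled_loss_prob

    state: dict = {index.tree.seed_node: np.ones(F, dtype=bool)}
    leaf_state: dict[str, np.ndarray] = {}
    edge_id = {nd: e for e, nd in enumerate(index.edge_nodes)}
    for nd in index.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        p = np.where(symbiotic & coupled_edges[edge_id[nd]], p_coup, p_base)
        survive = rng.random(F) >= p
        state[nd] = state[nd.parent_node] & survive
        if nd.is_leaf():
            leaf_state[nd.taxon.label] = state[nd]
    fam_ids = [f"fam{i + 1:05d}" for i in range(F)]
    presence = pd.DataFrame(
        {sp: np.where(leaf_state[sp], "present", "absent") for sp in index.species},
        index=pd.Index(fam_ids, name="family_id"),
    )
    truth = pd.DataFrame(
        {"family_id": fam_ids, "symbiotic": symbiotic}
    ).set_index("family_id")
    return presence, truth


class _GNode:
    __slots__ = ("children", "event", "species", "gene_id", "label")

    def __init__(self, children=None, event=None, species=None, gene_id=None):
        self.children = children or []
        self.event = event
        self.species = species
        self.gene_id = gene_id
        self.label = None


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    dup_rate: float,
    gloss_rate: float,
    seed: int,
    forced_root_duplications: int = 0,
):
    """Birth-death evolution of gene lineages inside the species tree.

    Each lineage duplicates at ``dup_rate`` and dies at ``gloss_rate`` per
    unit branch length; at species-tree splits every surviving lineage
    enters both child branches (a speciation node).  Returns a Newick string
    with leaves ``species|gene`` and labelled internal nodes, plus the true
    event label of every surviving internal node.

    ``forced_root_duplications`` seeds k extra duplications on the root
    branch (k+1 starting lineages), which is convenient for fixtures.
    Raises :class:`EmptyGeneTreeError` when all lineages go extinct.
    """
    if dup_rate < 0 or gloss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = component_rng(seed, "gene_tree")
    counter = {"gene": 0}

    def leaf_for(species: str) -> _GNode:
        counter["gene"] += 1
        return _GNode(species=species, gene_id=f"g{counter['gene']:04d}")

    total = dup_rate + gloss_rate

    def evolve(sp_node, remaining: float):
        if total > 0:
            dt = rng.exponential(1.0 / total)
            if dt < remaining:
                if rng.random() < (dup_rate / total):
                    a = evolve(sp_node, remaining - dt)
                    b = evolve(sp_node, remaining - dt)
                    if a is not None and b is not None:
                        return _GNode(children=[a, b], event="duplication")
                    return a if a is not None else b
                return None  # gene loss
        if sp_node.is_leaf():
            return leaf_for(sp_node.taxon.label)
        kids = []
        for ch in sp_node.child_nodes():
            sub = evolve(ch, ch.edge.length if ch.edge.length is not None else 1.0)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return _GNode(children=kids, event="speciation")

    def from_root():
        root = species_tree.seed_node
        if root.is_leaf():
            return leaf_for(root.taxon.label)
        kids = []
        for ch in root.child_nodes():
            sub = evolve(ch, ch.edge.length if ch.edge.length is not None else 1.0)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        return kids[0] if len(kids) == 1 else _GNode(children=kids, event="speciation")

    lineages = [from_root() for _ in range(forced_root_duplications + 1)]
    lineages = [ln for ln in lineages if ln is not None]
    if not lineages:
        raise EmptyGeneTreeError("all gene lineages went extinct")
    groot = lineages[0]
    for extra in lineages[1:]:
        groot = _GNode(children=[groot, extra], event="duplication")

    truth: dict[str, str] = {}
    counter_n = {"node": 0}

    def to_newick(node: _GNode) -> str:
        if not node.children:
            return f"{node.species}|{node.gene_id}"
        counter_n["node"] += 1
        node.label = f"n{counter_n['node']:04d}"
        truth[node.label] = node.event
        inner = ",".join(to_newick(ch) for ch in node.children)
        return f"({inner}){node.label}"

    newick = to_newick(groot) + ";"
    return newick, truth


def make_design(timepoints: Sequence[str], reps_per_group: int) -> pd.DataFrame:
    """Sample sheet for a mock-vs-colonized time course."""
    rows = []
    for tp in timepoints:
        for cond in (MOCK, COLONIZED):
            for r in range(1, reps_per_group + 1):
                rows.append(
                    {"sample_id": f"{cond}_{tp}_r{r}", "condition": cond,
                     "timepoint": tp, "replicate": r}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replicated NB counts for a mock-vs-colonized time course.

    A ``frac_induced`` subset of genes carries a true log2 fold change drawn
    from N(lfc_location, lfc_scale), applied in colonized samples at every
    timepoint.  Per-sample library-size factors are lognormal and recorded
    in the sample sheet.  Counts are NB with the configured dispersion
    (variance mu + dispersion * mu^2).

    Returns (counts genes x samples, sample sheet with size factors, truth
    table gene_id/induced/true_log2fc).
    """
    config.validate()
    if config.reps_per_group < 2:
        raise ValueError("reps_per_group must be >= 2 for a testable design")
    if seed is None:
        seed = config.seed
    rng = component_rng(seed, "counts")
    G = config.n_genes
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=G)
    induced = rng.random(G) < config.frac_induced
    lfc = np.where(induced, rng.normal(config.lfc_location, config.lfc_scale, G), 0.0)

    samples = make_design(config.timepoints, config.reps_per_group)
    factors = rng.lognormal(mean=0.0, sigma=0.15, size=len(samples))
    samples = samples.assign(size_factor=factors)

    inv_disp = 1.0 / config.dispersion
    counts = np.empty((G, len(samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        mu = base * row["size_factor"]
        if row["condition"] == COLONIZED:
            mu = mu * np.power(2.0, lfc)
        p = inv_disp / (inv_disp + mu)
        counts[:, j] = rng.negative_binomial(inv_disp, p)
    gene_ids = [f"gene{i + 1:05d}" for i in range(G)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples.index)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "induced": induced, "true_log2fc": lfc}
    ).set_index("gene_id")
    return counts_df, samples, truth


def simulate_colonization_observations(
    genotype_probs: Mapping[str, Mapping[str, float]],
    n_reps: int,
    n_positions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli presence/absence of fungal structures along the thallus.

    ``genotype_probs`` maps genotype -> structure -> probability that the
    structure is observed at any one of the ``n_positions`` transverse
    sections (default 10, as in the x/10 colonization ratio).
    """
    if n_reps < 1 or n_positions < 1:
        raise ValueError("n_reps and n_positions must be positive")
    for geno, probs in genotype_probs.items():
        for struct, p in probs.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(
                    f"probability for {geno}/{struct} outside [0, 1]: {p}"
                )
    rng = component_rng(seed, "colonization")
    rows = []
    for geno in genotype_probs:
        for rep in range(1, n_reps + 1):
            for struct, p in genotype_probs[geno].items():
                draws = rng.random(n_positions) < float(p)
                for pos in range(1, n_positions + 1):
                    rows.append(
                        {"replicate": f"{geno}_r{rep}", "genotype": geno,
                         "structure": struct, "position": pos,
                         "observed": int(draws[pos - 1])}
                    )
    return pd.DataFrame(rows)


def write_run_manifest(path, config: SimulationConfig, extra: Mapping | None = None) -> None:
    """Echo every generation parameter into a structured manifest file."""
    payload = {"config": asdict(config)}
    if extra:
        payload.update(extra)
    payload["config"]["timepoints"] = list(config.timepoints)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_simulated_inputs(
    outdir,
    config: SimulationConfig,
) -> dict[str, str]:
    """Generate and write a full set of pipeline inputs; returns file paths."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import tables  # local import to avoid a cycle at module load

    tree = simulate_species_tree(config.n_species, config.seed)
    trait_map, events = simulate_trait_losses(tree, config.n_trait_losses, config.seed)
    presence, fam_truth = simulate_gene_families(tree, trait_map, config)
    counts, samples, gene_truth = simulate_counts(config)

    paths = {
        "species_tree": str(outdir / "species_tree.nwk"),
        "trait_table": str(outdir / "traits.tsv"),
        "presence_matrix": str(outdir / "presence.tsv"),
        "family_truth": str(outdir / "family_truth.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "sample_sheet": str(outdir / "samples.tsv"),
        "gene_truth": str(outdir / "gene_truth.tsv"),
        "manifest": str(outdir / "run_manifest.json"),
    }
    write_newick_tree(tree, paths["species_tree"])
    tables.write_trait_table(trait_map, paths["trait_table"])
    tables.write_presence_matrix(presence, paths["presence_matrix"])
    tables.write_table(fam_truth.reset_index(), paths["family_truth"])
    tables.write_table(counts.reset_index(), paths["counts"])
    tables.write_table(samples.reset_index(), paths["sample_sheet"])
    tables.write_table(gene_truth.reset_index(), paths["gene_truth"])
    write_run_manifest(
        paths["manifest"], config,
        extra={"trait_loss_branches": [sorted(e) for e in events]},
    )
    return paths
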