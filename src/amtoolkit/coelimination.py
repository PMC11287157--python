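"""Gene-trait coelimination analysis across independent trait losses.

The mycorrhizal-competence trait is assumed to have a single origin at the
root of the species tree (monophyletic origin), so ancestral reconstruction
is Dollo parsimony with the root fixed to trait-present: the unique minimal
solution places one loss on the stem of every maximal all-nonhost clade.

A gene family coeliminates with the trait when it is retained by trait-
positive (host) species but absent from several of those independently
derived nonhost clades.  The permutation test relocates the same number of
non-nested loss events uniformly at random on the tree and recomputes the
number of independent co-losses, which makes observed and null events
exchangeable when gene loss is independent of the trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .phylo import InfeasiblePlacementError, PhyloError, SpeciesTreeIndex

HOST = "host"
NONHOST = "nonhost"

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

AM_ONLY = "AM-only"
CONSERVED_ALL = "conserved-all"
LOST_IN_NONHOST = "lost-in-nonhost"
RETAINED_IN_NONHOST = "retained-in-nonhost"


class TraitError(ValueError):
    """Invalid trait map for the given species tree."""


class DataIntegrityError(ValueError):
    """Presence row and species tree disagree."""


def normalise_presence_state(value) -> str:
    """Map common presence/absence tokens onto present/absent/unknown."""
    if isinstance(value, str):
        token = value.strip().lower()
        if token in {"present", "1", "yes", "true"}:
            return PRESENT
        if token in {"absent", "0", "no", "false"}:
            return ABSENT
        if token in {"unknown", "na", "nan", "", "?"}:
            return UNKNOWN
        raise DataIntegrityError(f"unrecognised presence token {value!r}")
    if value is True:
        return PRESENT
    if value is False:
        return ABSENT
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    raise DataIntegrityError(f"unrecognised presence value {value!r}")


@dataclass(frozen=True)
class LossEventSet:
    """Mutually non-nested species-tree branches carrying a trait loss."""

    events: tuple[frozenset, ...]

    def __post_init__(self):
        evs = [frozenset(e) for e in self.events]
        for i, a in enumerate(evs):
            for b in evs[i + 1:]:
                if a & b:
                    raise TraitError(
                        f"loss branches are nested/overlapping: {sorted(a)} vs {sorted(b)}"
                    )
        object.__setattr__(self, "events", tuple(evs))

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def nonhost_species(self) -> frozenset:
        out: set = set()
        for e in self.events:
            out |= e
        return frozenset(out)


def validate_trait_map(index: SpeciesTreeIndex, trait_map: Mapping[str, str]) -> None:
    missing = set(index.species) - set(trait_map)
    if missing:
        raise TraitError(f"species without trait assignment: {sorted(missing)}")
    bad = {s: t for s, t in trait_map.items() if t not in (HOST, NONHOST)}
    if bad:
        raise TraitError(f"invalid trait values: {bad}")


def infer_trait_losses(
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    trait_map: Mapping[str, str],
) -> LossEventSet:
    """Dollo reconstruction of independent trait losses.

    With the root fixed to trait-present and regains forbidden, the minimal
    loss set is unique: one loss on the stem branch of every maximal clade
    whose species are all nonhost.  Raises :class:`TraitError` when no host
    species exists (the trait must be present somewhere).
    """
    index = species_tree if isinstance(species_tree, SpeciesTreeIndex) \
        else SpeciesTreeIndex(species_tree)
    validate_trait_map(index, trait_map)
    nonhost = index.presence_vector(trait_map, states=(NONHOST,))
    if not (~nonhost).any():
        raise TraitError("trait absent in every species; no host species")
    if not nonhost.any():
        return LossEventSet(())
    # all-nonhost branches whose parent branch is not all-nonhost
    all_nonhost = (index.masks & ~nonhost).sum(axis=1) == 0
    edge_id = {nd: e for e, nd in enumerate(index.edge_nodes)}
    events = []
    for e, nd in enumerate(index.edge_nodes):
        if not all_nonhost[e]:
            continue
        parent = nd.parent_node
        if parent is index.tree.seed_node or not all_nonhost[edge_id[parent]]:
            events.append(index.clades[e])
    return LossEventSet(tuple(sorted(events, key=lambda c: sorted(c))))


@dataclass
class CoeliminationResult:
    """Per-family coelimination summary (Dollo events vs presence pattern)."""

    family_id: str
    host_retention_fraction: float
    n_independent_colosses: int
    angiosperm_coeliminated: bool
    genus_coeliminated: bool
    focal_present: bool | None = None
    partner_present: bool | None = None
    permutation_p: float | None = None
    host_retention_min: float = 0.75
    k_min: int = 3


def _states_vector(index: SpeciesTreeIndex, presence_row: Mapping[str, object]):
    extra = set(presence_row) - set(index.species)
    missing = set(index.species) - set(presence_row)
    if extra or missing:
        raise DataIntegrityError(
            f"presence row does not match tree species; "
            f"missing={sorted(missing)} extra={sorted(extra)}"
        )
    present = np.zeros(index.n_species, dtype=bool)
    known = np.zeros(index.n_species, dtype=bool)
    for sp, val in presence_row.items():
        st = normalise_presence_state(val)
        i = index.species_index(sp)
        if st != UNKNOWN:
            known[i] = True
            present[i] = st == PRESENT
    return present, known


def _colosses(index, present, known, edge_ids) -> int:
    n = 0
    for e in edge_ids:
        m = index.masks[e] & known
        if m.any() and not (present & m).any():
            n += 1
    return n


def coelimination_score(
    presence_row: Mapping[str, object],
    loss_events: LossEventSet,
    trait_map: Mapping[str, str],
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    family_id: str = "",
    host_retention_min: float = 0.75,
    k_min: int = 3,
    focal_species: str | None = None,
    genus_partner_species: str | None = None,
) -> CoeliminationResult:
    """Score one family's presence pattern against the trait-loss events.

    host_retention_fraction = present hosts / hosts with known state;
    n_independent_colosses counts loss events whose known descendants are
    all absent (events with only unknown descendants are not counted).
    The genus-level call contrasts the declared focal host with its declared
    nonhost genus partner.
    """
    index = species_tree if isinstance(species_tree, SpeciesTreeIndex) \
        else SpeciesTreeIndex(species_tree)
    validate_trait_map(index, trait_map)
    present, known = _states_vector(index, presence_row)
    hosts = index.presence_vector(trait_map, states=(HOST,))
    scored_hosts = hosts & known
    retention = (
        float((present & scored_hosts).sum() / scored_hosts.sum())
        if scored_hosts.any() else float("nan")
    )
    edge_ids = index.edges_for_clades(loss_events)
    n_co = _colosses(index, present, known, edge_ids)
    flag = bool(
        n_co >= k_min
        and np.isfinite(retention)
        and retention >= host_retention_min
    )

    focal_present = partner_present = None
    genus_flag = False
    if focal_species is not None:
        st = normalise_presence_state(presence_row[focal_species])
        focal_present = None if st == UNKNOWN else st == PRESENT
    if genus_partner_species is not None:
        st = normalise_presence_state(presence_row[genus_partner_species])
        partner_present = None if st == UNKNOWN else st == PRESENT
    if focal_present is True and partner_present is False:
        genus_flag = True

    return CoeliminationResult(
        family_id=family_id,
        host_retention_fraction=retention,
        n_independent_colosses=n_co,
        angiosperm_coeliminated=flag,
        genus_coeliminated=genus_flag,
        focal_present=focal_present,
        partner_present=partner_present,
        host_retention_min=host_retention_min,
        k_min=k_min,
    )


def permutation_test(
    presence_row: Mapping[str, object],
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    loss_events: LossEventSet,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the independent co-loss count.

    Null: relocate ``len(loss_events)`` mutually non-nested loss branches
    uniformly at random on the tree and recompute the co-loss count;
    p = (1 + #{null >= observed}) / (1 + n_perm).  Deterministic given seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    index = species_tree if isinstance(species_tree, SpeciesTreeIndex) \
        else SpeciesTreeIndex(species_tree)
    k = len(loss_events)
    if k == 0:
        return 1.0
    present, known = _states_vector(index, presence_row)
    edge_ids = index.edges_for_clades(loss_events)
    obs = _colosses(index, present, known, edge_ids)
    if obs == 0:
        return 1.0
    if rng is None:
        rng = np.random.default_rng(seed)
    # per-edge "all known descendants absent" indicator, reused by every draw
    km = index.masks & known
    co = km.any(axis=1) & ~(index.masks & known & present).any(axis=1)
    sets = index.sample_non_nested_sets(k, n_perm, rng)
    null = co[sets].sum(axis=1)
    return float((1 + int((null >= obs).sum())) / (1 + n_perm))


@dataclass
class ConservationPattern:
    """Two-axis conservation label for one family."""

    family_id: str
    angiosperm_axis: str  # AM-only | conserved-all
    bryophyte_axis: str   # lost-in-nonhost | retained-in-nonhost
    focal_conserved: bool
    out_of_pattern: bool = False

    @property
    def label(self) -> str:
        return f"{self.angiosperm_axis} / {self.bryophyte_axis}"


CORE_PATTERN = f"{AM_ONLY} / {LOST_IN_NONHOST}"


def classify_conservation_pattern(record, coelim: CoeliminationResult) -> ConservationPattern:
    """Combine orthology and coelimination evidence into a pattern label.

    ``record`` is a :class:`~amtoolkit.orthology.FamilyConservationRecord`.
    A family present in the genus nonhost but absent from the focal host is
    flagged out-of-pattern rather than rejected.
    """
    if record.family_id and coelim.family_id and record.family_id != coelim.family_id:
        raise DataIntegrityError(
            f"records refer to different families: "
            f"{record.family_id!r} vs {coelim.family_id!r}"
        )
    ang = AM_ONLY if coelim.angiosperm_coeliminated else CONSERVED_ALL
    bry = LOST_IN_NONHOST if coelim.partner_present is False else RETAINED_IN_NONHOST
    focal_conserved = record.focal_status in {"one_to_one", "proto_ortholog", "multi_copy"}
    out_of_pattern = bool(coelim.partner_present) and coelim.focal_present is False
    return ConservationPattern(
        family_id=record.family_id,
        angiosperm_axis=ang,
        bryophyte_axis=bry,
        focal_conserved=focal_conserved,
        out_of_pattern=out_of_pattern,
    )
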