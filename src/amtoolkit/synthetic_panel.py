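"""Synthetic demonstration panel of 104 mycorrhizal gene families.

This is a constructed, fully synthetic stand-in for a curated per-family
status table: an 18-species land-plant panel (two congeneric liverworts -
the mycorrhizal host focal species and its nonhost sister - a hornwort, a
lycophyte and 14 angiosperms containing four independent nonhost clades)
and 104 gene families whose trees, presence/absence patterns and DE tables
are generated so that the pipeline's own classification rules recover the
headline tallies of the comparative study design it emulates:

* 56 of 104 families with a focal ortholog (49 one-to-one, 16 proto-ortholog,
  9 families carrying both flags);
* 30 families conserved only in mycorrhiza-competent angiosperms, of which
  14 also lost the nonhost-liverwort gene and 16 retained it;
* 28 of the 56 conserved families induced in the focal species, 25 of which
  (89.3%) are also up-regulated in the angiosperm reference;
* a core intersection of ten families (ARK, RAD1, ERF1, RFC, AMT2, DHY,
  STR, STR2, ABCB20a, ABCB20b).

Every number reported by :func:`summarize_panel` is recomputed at run time
from the generated trees and tables; nothing is looked up.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import transcriptomics as tx
from .coelimination import (
    classify_conservation_pattern,
    coelimination_score,
    infer_trait_losses,
)
from .orthology import classify_family, label_duplications, parse_gene_tree
from .phylo import SpeciesTreeIndex, parse_newick_tree

FOCAL = "Mpaleacea"
GENUS_PARTNER = "Mpolymorpha"

BRYO_TOPOLOGY = ((FOCAL, GENUS_PARTNER), "Anthoceros")
ANGIO_TOPOLOGY = (
    "Oryza",
    (
        ((("Arabidopsis", "Brassica"), ("Populus", "Medicago")),
         (("Beta", "Spinacia"), "Solanum")),
        ((("CuscutaA", "CuscutaB"), "Vitis"),
         (("Utricularia", "Genlisea"), "Nicotiana")),
    ),
)
SPECIES_TOPOLOGY = (BRYO_TOPOLOGY, ("Selaginella", ANGIO_TOPOLOGY))

ANGIOSPERMS = (
    "Oryza", "Arabidopsis", "Brassica", "Populus", "Medicago", "Beta",
    "Spinacia", "Solanum", "CuscutaA", "CuscutaB", "Vitis", "Utricularia",
    "Genlisea", "Nicotiana",
)
NONHOSTS = frozenset(
    {GENUS_PARTNER, "Arabidopsis", "Brassica", "Beta", "Spinacia",
     "CuscutaA", "CuscutaB", "Utricularia", "Genlisea"}
)


def _leaves(topo) -> list[str]:
    if isinstance(topo, str):
        return [topo]
    out = []
    for child in topo:
        out.extend(_leaves(child))
    return out


ALL_SPECIES = tuple(_leaves(SPECIES_TOPOLOGY))
HOSTS = tuple(s for s in ALL_SPECIES if s not in NONHOSTS)
TRAIT_MAP = {s: ("nonhost" if s in NONHOSTS else "host") for s in ALL_SPECIES}


def species_tree_newick() -> str:
    def render(topo):
        if isinstance(topo, str):
            return topo
        return "(" + ",".join(render(c) for c in topo) + ")"

    return render(SPECIES_TOPOLOGY) + ";"


# ---------------------------------------------------------------------------
# family design table (synthetic truth used to CONSTRUCT inputs, never read
# back by the summary functions)
# ---------------------------------------------------------------------------

CORE_FAMILIES = ("ARK", "RAD1", "ERF1", "RFC", "AMT2", "DHY",
                 "STR", "STR2", "ABCB20a", "ABCB20b")
PINK_EXTRA = tuple(f"GLF{i:03d}" for i in range(11, 15))            # 4
BLUE_FAMILIES = ("VPYL",) + tuple(f"BLF{i:03d}" for i in range(2, 17))  # 16
CONSERVED_ALL_NAMED = (
    "NOPE1", "AP2A", "DELLA1", "NSP1", "NSP2", "PT4", "HA1", "SUT2",
    "KO", "GA20ox", "CCaMK", "CYCLOPS", "WRI", "MAX1", "CCD8", "ZAS",
)
CONSERVED_ALL = CONSERVED_ALL_NAMED + tuple(f"CAF{i:03d}" for i in range(17, 27))  # 26
NON_CONSERVED = tuple(f"NCF{i:03d}" for i in range(57, 105))        # 48

_BOTH_COPY = {"ARK", "GLF011", "BLF002", "BLF003",
              "CAF017", "CAF018", "CAF019", "CAF020", "CAF021"}      # 9
_PROTO_ONLY = {"BLF004", "BLF005", "CAF022", "CAF023",
               "CAF024", "CAF025", "CAF026"}                         # 7

_FOCAL_UP = set(CORE_FAMILIES) \
    | {f"BLF{i:03d}" for i in range(2, 10)} \
    | {"NOPE1", "KO", "GA20ox", "MAX1", "CCD8", "ZAS", "WRI",
       "CYCLOPS", "CCaMK", "NSP1"}                                   # 28
_NOT_REF_UP = {"NSP1", "CCaMK", "BLF009"}                            # 3 of the 28


def design_table() -> pd.DataFrame:
    """Synthetic per-family design flags (construction truth)."""
    rows = []
    for fam in (CORE_FAMILIES + PINK_EXTRA + BLUE_FAMILIES
                + CONSERVED_ALL + NON_CONSERVED):
        conserved = fam not in NON_CONSERVED
        pink = fam in CORE_FAMILIES or fam in PINK_EXTRA
        blue = fam in BLUE_FAMILIES
        rows.append(
            {
                "family_id": fam,
                "conserved": conserved,
                "copy_class": ("both" if fam in _BOTH_COPY
                               else "proto" if fam in _PROTO_ONLY
                               else "one_to_one" if conserved else "none"),
                "am_only": pink or blue,
                "genus_lost": pink,
                "focal_up": fam in _FOCAL_UP,
                "ref_up": fam in _FOCAL_UP and fam not in _NOT_REF_UP,
            }
        )
    return pd.DataFrame(rows).set_index("family_id")


def _presence_species(fam: str, row) -> set[str]:
    if not row["conserved"]:
        return {"Anthoceros", "Selaginella"} | {s for s in ANGIOSPERMS
                                                if s not in NONHOSTS}
    if row["genus_lost"]:
        return set(HOSTS)
    if row["am_only"]:
        return set(HOSTS) | {GENUS_PARTNER}
    return set(ALL_SPECIES)


def _render(topo, fam, present, suffix="", dup_pm=False):
    if isinstance(topo, str):
        if topo not in present:
            return None
        return f"{topo}|{fam}_{topo}{suffix}"
    if (dup_pm and topo == ("Populus", "Medicago")
            and "Populus" in present and "Medicago" in present):
        a = _render(topo, fam, present, suffix="_1")
        b = _render(topo, fam, present, suffix="_2")
        return f"({a},{b})"
    parts = [p for p in
             (_render(c, fam, present, suffix, dup_pm) for c in topo)
             if p is not None]
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(parts) + ")"


def _join(*parts):
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    return parts[0] if len(parts) == 1 else "(" + ",".join(parts) + ")"


def gene_tree_newick(fam: str, present: set[str], copy_class: str) -> str:
    """Family tree mirroring the species tree over the present species.

    ``copy_class`` both   - the (Populus,Medicago) clade is duplicated, so
    some reference species carry one ortholog and some two;
    ``proto``             - the whole angiosperm clade is duplicated, so
    every present reference species carries two orthologs.
    """
    bryo = _render(BRYO_TOPOLOGY, fam, present)
    sel = _render("Selaginella", fam, present)
    if copy_class == "proto":
        a = _render(ANGIO_TOPOLOGY, fam, present, suffix="_1")
        b = _render(ANGIO_TOPOLOGY, fam, present, suffix="_2")
        angio = _join(a, b) if (a and b) else (a or b)
    else:
        angio = _render(ANGIO_TOPOLOGY, fam, present,
                        dup_pm=(copy_class == "both"))
    tree = _join(bryo, _join(sel, angio))
    return tree + ";"


def _reference_genes(fam: str, copy_class: str) -> list[str]:
    if copy_class in {"both", "proto"}:
        return [f"{fam}_Medicago_1", f"{fam}_Medicago_2"]
    return [f"{fam}_Medicago"]


@dataclass
class PanelData:
    """All synthetic inputs for the 104-family demonstration panel."""

    species_tree_newick: str
    trait_map: dict
    panel_table: pd.DataFrame
    gene_trees: dict
    presence: pd.DataFrame
    focal_de: pd.DataFrame
    reference_de: pd.DataFrame
    ortholog_map: pd.DataFrame
    design: pd.DataFrame


def build_panel() -> PanelData:
    """Construct the full synthetic panel deterministically."""
    design = design_table()
    gene_trees = {}
    presence_rows = {}
    focal_rows, ref_rows, map_rows = [], [], []
    for fam, row in design.iterrows():
        present = _presence_species(fam, row)
        gene_trees[fam] = gene_tree_newick(fam, present, row["copy_class"])
        states = {s: ("present" if s in present else "absent")
                  for s in ALL_SPECIES}
        if fam == "SUT2":
            # presence known only from transcriptome evidence in one taxon
            states["Selaginella"] = "unknown"
            gene_trees[fam] = gene_tree_newick(
                fam, present - {"Selaginella"}, row["copy_class"])
        presence_rows[fam] = states
        if row["conserved"]:
            up = bool(row["focal_up"])
            focal_rows.append(
                {"gene_id": f"{fam}_{FOCAL}",
                 "log2_fold_change": 2.5 if up else 0.3,
                 "p_value": 1e-6 if up else 0.4,
                 "p_adjusted": 1e-5 if up else 0.6}
            )
            refs = _reference_genes(fam, row["copy_class"])
            for i, g in enumerate(refs):
                gup = bool(row["ref_up"]) and i == 0
                ref_rows.append(
                    {"gene_id": g,
                     "log2_fold_change": 2.2 if gup else 0.1,
                     "p_value": 1e-5 if gup else 0.5,
                     "p_adjusted": 1e-4 if gup else 0.7}
                )
            map_rows.append(
                {"family_id": fam, "focal_gene": f"{fam}_{FOCAL}",
                 "reference_genes": ";".join(refs)}
            )
    presence = pd.DataFrame(presence_rows).T[list(ALL_SPECIES)]
    presence.index.name = "family_id"
    panel_table = pd.DataFrame(
        {
            "species": list(ALL_SPECIES),
            "clade": ["bryophyte" if s in {FOCAL, GENUS_PARTNER, "Anthoceros"}
                      else "lycophyte" if s == "Selaginella" else "angiosperm"
                      for s in ALL_SPECIES],
            "trait": [TRAIT_MAP[s] for s in ALL_SPECIES],
            "role": ["focal" if s == FOCAL
                     else "genus_partner" if s == GENUS_PARTNER
                     else "reference" if s in ANGIOSPERMS else "other"
                     for s in ALL_SPECIES],
        }
    )
    return PanelData(
        species_tree_newick=species_tree_newick(),
        trait_map=dict(TRAIT_MAP),
        panel_table=panel_table,
        gene_trees=gene_trees,
        presence=presence,
        focal_de=pd.DataFrame(focal_rows).set_index("gene_id"),
        reference_de=pd.DataFrame(ref_rows).set_index("gene_id"),
        ortholog_map=pd.DataFrame(map_rows),
        design=design,
    )


def write_panel_inputs(panel: PanelData, outdir) -> dict[str, str]:
    """Write every panel input as standard files; returns the path map."""
    from pathlib import Path

    from . import tables as tb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species_tree": str(outdir / "species_tree.nwk"),
        "panel_table": str(outdir / "panel.tsv"),
        "gene_trees": str(outdir / "gene_trees.tsv"),
        "presence_matrix": str(outdir / "presence.tsv"),
        "focal_de_table": str(outdir / "focal_de.tsv"),
        "reference_de_table": str(outdir / "reference_de.tsv"),
        "ortholog_map": str(outdir / "ortholog_map.tsv"),
    }
    Path(paths["species_tree"]).write_text(panel.species_tree_newick + "\n")
    tb.write_table(panel.panel_table, paths["panel_table"])
    tb.write_gene_trees(panel.gene_trees, paths["gene_trees"])
    tb.write_presence_matrix(panel.presence, paths["presence_matrix"])
    tb.write_table(panel.focal_de.reset_index(), paths["focal_de_table"])
    tb.write_table(panel.reference_de.reset_index(), paths["reference_de_table"])
    tb.write_table(panel.ortholog_map, paths["ortholog_map"])
    return paths


def summarize_panel(
    panel: PanelData | None = None,
    k_min: int = 3,
    host_retention_min: float = 0.75,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Run the classification, coelimination and overlay stages on the panel.

    Returns the recomputed headline tallies plus the per-family tables they
    are derived from.
    """
    if panel is None:
        panel = build_panel()
    tree = parse_newick_tree(panel.species_tree_newick)
    index = SpeciesTreeIndex(tree)
    events = infer_trait_losses(index, panel.trait_map)

    records, coelims, patterns = {}, {}, {}
    for fam, nwk in panel.gene_trees.items():
        gt = label_duplications(parse_gene_tree(nwk))
        records[fam] = classify_family(
            gt, fam, FOCAL, GENUS_PARTNER,
            {"angiosperms": ANGIOSPERMS}, list(ALL_SPECIES),
        )
        coelims[fam] = coelimination_score(
            panel.presence.loc[fam].to_dict(), events, panel.trait_map, index,
            family_id=fam, host_retention_min=host_retention_min, k_min=k_min,
            focal_species=FOCAL, genus_partner_species=GENUS_PARTNER,
        )
        patterns[fam] = classify_conservation_pattern(records[fam], coelims[fam])

    conserved = {f for f, r in records.items()
                 if r.focal_status in {"one_to_one", "proto_ortholog", "multi_copy"}}
    n_one = sum(records[f].one_to_one for f in conserved)
    n_proto = sum(records[f].proto_ortholog for f in conserved)
    am_only = {f for f in conserved if coelims[f].angiosperm_coeliminated}
    genus_co = {f for f in am_only if coelims[f].genus_coeliminated}

    focal_called = tx.call_de(panel.focal_de, lfc_threshold, alpha)
    ref_called = tx.call_de(panel.reference_de, lfc_threshold, alpha)
    overlay, summary, unmapped = tx.cross_species_overlay(
        focal_called, ref_called, panel.ortholog_map)
    up_families = set(overlay.index[overlay["focal_call"] == "up"]) & conserved
    core = tx.core_set(patterns, overlay)

    return {
        "n_families": len(panel.gene_trees),
        "n_conserved": len(conserved),
        "n_one_to_one": int(n_one),
        "n_proto_ortholog": int(n_proto),
        "n_am_only": len(am_only),
        "n_genus_coeliminated": len(genus_co),
        "n_am_only_retained": len(am_only - genus_co),
        "n_focal_de": len(up_families),
        "n_conserved_induced": summary.n_conserved_induced,
        "conserved_induced_pct": round(summary.percent, 1),
        "core_set": core,
        "n_trait_loss_events": len(events),
        "records": records,
        "coelimination": coelims,
        "patterns": patterns,
        "overlay": overlay,
        "unmapped": unmapped,
    }
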