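"""Configurable end-to-end pipeline: orthology -> coelimination -> DE overlay.

Inputs are standard files (Newick trees, TSV tables), thresholds and
species-role declarations come from a :class:`PipelineConfig` (optionally a
YAML file), every stage writes its table into the output directory, and a
structured JSON report summarises counts, thresholds, seed and version so
that every reported number is recomputable from the emitted tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import tables as tb
from . import transcriptomics as tx
from .coelimination import (
    classify_conservation_pattern,
    coelimination_score,
    infer_trait_losses,
    permutation_test,
)
from .colonization import colonization_ratio, compare_structures
from .orthology import classify_family, label_duplications, parse_gene_tree
from .phylo import SpeciesTreeIndex, read_newick_tree

log = logging.getLogger("amtoolkit")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths, thresholds and species declarations for a full run."""

    species_tree: str
    panel_table: str
    gene_trees: str
    outdir: str
    presence_matrix: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    focal_de_table: str | None = None
    reference_de_table: str | None = None
    ortholog_map: str | None = None
    observations: str | None = None
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    host_retention_min: float = 0.75
    k_min: int = 3
    n_perm: int = 999
    overlay_rule: str = "any"
    colonization_method: str = "kruskal"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> "PipelineConfig":
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= self.host_retention_min <= 1:
            raise ValueError("host_retention_min must be in [0, 1]")
        if self.k_min < 0 or self.n_perm < 99:
            raise ValueError("k_min must be >= 0 and n_perm >= 99")
        for name in ("species_tree", "panel_table", "gene_trees", "counts",
                     "sample_sheet", "focal_de_table", "reference_de_table",
                     "ortholog_map", "observations", "presence_matrix"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: file not found: {p}")
        return self


def _roles(panel: pd.DataFrame):
    focal = panel.loc[panel["role"] == "focal", "species"].tolist()
    partner = panel.loc[panel["role"] == "genus_partner", "species"].tolist()
    reference = panel.loc[panel["role"] == "reference", "species"].tolist()
    if len(focal) != 1:
        raise PipelineError(f"panel must declare exactly one focal species, got {focal}")
    if len(partner) > 1:
        raise PipelineError(f"panel declares multiple genus partners: {partner}")
    if not reference:
        raise PipelineError("panel declares no reference species")
    return focal[0], (partner[0] if partner else None), reference


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": _version,
        "seed": config.seed,
        "thresholds": {
            "lfc_threshold": config.lfc_threshold,
            "alpha": config.alpha,
            "host_retention_min": config.host_retention_min,
            "k_min": config.k_min,
            "n_perm": config.n_perm,
            "overlay_rule": config.overlay_rule,
        },
        "stages": {},
    }
    report_path = outdir / "report.json"
    stage = "setup"
    t0 = time.perf_counter()
    try:
        tree = read_newick_tree(config.species_tree)
        index = SpeciesTreeIndex(tree)
        panel = tb.read_panel_table(config.panel_table)
        missing = set(panel["species"]) - set(index.species)
        if missing:
            raise PipelineError(f"panel species absent from tree: {sorted(missing)}")
        focal, partner, reference = _roles(panel)
        trait_map = dict(zip(panel["species"], panel["trait"]))
        panel_species = list(panel["species"])

        # ---- orthology ------------------------------------------------
        stage = "orthology"
        trees = tb.read_gene_trees(config.gene_trees)
        records = {}
        for fam in sorted(trees):
            gt = label_duplications(parse_gene_tree(trees[fam]))
            records[fam] = classify_family(
                gt, fam, focal, partner, reference, panel_species)
        cls_df = pd.DataFrame(
            [
                {
                    "family_id": r.family_id,
                    "focal_status": r.focal_status,
                    "one_to_one": r.one_to_one,
                    "proto_ortholog": r.proto_ortholog,
                    "focal_genes": ";".join(r.focal_gene_ids),
                    "absent_in_tree": r.absent_in_tree,
                }
                for r in records.values()
            ]
        )
        tb.write_table(cls_df, outdir / "classification.tsv")
        report["stages"]["orthology"] = {
            "n_families": len(records),
            "n_with_focal_ortholog": int(
                cls_df["focal_status"].isin(
                    ["one_to_one", "proto_ortholog", "multi_copy"]).sum()),
            "n_one_to_one": int(cls_df["one_to_one"].sum()),
            "n_proto_ortholog": int(cls_df["proto_ortholog"].sum()),
        }
        log.info("orthology: %d families classified", len(records))

        # ---- coelimination --------------------------------------------
        stage = "coelimination"
        if config.presence_matrix:
            presence = tb.read_presence_matrix(config.presence_matrix)
        else:
            presence = pd.DataFrame(
                {fam: records[fam].presence for fam in records}).T
            presence.index.name = "family_id"
        events = infer_trait_losses(index, trait_map)
        rng = np.random.default_rng(config.seed)
        co_rows, patterns = [], {}
        for fam in sorted(records):
            row = presence.loc[fam].to_dict()
            co = coelimination_score(
                row, events, trait_map, index, family_id=fam,
                host_retention_min=config.host_retention_min,
                k_min=config.k_min, focal_species=focal,
                genus_partner_species=partner)
            co.permutation_p = permutation_test(
                row, index, events, n_perm=config.n_perm, rng=rng)
            patterns[fam] = classify_conservation_pattern(records[fam], co)
            co_rows.append(
                {
                    "family_id": fam,
                    "host_retention_fraction": co.host_retention_fraction,
                    "n_independent_colosses": co.n_independent_colosses,
                    "angiosperm_coeliminated": co.angiosperm_coeliminated,
                    "genus_coeliminated": co.genus_coeliminated,
                    "permutation_p": co.permutation_p,
                    "pattern": patterns[fam].label,
                    "host_retention_min": config.host_retention_min,
                    "k_min": config.k_min,
                    "n_perm": config.n_perm,
                }
            )
        co_df = pd.DataFrame(co_rows)
        tb.write_table(co_df, outdir / "coelimination.tsv")
        conserved = {f for f, r in records.items() if r.focal_present}
        report["stages"]["coelimination"] = {
            "n_loss_events": len(events),
            "n_angiosperm_coeliminated": int(
                co_df["angiosperm_coeliminated"].sum()),
            "n_am_only_conserved": int(sum(
                co_df.set_index("family_id").loc[f, "angiosperm_coeliminated"]
                for f in conserved)),
            "n_genus_coeliminated": int(co_df["genus_coeliminated"].sum()),
        }
        log.info("coelimination: %d loss events", len(events))

        # ---- differential expression ----------------------------------
        stage = "differential_expression"
        focal_calls = None
        if config.focal_de_table:
            de = tb.read_de_table(config.focal_de_table)
            focal_calls = tx.call_de(de, config.lfc_threshold, config.alpha)
            tb.write_table(focal_calls.reset_index(), outdir / "de_focal.tsv")
        elif config.counts and config.sample_sheet:
            counts = tb.read_counts(config.counts)
            samples = tb.read_sample_sheet(config.sample_sheet)
            per_tp = {}
            for tp in sorted(samples["timepoint"].unique()):
                mock = samples.index[(samples["timepoint"] == tp)
                                     & (samples["condition"] == "mock")]
                col = samples.index[(samples["timepoint"] == tp)
                                    & (samples["condition"] == "colonized")]
                de = tx.adjust_de_table(tx.de_test(counts, mock, col))
                per_tp[tp] = tx.call_de(de, config.lfc_threshold, config.alpha)
                tb.write_table(per_tp[tp].reset_index(), outdir / f"de_{tp}.tsv")
            up_sets = {tp: set(d.index[d["call"] == "up"])
                       for tp, d in per_tp.items()}
            down_sets = {tp: set(d.index[d["call"] == "down"])
                         for tp, d in per_tp.items()}
            if len(per_tp) == 3:
                venn = {"up": tx.venn_counts(up_sets),
                        "down": tx.venn_counts(down_sets)}
                venn_df = pd.DataFrame(
                    [{"direction": d, "region": r, "count": c}
                     for d, regions in venn.items()
                     for r, c in regions.items()])
                tb.write_table(venn_df, outdir / "venn.tsv")
                report["stages"]["venn"] = venn
            # combined per-gene call: induced at any timepoint
            all_genes = counts.index
            call = pd.Series("ns", index=all_genes)
            for tp in per_tp:
                call[call.index.isin(down_sets[tp]) & (call == "ns")] = "down"
            for tp in per_tp:
                call[call.index.isin(up_sets[tp])] = "up"
            focal_calls = pd.DataFrame({"call": call})
            tb.write_table(
                focal_calls.rename_axis("gene_id").reset_index(),
                outdir / "de_focal_combined.tsv")
            report["stages"]["differential_expression"] = {
                tp: {"n_up": len(up_sets[tp]), "n_down": len(down_sets[tp])}
                for tp in per_tp
            }

        # ---- overlay + core set ---------------------------------------
        stage = "overlay"
        if focal_calls is not None and config.reference_de_table \
                and config.ortholog_map:
            ref = tx.call_de(tb.read_de_table(config.reference_de_table),
                             config.lfc_threshold, config.alpha)
            omap = tb.read_ortholog_map(config.ortholog_map)
            overlay, summary, unmapped = tx.cross_species_overlay(
                focal_calls, ref, omap, rule=config.overlay_rule)
            tb.write_table(overlay.reset_index(), outdir / "overlay.tsv")
            core = tx.core_set(patterns, overlay)
            (outdir / "core_set.txt").write_text(
                "\n".join(core) + ("\n" if core else ""))
            report["stages"]["overlay"] = {
                "n_focal_up": summary.n_focal_up,
                "n_conserved_induced": summary.n_conserved_induced,
                "percent_conserved_induced": round(summary.percent, 1)
                if summary.n_focal_up else None,
                "n_unmapped": len(unmapped),
                "core_set": core,
            }
            log.info("overlay: core set of %d families", len(core))

        # ---- colonization ---------------------------------------------
        stage = "colonization"
        if config.observations:
            obs = tb.read_observations(config.observations)
            ratios = colonization_ratio(obs)
            tb.write_table(ratios, outdir / "colonization_ratios.tsv")
            results = compare_structures(
                ratios, method=config.colonization_method, alpha=config.alpha)
            col_rows = []
            for res in results:
                for geno, letter in sorted(res.letters.items()):
                    col_rows.append(
                        {"structure": res.structure, "genotype": geno,
                         "mean": float(np.mean(res.group_values[geno])),
                         "statistic": res.statistic, "p_value": res.p_value,
                         "letters": letter, "method": res.method,
                         "alpha": res.alpha})
            tb.write_table(pd.DataFrame(col_rows),
                           outdir / "colonization_stats.tsv")
            report["stages"]["colonization"] = {
                res.structure: {"statistic": res.statistic,
                                "p_value": res.p_value,
                                "letters": res.letters}
                for res in results
            }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        raise
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
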