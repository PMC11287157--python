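"""Table round trips, schema validation, the pipeline and the CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from amtoolkit import tables as tb
from amtoolkit.cli import main as cli_main
from amtoolkit.pipeline import PipelineConfig, run_pipeline
from amtoolkit.simulate import simulate_colonization_observations
from amtoolkit.synthetic_panel import build_panel, write_panel_inputs


class TestTables:
    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("species\tvalue\nA\t1\n")
        with pytest.raises(tb.SchemaError, match="trait"):
            tb.read_table(p, required=("species", "trait"))

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("family_id\tx\nf1\t1\nf1\t2\n")
        with pytest.raises(tb.SchemaError, match="duplicate"):
            tb.read_table(p, required=("family_id",), key="family_id")

    def test_missing_file_named_before_compute(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            tb.read_table(tmp_path / "nope.tsv")

    def test_presence_matrix_round_trip_with_na_tokens(self, tmp_path):
        rng = np.random.default_rng(4)
        species = [f"sp{i}" for i in range(6)]
        states = rng.choice(["present", "absent", "unknown"], size=(10, 6))
        mat = pd.DataFrame(states, columns=species,
                           index=pd.Index([f"f{i}" for i in range(10)],
                                          name="family_id"))
        p = tmp_path / "m.tsv"
        tb.write_presence_matrix(mat, p)
        back = tb.read_presence_matrix(p)
        assert back.equals(mat)
        # NA token maps to the unknown state
        p2 = tmp_path / "m2.tsv"
        p2.write_text("family_id\tspA\tspB\nf1\tNA\t1\n")
        m2 = tb.read_presence_matrix(p2)
        assert m2.loc["f1", "spA"] == "unknown"
        assert m2.loc["f1", "spB"] == "present"

    def test_trait_table_round_trip(self, tmp_path):
        tm = {"A": "host", "B": "nonhost"}
        p = tmp_path / "traits.tsv"
        tb.write_trait_table(tm, p)
        assert tb.read_trait_table(p) == tm

    def test_counts_round_trip_and_validation(self, tmp_path):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(8, 4)),
            index=pd.Index([f"g{i}" for i in range(8)], name="gene_id"),
            columns=[f"s{i}" for i in range(4)])
        p = tmp_path / "c.tsv"
        tb.write_table(counts.reset_index(), p)
        assert tb.read_counts(p).equals(counts)
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene_id\ts1\ng1\t-3\n")
        with pytest.raises(tb.SchemaError, match="non-negative"):
            tb.read_counts(bad)


@pytest.fixture(scope="module")
def panel_run(tmp_path_factory):
    """Panel inputs on disk plus one completed pipeline run."""
    root = tmp_path_factory.mktemp("panelrun")
    panel = build_panel()
    paths = write_panel_inputs(panel, root / "inputs")
    obs = simulate_colonization_observations(
        {"wild_type": {"vesicles": 0.8, "arbuscules": 0.9},
         "ark": {"vesicles": 0.3, "arbuscules": 0.4}},
        n_reps=6, seed=3)
    obs_path = root / "inputs" / "observations.tsv"
    tb.write_table(obs, obs_path)
    config = PipelineConfig(
        outdir=str(root / "out"), observations=str(obs_path),
        n_perm=99, seed=7, **paths)
    report = run_pipeline(config)
    return panel, paths, obs_path, config, report, root


class TestPipeline:
    def test_report_contains_every_stage_and_core_set(self, panel_run):
        panel, paths, obs_path, config, report, root = panel_run
        assert report["stages"]["orthology"]["n_with_focal_ortholog"] == 56
        assert report["stages"]["coelimination"]["n_am_only_conserved"] == 30
        assert report["stages"]["overlay"]["core_set"] == sorted(
            ["ARK", "RAD1", "ERF1", "RFC", "AMT2", "DHY", "STR", "STR2",
             "ABCB20a", "ABCB20b"])
        assert "colonization" in report["stages"]
        assert (Path(config.outdir) / "coelimination.tsv").exists()

    def test_summary_numbers_recomputable_from_emitted_tables(self, panel_run):
        panel, paths, obs_path, config, report, root = panel_run
        co = pd.read_csv(Path(config.outdir) / "coelimination.tsv", sep="\t")
        cls = pd.read_csv(Path(config.outdir) / "classification.tsv", sep="\t")
        conserved = set(cls.loc[cls["focal_status"].isin(
            ["one_to_one", "proto_ortholog", "multi_copy"]), "family_id"])
        n_am_only = int(co.loc[co["family_id"].isin(conserved),
                               "angiosperm_coeliminated"].sum())
        assert n_am_only == report["stages"]["coelimination"]["n_am_only_conserved"]
        overlay = pd.read_csv(Path(config.outdir) / "overlay.tsv", sep="\t")
        assert int(overlay["conserved_induced"].sum()) \
            == report["stages"]["overlay"]["n_conserved_induced"]

    def test_same_seed_runs_are_byte_identical(self, panel_run):
        panel, paths, obs_path, config, report, root = panel_run
        cfg2 = PipelineConfig(**{**config.__dict__, "outdir": str(root / "out2")})
        run_pipeline(cfg2)
        for f in sorted(Path(config.outdir).iterdir()):
            other = Path(cfg2.outdir) / f.name
            assert other.read_bytes() == f.read_bytes(), f.name

    def test_threshold_limits_match_direct_set_computation(self, panel_run):
        """k_min=0, alpha=1: core equals the directly computed intersection."""
        panel, paths, obs_path, config, report, root = panel_run
        cfg = PipelineConfig(**{**config.__dict__, "outdir": str(root / "out3"),
                                "k_min": 0, "alpha": 1.0})
        rep = run_pipeline(cfg)
        # independent route: straight from the input tables
        focal_de = tb.read_de_table(paths["focal_de_table"])
        ref_de = tb.read_de_table(paths["reference_de_table"])
        omap = tb.read_ortholog_map(paths["ortholog_map"])
        pres = tb.read_presence_matrix(paths["presence_matrix"])
        hosts = [s for s, t in panel.trait_map.items() if t == "host"]
        expected = set()
        for _, r in omap.iterrows():
            fam = r["family_id"]
            f_up = (focal_de.loc[r["focal_gene"], "log2_fold_change"] > 1
                    and focal_de.loc[r["focal_gene"], "p_adjusted"] < 1)
            refs = r["reference_genes"].split(";")
            r_up = any(ref_de.loc[g, "log2_fold_change"] > 1
                       and ref_de.loc[g, "p_adjusted"] < 1 for g in refs)
            retention = float((pres.loc[fam, hosts] == "present").mean())
            partner_lost = pres.loc[fam, "Mpolymorpha"] == "absent"
            focal_present = pres.loc[fam, "Mpaleacea"] == "present"
            if f_up and r_up and partner_lost and focal_present \
                    and retention >= 0.75:
                expected.add(fam)
        assert set(rep["stages"]["overlay"]["core_set"]) == expected

    def test_missing_input_named_before_any_computation(self, panel_run, tmp_path):
        panel, paths, obs_path, config, report, root = panel_run
        cfg = PipelineConfig(**{**config.__dict__,
                                "species_tree": str(tmp_path / "ghost.nwk")})
        with pytest.raises(FileNotFoundError, match="ghost.nwk"):
            run_pipeline(cfg)
        assert not (tmp_path / "out").exists()


class TestCli:
    def test_simulate_writes_all_inputs(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "simulate", "--n-species", "12", "--n-trait-losses", "2",
            "--n-families", "30", "--n-genes", "40", "--seed", "11",
            "--out", str(tmp_path / "sim")])
        assert res.exit_code == 0, res.output
        for name in ("species_tree.nwk", "traits.tsv", "presence.tsv",
                     "counts.tsv", "samples.tsv", "run_manifest.json",
                     "family_truth.tsv", "gene_truth.tsv"):
            assert (tmp_path / "sim" / name).exists(), name
        manifest = json.loads((tmp_path / "sim" / "run_manifest.json").read_text())
        assert manifest["config"]["seed"] == 11

    def test_coelim_without_species_tree_names_the_file(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "coelim", "--species-tree", str(tmp_path / "missing.nwk"),
            "--panel", str(tmp_path / "p.tsv"),
            "--presence", str(tmp_path / "m.tsv"),
            "--out", str(tmp_path / "o.tsv")])
        assert res.exit_code != 0
        assert "missing.nwk" in res.output

    def test_unknown_flag_gives_usage_error(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--frobnicate", "1"])
        assert res.exit_code == 2
        assert "no such option" in res.output.lower()

    def test_full_run_from_yaml_config(self, panel_run, tmp_path):
        import yaml

        panel, paths, obs_path, config, report, root = panel_run
        cfg = {**paths, "outdir": str(tmp_path / "cli_out"),
               "observations": str(obs_path), "n_perm": 99, "seed": 1}
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["all", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        rep = json.loads((tmp_path / "cli_out" / "report.json").read_text())
        assert len(rep["stages"]["overlay"]["core_set"]) == 10
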