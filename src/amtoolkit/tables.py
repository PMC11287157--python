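"""Tab-separated readers/writers for every pipeline table.

All interchange tables are TSV with a mandatory header row; extra columns
are preserved, missing required columns are fatal and named.  Presence
matrices map the tokens present/1 -> present, absent/0 -> absent and
NA/empty/? -> unknown.  Trees travel as Newick.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coelimination import normalise_presence_state


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(
    path,
    required: Sequence[str] = (),
    key: str | None = None,
) -> pd.DataFrame:
    """Read a TSV with header; validate required columns and key uniqueness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if key is not None:
        dup = df[key][df[key].duplicated()]
        if len(dup):
            raise SchemaError(
                f"{path}: duplicate {key} value(s): {sorted(set(dup))[:5]}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# -- specific table types -------------------------------------------------

def read_trait_table(path) -> dict[str, str]:
    df = read_table(path, required=("species", "trait"), key="species")
    return dict(zip(df["species"], df["trait"]))


def write_trait_table(trait_map: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        {"species": list(trait_map), "trait": [trait_map[s] for s in trait_map]}
    ).sort_values("species")
    write_table(df, path)


def read_presence_matrix(path) -> pd.DataFrame:
    """family_id x species matrix with present/absent/unknown states."""
    df = read_table(path, required=("family_id",), key="family_id")
    df = df.set_index("family_id")
    try:
        return df.map(normalise_presence_state)
    except AttributeError:  # pandas < 2.1
        return df.applymap(normalise_presence_state)


def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    write_table(matrix.reset_index(), path)


def read_counts(path) -> pd.DataFrame:
    df = read_table(path, required=("gene_id",), key="gene_id").set_index("gene_id")
    try:
        out = df.astype(np.int64)
    except ValueError as exc:
        raise SchemaError(f"{path}: counts must be integers ({exc})") from exc
    if (out < 0).any().any():
        raise SchemaError(f"{path}: counts must be non-negative")
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    df = read_table(
        path, required=("sample_id", "condition", "timepoint", "replicate"),
        key="sample_id",
    )
    return df.set_index("sample_id")


def read_de_table(path) -> pd.DataFrame:
    df = read_table(
        path, required=("gene_id", "log2_fold_change", "p_adjusted"), key="gene_id"
    ).set_index("gene_id")
    df["log2_fold_change"] = df["log2_fold_change"].astype(float)
    df["p_adjusted"] = df["p_adjusted"].replace("", "nan").astype(float)
    if "p_value" in df.columns:
        df["p_value"] = df["p_value"].astype(float)
    return df


def read_ortholog_map(path) -> pd.DataFrame:
    return read_table(
        path, required=("family_id", "focal_gene", "reference_genes"),
        key="family_id",
    )


def read_observations(path) -> pd.DataFrame:
    df = read_table(
        path,
        required=("replicate", "genotype", "structure", "position", "observed"),
    )
    df["position"] = df["position"].astype(int)
    df["observed"] = df["observed"].astype(int)
    return df


def read_panel_table(path) -> pd.DataFrame:
    """Species panel: species, clade, trait, role (focal/genus_partner/reference/other)."""
    return read_table(path, required=("species", "clade", "trait", "role"), key="species")


def read_gene_trees(path) -> dict[str, str]:
    """Gene trees as family_id -> Newick.

    Accepts either a directory of ``<family_id>.nwk`` files or a two-column
    TSV (family_id, newick).
    """
    path = Path(path)
    if path.is_dir():
        out = {}
        for f in sorted(path.glob("*.nwk")):
            out[f.stem] = f.read_text().strip()
        if not out:
            raise FileNotFoundError(f"no *.nwk files in {path}")
        return out
    df = read_table(path, required=("family_id", "newick"), key="family_id")
    return dict(zip(df["family_id"], df["newick"]))


def write_gene_trees(trees: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        {"family_id": list(trees), "newick": [trees[k].strip() for k in trees]}
    )
    write_table(df, path)
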