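"""Readers and writers for the plain-text exchange formats.

Count tables are stored on disk as taxa (rows) x samples (columns) TSV —
the layout amplicon workflows usually export — but held in memory as a
pandas DataFrame with samples as rows and taxa as columns, which is the
orientation every function in this package expects.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from skbio import TreeNode

REQUIRED_METADATA_COLUMNS = ("sample_id", "role", "group")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples TSV into a samples x taxa integer DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.T
    counts.index.name = "sample_id"
    counts.columns.name = "taxon_id"
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x taxa DataFrame as a taxa x samples TSV."""
    out = counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_counts_biom_json(path: str | Path) -> pd.DataFrame:
    """Read a dense BIOM-style JSON table (rows = taxa, columns = samples)."""
    with open(path) as fh:
        obj = json.load(fh)
    taxa = [row["id"] for row in obj["rows"]]
    samples = [col["id"] for col in obj["columns"]]
    data = obj["data"]
    df = pd.DataFrame(data, index=taxa, columns=samples)
    counts = df.T
    counts.index.name = "sample_id"
    counts.columns.name = "taxon_id"
    return counts


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; requires sample_id/role/group columns."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks required columns: {missing}")
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_copy_numbers(path: str | Path) -> pd.Series:
    """Read a (taxon_id, copy_number) TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    if not {"taxon_id", "copy_number"}.issubset(df.columns):
        raise ValueError("copy-number table needs columns taxon_id and copy_number")
    series = df.set_index("taxon_id")["copy_number"].astype(float)
    if (series < 1).any():
        raise ValueError("operon copy numbers must be >= 1")
    return series


def write_copy_numbers(copy_numbers: pd.Series, path: str | Path) -> None:
    df = copy_numbers.rename("copy_number").rename_axis("taxon_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
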