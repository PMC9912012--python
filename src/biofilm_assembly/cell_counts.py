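"""qPCR copy-number to cell-number conversion (community-average correction).

qPCR of the 16S rRNA gene counts gene copies, not cells; genomes carry
1–15+ rRNA operons. Dividing the qPCR total by a community-average copy
number Ĉ — the abundance-weighted mean of per-taxon operon counts looked
up by taxonomic match — converts copies to cells, which supply the local
community size N_T for migration-rate estimation.

Two weightings of Ĉ are offered. The arithmetic mean over read-based
relative abundances (Ĉ = Σ f̃_i c_i) is the form the standard workflow
uses, but read abundances are themselves copy-number-weighted, so it
overestimates the per-cell mean by a factor 1 + CV²(c) and hence
underestimates cells. The harmonic mean (Ĉ = 1/Σ f̃_i/c_i) undoes that
weighting exactly and recovers cell numbers perfectly when the copy
numbers are exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WEIGHTINGS = ("arithmetic", "harmonic")


def lookup_copy_numbers(
    taxa, copy_table: pd.Series, fallback: float | None = None
) -> pd.Series:
    """Look up per-taxon copy numbers with rank fallback.

    Taxon identifiers may be semicolon-delimited taxonomy paths
    ("Phylum;Family;Genus"); a miss walks up the path one rank at a time
    before falling back to the table's global mean (or `fallback`).
    """
    if copy_table.empty:
        raise ValueError("copy-number table is empty")
    if fallback is None:
        fallback = float(copy_table.mean())
    out = {}
    for taxon in taxa:
        key = str(taxon)
        value = None
        while True:
            if key in copy_table.index:
                value = float(copy_table[key])
                break
            if ";" not in key:
                break
            key = key.rsplit(";", 1)[0]
        out[taxon] = fallback if value is None else value
    return pd.Series(out, name="copy_number")


def community_avg_copy_number(
    rel_abund: pd.Series,
    copy_table: pd.Series,
    fallback: float | None = None,
    weighting: str = "arithmetic",
) -> float:
    """Community-average 16S copy number Ĉ for one sample."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    f = rel_abund[rel_abund > 0]
    if abs(float(f.sum()) - 1.0) > 1e-6:
        raise ValueError("relative abundances must sum to 1")
    c = lookup_copy_numbers(f.index, copy_table, fallback=fallback)
    fv = f.to_numpy(dtype=float)
    cv = c.to_numpy(dtype=float)
    if weighting == "arithmetic":
        return float(np.sum(fv * cv))
    return float(1.0 / np.sum(fv / cv))


def copies_to_cells(total_copies: float, avg_copy_number: float) -> float:
    """Convert a qPCR gene-copy total into a cell number."""
    if total_copies <= 0 or avg_copy_number <= 0:
        raise ValueError("total_copies and avg_copy_number must be > 0")
    return total_copies / avg_copy_number


def estimate_cells(
    counts: pd.DataFrame,
    qpcr_totals: pd.Series,
    copy_table: pd.Series,
    weighting: str = "arithmetic",
) -> pd.DataFrame:
    """Per-sample cell-number estimates from read counts and qPCR totals."""
    rows = []
    for sample in counts.index:
        total = qpcr_totals.get(sample, np.nan)
        if not np.isfinite(total) or total <= 0:
            continue
        row = counts.loc[sample]
        rel = row / row.sum()
        c_bar = community_avg_copy_number(rel, copy_table, weighting=weighting)
        rows.append(
            {
                "sample_id": sample,
                "total_copies": float(total),
                "avg_copy_number": c_bar,
                "cells": copies_to_cells(float(total), c_bar),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["total_copies", "avg_copy_number", "cells"]
    )
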