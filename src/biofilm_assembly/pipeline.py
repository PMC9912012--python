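"""End-to-end analysis pipeline: rarefy → NCM → cells → SES → ordination.

Every stage is a pure function of (inputs, config, seed); stage seeds are
derived from one master seed by hashing the stage name, so re-running a
single stage from saved intermediates reproduces its section of the
report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cell_counts as cc
from . import io as pkgio
from . import ncm, ordination, phylo

log = logging.getLogger("biofilm_assembly")


def auto_depth(counts: pd.DataFrame) -> int:
    """Rarefaction depth = the smallest sample total."""
    if counts.empty:
        raise ValueError("empty count table")
    return int(counts.sum(axis=1).min())


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to exactly `depth` reads without replacement.

    Samples with fewer than `depth` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(counts.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    kept = counts.loc[keep]
    rng = np.random.default_rng(seed)
    rows = [
        rng.multivariate_hypergeometric(row.astype(np.int64), depth)
        for row in kept.to_numpy()
    ]
    return pd.DataFrame(np.vstack(rows), index=kept.index, columns=kept.columns)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the full analysis and write every intermediate under out_dir.

    Config keys: counts, tree, metadata (paths; required); copy_table
    (path, optional); depth (int or "auto"); runs, samples_per_run
    (replicate NCM scheme); n_null; normalized_unifrac; alpha.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "version": __version__,
        }
    }

    counts_path = str(config["counts"])
    if counts_path.endswith(".json"):
        counts = pkgio.read_counts_biom_json(counts_path)
    else:
        counts = pkgio.read_counts(counts_path)
    tree = pkgio.read_tree(config["tree"])
    metadata = pkgio.read_metadata(config["metadata"])

    unknown = set(counts.index) - set(metadata["sample_id"])
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    tree_tips = {t.name for t in tree.tips()}
    off_tree = set(counts.columns) - tree_tips
    if off_tree:
        raise ValueError(f"taxa absent from the tree: {sorted(off_tree)[:5]}...")

    depth_cfg = config.get("depth", "auto")
    depth = auto_depth(counts) if depth_cfg in (None, "auto") else int(depth_cfg)
    counts = rarefy(counts, depth, seed=stage_seed(seed, "rarefy"))
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    pkgio.write_counts(counts, out / "rarefied_counts.tsv")
    metadata = metadata.loc[metadata["sample_id"].isin(counts.index)]
    report["rarefaction"] = {"depth": depth, "n_samples": int(counts.shape[0])}
    log.info("rarefied %d samples to depth %d", counts.shape[0], depth)

    meta = metadata.set_index("sample_id", drop=False)
    source_ids = list(meta.index[meta["role"] == "source"])
    target_meta = meta.loc[meta["role"] == "target"]
    if len(source_ids) < 2 or len(target_meta) < 2:
        raise ValueError("need at least 2 source and 2 target samples")
    source = counts.loc[source_ids]
    groups = {g: list(m.index) for g, m in target_meta.groupby("group")}

    # --- neutral community model, overall and per group -------------------
    scheme = ncm.ReplicateScheme(
        n_runs=int(config.get("runs", 10)),
        samples_per_run=int(config.get("samples_per_run", 5)),
    )
    alpha = float(config.get("alpha", 0.05))
    ncm_dir = out / "ncm"
    ncm_dir.mkdir(exist_ok=True)
    report["ncm"] = {}
    ncm_runs: dict[str, ncm.ReplicatedNCMFit] = {}

    def _fit_group(label: str, target_ids: list, strata=None):
        target = counts.loc[target_ids]
        spr = min(scheme.samples_per_run, len(target_ids))
        local = ncm.ReplicateScheme(n_runs=scheme.n_runs, samples_per_run=spr)
        rep = ncm.run_replicated(
            source,
            target,
            local,
            seed=stage_seed(seed, f"ncm:{label}"),
            depth=depth,
            alpha=alpha,
            strata=strata,
        )
        rep.per_taxon.to_csv(ncm_dir / f"{label}_per_taxon.tsv", sep="\t")
        with open(ncm_dir / f"{label}_summary.json", "w") as fh:
            json.dump(rep.summary(), fh, indent=1)
        report["ncm"][label] = rep.summary()
        ncm_runs[label] = rep

    all_targets = [s for ids in groups.values() for s in ids]
    strata = target_meta["group"] if len(groups) > 1 else None
    _fit_group("all", all_targets, strata=strata)
    if len(groups) > 1:
        for g, ids in groups.items():
            if len(ids) >= 2:
                _fit_group(g, ids)

    # --- cell counts and migration rates ----------------------------------
    have_qpcr = (
        "qpcr_copies" in meta.columns
        and meta.loc[all_targets, "qpcr_copies"].notna().any()
        and config.get("copy_table")
    )
    if have_qpcr:
        copy_table = pkgio.read_copy_numbers(config["copy_table"])
        cells = cc.estimate_cells(
            counts.loc[all_targets],
            meta["qpcr_copies"],
            copy_table,
            weighting=config.get("copy_weighting", "arithmetic"),
        )
        cells.to_csv(out / "cell_counts.tsv", sep="\t")
        report["migration"] = {}
        for label, rep in ncm_runs.items():
            ids = all_targets if label == "all" else groups[label]
            ids = [s for s in ids if s in cells.index]
            if not ids:
                continue
            n_t = float(cells.loc[ids, "cells"].mean())
            area = None
            if "surface_area_cm2" in meta.columns:
                vals = meta.loc[ids, "surface_area_cm2"].dropna()
                area = float(vals.mean()) if len(vals) else None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = ncm.migration_rates(rep.ntm, depth, n_t, surface_area=area)
            report["migration"][label] = est.summary()
        with open(out / "migration.json", "w") as fh:
            json.dump(report["migration"], fh, indent=1)
    else:
        log.warning("no qPCR totals or copy table: skipping cell/migration stages")
        report["migration"] = None

    # --- SES phylogenetic metrics -----------------------------------------
    n_null = int(config.get("n_null", phylo.DEFAULT_N_NULL))
    metrics = config.get("ses_metrics", ["pd", "mpd", "mntd"])
    report["ses"] = {}
    for comparison in ("vs_source", "within_group"):
        for metric in metrics:
            res = phylo.ses_metric(
                metric,
                counts,
                tree,
                metadata,
                comparison,
                n_null=n_null,
                seed=stage_seed(seed, f"ses:{comparison}:{metric}"),
            )
            res.to_csv(out / f"ses_{comparison}_{metric}.tsv", sep="\t", index=False)
            report["ses"][f"{comparison}:{metric}"] = {
                "n_units": int(len(res)),
                "median_ses": float(res["ses"].median()),
                "frac_significant": float(res["significant"].mean()),
            }

    # --- ordination --------------------------------------------------------
    ord_dir = out / "ordination"
    ord_dir.mkdir(exist_ok=True)
    dp = ordination.dpcoa(counts, tree)
    dp.sample_coords.to_csv(ord_dir / "dpcoa_samples.tsv", sep="\t")
    dp.taxon_coords.to_csv(ord_dir / "dpcoa_taxa.tsv", sep="\t")
    with open(ord_dir / "dpcoa_eigenvalues.json", "w") as fh:
        json.dump(
            {
                "eigenvalues": dp.eigenvalues.tolist(),
                "axis_variance_fraction": dp.axis_variance_fraction.tolist(),
            },
            fh,
            indent=1,
        )
    wu = ordination.weighted_unifrac_matrix(
        counts, tree, normalized=bool(config.get("normalized_unifrac", False))
    )
    wu.to_csv(ord_dir / "weighted_unifrac.tsv", sep="\t")
    report["ordination"] = {
        "axis_variance_fraction": dp.axis_variance_fraction[:5].tolist()
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
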