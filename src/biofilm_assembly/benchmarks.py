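"""Reproducible desk-scale validation experiments.

Each function runs one self-contained simulation experiment against the
package's own generators and estimators and returns plain numbers:
parameter recovery of the neutral-model fit, calibration of the
neutral/above/below partition, selection detection, the Moran simulator
against its exactly solved small chain, and the calibration and
directional behaviour of the richness-null SES metrics. They are used by
the test suite and the reproduction script; all randomness derives from
the single `seed` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ncm import classify_taxa, fit_ncm, fit_ntm
from .phylo import richness_null, ses_beta, ses_pd
from .simulate import (
    SimulationConfig,
    apply_selection_regime,
    assemble_dirichlet,
    assemble_moran,
    make_source_pool,
    moran_occupancy,
    moran_stationary_exact,
    sequence_communities,
    sequence_source_samples,
    simulate_phylogeny,
)

_MOD = 2**31


def _sub(seed: int, k: int) -> int:
    return (seed * 10_007 + k) % _MOD


def ncm_recovery(
    seed: int = 0,
    ntm_values: tuple = (50, 500, 5000),
    n_reps: int = 10,
    n_taxa: int = 500,
    n_communities: int = 30,
    depth: int = 10_000,
) -> dict:
    """Median fitted N_T·m over `n_reps` stationary-model simulations.

    Communities are drawn from the model's own stationary distribution
    (Dirichlet compositions) and occurrence is scored by thresholding the
    composition at the detection limit d = 1/depth — the detection
    process the beta-CDF model assumes — so the experiment measures
    parameter recovery of the estimator itself.
    """
    pool = make_source_pool(n_taxa, seed=_sub(seed, 11))
    p = pool.rel_abundance
    d = 1.0 / depth
    cells = 1_000_000
    out = {}
    for ntm in ntm_values:
        fits = []
        for r in range(n_reps):
            ens = assemble_dirichlet(
                pool, ntm, n_communities, seed=_sub(seed, 100 + r), community_size=cells
            )
            rel = ens.counts.to_numpy() / cells
            obs = (rel > d).mean(axis=0)
            keep = obs > 0
            fits.append(fit_ntm(obs[keep], p[keep], d)["ntm"])
        out[ntm] = float(np.median(fits))
    return out


def ncm_recovery_reads(
    seed: int = 0,
    ntm: float = 500,
    n_reps: int = 10,
    n_taxa: int = 500,
    n_communities: int = 30,
    depth: int = 10_000,
) -> float:
    """Median fitted N_T·m when detection runs through multinomial reads.

    Finite-depth sequencing smooths the detection indicator
    (P(detect) = 1 − (1−x)^depth instead of 1{x > d}), which biases the
    threshold-model fit upward; this function quantifies that bias.
    """
    pool = make_source_pool(n_taxa, seed=_sub(seed, 11))
    copy_numbers = pd.Series(1.0, index=list(pool.taxon_ids))
    fits = []
    for r in range(n_reps):
        ens = assemble_dirichlet(
            pool, ntm, n_communities, seed=_sub(seed, 100 + r), community_size=1_000_000
        )
        target, _ = sequence_communities(ens, depth, copy_numbers, seed=_sub(seed, 300 + r))
        source = sequence_source_samples(pool, 5, depth, copy_numbers, seed=_sub(seed, 500 + r))
        fits.append(fit_ncm(source, target, depth=depth).ntm)
    return float(np.median(fits))


def neutral_calibration(
    seed: int = 0,
    ntm: float = 200.0,
    n_reps: int = 5,
    n_taxa: int = 500,
    n_communities: int = 30,
    depth: int = 10_000,
) -> dict:
    """False-positive rate of the taxon partition under exact neutrality.

    Fully neutral stationary communities are classified against the
    fitted model; with a calibrated band the non-neutral fraction should
    sit near the nominal alpha = 0.05. Averaged over `n_reps` replicate
    simulations.
    """
    pool = make_source_pool(n_taxa, seed=_sub(seed, 11))
    p = pool.rel_abundance
    d = 1.0 / depth
    cells = 1_000_000
    fracs, rhos, ns = [], [], []
    for r in range(n_reps):
        ens = assemble_dirichlet(
            pool, ntm, n_communities, seed=_sub(seed, 700 + r), community_size=cells
        )
        rel = ens.counts.to_numpy() / cells
        obs = (rel > d).mean(axis=0)
        keep = (obs > 0) & (p > 0)
        fit = fit_ntm(obs[keep], p[keep], d)
        labels, _, _ = classify_taxa(obs[keep], fit["predicted_freq"], n_communities)
        fracs.append(float((labels != "neutral").mean()))
        rhos.append(fit["spearman_rho"])
        ns.append(int(keep.sum()))
    return {
        "nonneutral_fraction": float(np.mean(fracs)),
        "spearman_rho": float(np.mean(rhos)),
        "n_modelled": float(np.mean(ns)),
        "n_reps": n_reps,
    }


def selection_detection(seed: int = 0, n_taxa: int = 500) -> dict:
    """Habitat filtering versus a matched neutral run, full read path.

    Runs the Moran assembler under the default habitat-filter regime
    (fitness 5 on a ~10% clade) and a matched neutral run, sequences both,
    fits the neutral model against sequenced influent samples, and
    reports how strongly the "above" class is enriched in the truly
    favoured taxa, together with the fit quality of both runs.
    """
    pool = make_source_pool(n_taxa, seed=_sub(seed, 11))
    tree = simulate_phylogeny(n_taxa, seed=_sub(seed, 11))
    copy_numbers = pd.Series(1.0, index=list(pool.taxon_ids))
    cfg = SimulationConfig(n_taxa=n_taxa, selection_regime="habitat_filter", seed=_sub(seed, 23))
    source = sequence_source_samples(
        pool, 5, cfg.sequencing_depth, copy_numbers, seed=_sub(seed, 29)
    )

    fitness = apply_selection_regime(pool, tree, cfg)
    ens_sel = assemble_moran(pool, cfg, fitness)
    target_sel, _ = sequence_communities(
        ens_sel, cfg.sequencing_depth, copy_numbers, seed=_sub(seed, 31)
    )
    fit_sel = fit_ncm(source, target_sel, depth=cfg.sequencing_depth)

    cfg_neu = dataclasses.replace(cfg, selection_regime="neutral")
    ens_neu = assemble_moran(pool, cfg_neu)
    target_neu, _ = sequence_communities(
        ens_neu, cfg.sequencing_depth, copy_numbers, seed=_sub(seed, 31)
    )
    fit_neu = fit_ncm(source, target_neu, depth=cfg.sequencing_depth)

    favoured = set(np.array(pool.taxon_ids)[fitness[0] > 1])
    above = fit_sel.per_taxon["classification"] == "above"
    in_fav = fit_sel.per_taxon.index.isin(favoured)
    frac_fav = float(in_fav.mean())
    enrichment = (
        float((above & in_fav).sum()) / max(int(above.sum()), 1) / frac_fav
        if frac_fav > 0
        else np.nan
    )
    return {
        "above_enrichment_in_favoured": enrichment,
        "rho_selected": fit_sel.spearman_rho,
        "rho_neutral": fit_neu.spearman_rho,
        "n_above": int(above.sum()),
        "n_modelled": fit_sel.n_modelled,
    }


def moran_chain_tv(
    seed: int = 0,
    community_size: int = 10,
    migration_rate: float = 0.1,
    n_events: int = 1_000_000,
    burn_in: int = 100_000,
) -> float:
    """Total-variation distance of the simulator's occupancy from exact.

    The 3-taxon, N_T=10 Moran chain has only 66 states, so its stationary
    distribution can be solved exactly; the simulator's post-burn-in
    occupancy frequencies are compared against it. The event count is
    sized from the chain's autocorrelation so the sampling error of the
    TV estimate itself stays well below the tolerance it is judged by.
    """
    p = np.array([0.5, 0.3, 0.2])
    exact = moran_stationary_exact(p, community_size, migration_rate)
    occ = moran_occupancy(
        p, community_size, migration_rate, n_events, burn_in=burn_in, seed=_sub(seed, 41)
    )
    tv = 0.0
    for (c0, c1, _c2), prob in exact.items():
        tv += abs(occ[c0, c1] - prob)
    return float(tv / 2.0)


def ses_self_null(
    seed: int = 0,
    n_datasets: int = 24,
    n_samples: int = 25,
    n_taxa: int = 150,
    depth: int = 2000,
    n_null: int = 999,
) -> dict:
    """SES calibration on data generated by the richness null itself.

    Each dataset's count matrix is replaced by one richness-null draw, so
    every sample is exchangeable with its own null distribution and the
    SES of Faith's PD should be ≈ standard normal across units.
    """
    all_ses = []
    for rep in range(n_datasets):
        pool = make_source_pool(n_taxa, seed=_sub(seed, 800 + rep))
        tree = simulate_phylogeny(n_taxa, seed=_sub(seed, 800 + rep))
        copy_numbers = pd.Series(1.0, index=list(pool.taxon_ids))
        ens = assemble_dirichlet(
            pool, 200, n_samples, seed=_sub(seed, 900 + rep), community_size=100_000
        )
        reads, _ = sequence_communities(ens, depth, copy_numbers, seed=_sub(seed, 1000 + rep))
        taxa = list(reads.columns[(reads.sum(axis=0) > 0).to_numpy()])
        null_data = richness_null(reads, taxa, _sub(seed, 1100 + rep))
        res = ses_pd(null_data, tree, pool=taxa, n_null=n_null, seed=_sub(seed, 1200 + rep))
        all_ses.append(res["ses"].to_numpy())
    ses = np.concatenate(all_ses)
    return {
        "mean_ses": float(np.mean(ses)),
        "sd_ses": float(np.std(ses, ddof=1)),
        "n_units": int(ses.size),
    }


def clustering_recovery(
    seed: int = 0,
    n_taxa: int = 500,
    n_communities: int = 12,
    n_null: int = 999,
    n_datasets: int = 5,
) -> dict:
    """Within-group βNTI/βNRI medians under the three assembly regimes.

    Habitat filtering concentrates abundance on one clade and should push
    within-group βNTI (SES of βMNTD) well below −2; variable selection
    favours a different random taxon subset in every replicate community
    and should raise within-group βNRI (SES of βMPD) above the matched
    neutral run. The strength of the clustering signal depends on which
    clade the filter lands on (a clade that already dominates the source
    pool clusters the neutral baseline too), so the experiment pools
    sample pairs over `n_datasets` independently drawn pools and trees
    and reports medians across all pairs.
    """
    bnti_all: dict[str, list] = {}
    bnri_all: dict[str, list] = {}
    for rep in range(n_datasets):
        pool = make_source_pool(n_taxa, seed=_sub(seed, 1300 + rep))
        tree = simulate_phylogeny(n_taxa, seed=_sub(seed, 1300 + rep))
        copy_numbers = pd.Series(1.0, index=list(pool.taxon_ids))
        for regime in ("neutral", "habitat_filter", "variable_selection"):
            cfg = SimulationConfig(
                n_taxa=n_taxa,
                n_communities=n_communities,
                selection_regime=regime,
                seed=_sub(seed, 1400 + rep),
            )
            fitness = apply_selection_regime(pool, tree, cfg)
            ens = assemble_moran(pool, cfg, fitness)
            reads, _ = sequence_communities(
                ens, cfg.sequencing_depth, copy_numbers, seed=_sub(seed, 1500 + rep)
            )
            bnti = ses_beta(reads, tree, "mntd", n_null=n_null, seed=_sub(seed, 1600))
            bnri = ses_beta(reads, tree, "mpd", n_null=n_null, seed=_sub(seed, 1600))
            bnti_all.setdefault(regime, []).append(bnti["ses"].to_numpy())
            bnri_all.setdefault(regime, []).append(bnri["ses"].to_numpy())
    out = {}
    for regime in bnti_all:
        nti = np.concatenate(bnti_all[regime])
        nri = np.concatenate(bnri_all[regime])
        out[regime] = {
            "bnti_median": float(np.median(nti)),
            "bnri_median": float(np.median(nri)),
            "n_pairs": int(nti.size),
        }
    return out
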