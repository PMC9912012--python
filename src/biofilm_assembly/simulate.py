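"""Synthetic influent→biofilm community generator.

This module emulates the sampling design the rest of the package analyses:
a planktonic source pool (the reactor influent) seeds replicate local
communities (carrier biofilms) that assemble by drift, immigration and —
optionally — selection. It provides

* a skewed source pool (lognormal or log-series species-abundance curve),
* a clocklike pure-birth (Yule) phylogeny over the pool,
* an individual-based Moran assembly process with immigration and
  multiplicative fitness, which is exactly the generative process behind
  the Sloan neutral community model,
* a fast stationary-approximation generator drawing compositions from
  Dirichlet(N_T·m·p), whose per-taxon marginal is Beta(N_T·m·p_i,
  N_T·m·(1−p_i)),
* selection regimes (habitat filtering on a clade, homogeneous and
  variable selection on taxon subsets),
* a forward sequencing model (cells → 16S copies → multinomial reads)
  with per-taxon rRNA operon copy numbers and exact qPCR totals.

Everything is seeded and bit-reproducible; ground truth (the full
configuration and fitness vectors) travels with the generated data.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as _pkgio

SOURCE_DISTRIBUTIONS = ("lognormal", "logseries")
SELECTION_REGIMES = (
    "neutral",
    "habitat_filter",
    "homogeneous_selection",
    "variable_selection",
)


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class SourcePool:
    """Source (metacommunity) relative abundances p_i over named taxa."""

    taxon_ids: tuple[str, ...]
    rel_abundance: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.rel_abundance, dtype=float)
        object.__setattr__(self, "rel_abundance", p)
        if len(self.taxon_ids) != p.size:
            raise ConfigurationError("taxon_ids and rel_abundance length mismatch")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ConfigurationError("taxon_ids must be unique")
        if (p < 0).any():
            raise ConfigurationError("relative abundances must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("relative abundances must sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass
class SimulationConfig:
    """Full parameterization of one simulated carrier group.

    Defaults are desk-scale study conditions: a 500-taxon lognormal
    influent pool feeding 25 replicate biofilm communities of
    N_T = 2000 cells at migration rate m = 0.1 (composite N_T·m = 200,
    within the range implied by reported sample-scale migration rates),
    sequenced to 10^4 reads with operon copy numbers uniform on 1..15.
    """

    n_taxa: int = 500
    source_distribution: str = "lognormal"
    source_params: dict = field(default_factory=lambda: {"mu": 0.0, "sigma": 2.0})
    community_size: int = 2000
    migration_rate: float = 0.1
    n_communities: int = 25
    n_generations: int = 25
    selection_regime: str = "neutral"
    filter_clade_fraction: float = 0.10
    fitness_advantage: float = 5.0
    sequencing_depth: int = 10_000
    copy_number_range: tuple[int, int] = (1, 15)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ConfigurationError("n_taxa must be >= 1")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ConfigurationError("migration_rate must lie in [0, 1]")
        if self.community_size < 1:
            raise ConfigurationError("community_size must be >= 1")
        if self.sequencing_depth < 1:
            raise ConfigurationError("sequencing_depth must be >= 1")
        if self.source_distribution not in SOURCE_DISTRIBUTIONS:
            raise ConfigurationError(
                f"unknown source_distribution {self.source_distribution!r}"
            )
        if self.selection_regime not in SELECTION_REGIMES:
            raise ConfigurationError(
                f"unknown selection_regime {self.selection_regime!r}"
            )
        if self.fitness_advantage < 1.0:
            raise ConfigurationError("fitness_advantage must be >= 1")
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("copy_number_range must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["copy_number_range"] = list(self.copy_number_range)
        return d


@dataclass
class CommunityEnsemble:
    """Replicate local communities as integer cell counts plus ground truth."""

    counts: pd.DataFrame  # communities x taxa, cells
    config: SimulationConfig
    fitness: np.ndarray  # communities x taxa multiplicative weights

    def __post_init__(self):
        sums = self.counts.sum(axis=1).to_numpy()
        if not (sums == self.config.community_size).all():
            raise ValueError("community cell counts must each sum to community_size")


def _taxon_ids(n_taxa: int) -> tuple[str, ...]:
    width = max(4, len(str(n_taxa - 1)))
    return tuple(f"ASV_{i:0{width}d}" for i in range(n_taxa))


def make_source_pool(
    n_taxa: int,
    distribution: str = "lognormal",
    params: dict | None = None,
    seed: int = 0,
) -> SourcePool:
    """Draw a source pool with a skewed species-abundance distribution."""
    if n_taxa < 1:
        raise ConfigurationError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    params = dict(params or {})
    if distribution == "lognormal":
        mu = float(params.pop("mu", 0.0))
        sigma = float(params.pop("sigma", 2.0))
        x = rng.lognormal(mean=mu, sigma=sigma, size=n_taxa)
    elif distribution == "logseries":
        # numpy's log-series parameter p in (0, 1); larger -> longer tail
        pshape = float(params.pop("p", 0.99))
        x = rng.logseries(pshape, size=n_taxa).astype(float)
    else:
        raise ConfigurationError(f"unknown distribution {distribution!r}")
    if params:
        raise ConfigurationError(f"unused distribution parameters: {sorted(params)}")
    p = x / x.sum()
    return SourcePool(taxon_ids=_taxon_ids(n_taxa), rel_abundance=p)


def simulate_phylogeny(
    n_taxa: int,
    model: str = "yule",
    seed: int = 0,
    birth_rate: float = 1.0,
) -> TreeNode:
    """Simulate an ultrametric pure-birth tree with tips ASV_0000..ASV_nnnn.

    Lineages split at exponential waiting times (rate = birth_rate per
    lineage); the process stops one waiting time after the n-th lineage
    appears, so every tip sits at the same root-to-tip height.
    """
    if n_taxa < 2:
        raise ConfigurationError("a phylogeny needs at least 2 taxa")
    if model != "yule":
        raise ConfigurationError(f"unknown tree model {model!r}")
    rng = np.random.default_rng(seed)

    left, right = {"start": 0.0}, {"start": 0.0}
    root = {"start": 0.0, "children": [left, right], "split": 0.0}
    active = [left, right]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        kids = [{"start": t}, {"start": t}]
        node["children"] = kids
        node["split"] = t
        active.extend(kids)
    height = t + rng.exponential(1.0 / (birth_rate * n_taxa))

    labels = list(_taxon_ids(n_taxa))
    rng.shuffle(labels)  # decouple tree position from abundance rank
    counter = iter(labels)

    def newick(node) -> str:
        if "children" in node:
            inner = ",".join(newick(c) for c in node["children"])
            length = node["split"] - node["start"]
            return f"({inner}):{length:.10f}"
        length = height - node["start"]
        return f"{next(counter)}:{length:.10f}"

    text = "(%s,%s):0.0;" % (newick(left), newick(right))
    return TreeNode.read(
        _io.StringIO(text), format="newick", convert_underscores=False
    )


# ---------------------------------------------------------------------------
# Moran assembly process
# ---------------------------------------------------------------------------

def _run_moran(
    counts: np.ndarray,
    source_p: np.ndarray,
    fitness: np.ndarray,
    m: float,
    n_events: int,
    rng: np.random.Generator,
    tally: np.ndarray | None = None,
    tally_after: int = 0,
) -> np.ndarray:
    """Run `n_events` single-individual replacement events in place.

    Each event: one uniformly random individual dies; with probability m
    the empty slot is filled by an immigrant drawn with weight p_i·w_i,
    otherwise by a local birth with weight (local count)_i·w_i computed
    after the death. Community size is invariant throughout.

    If `tally` (shape (N+1, N+1), for 3-taxon runs) is given, the state
    (c_0, c_1) is tallied after every event past `tally_after`.
    """
    n_total = int(counts.sum())
    w = np.asarray(fitness, dtype=float)
    src_w = source_p * w
    total = src_w.sum()
    if total <= 0:
        raise ConfigurationError("all-zero fitness: no taxon can ever win a slot")
    src_cum = np.cumsum(src_w / total)
    src_cum[-1] = 1.0

    slots = np.repeat(np.arange(counts.size), counts).astype(np.int64)
    rng.shuffle(slots)
    lw = counts.astype(float) * w
    do_tally = tally is not None

    chunk = 1 << 15
    done = 0
    while done < n_events:
        k = min(chunk, n_events - done)
        # refresh local weights from integer counts to kill float drift
        lw = counts.astype(float) * w
        death_idx = rng.integers(0, n_total, size=k)
        migrate = rng.random(k) < m
        u = rng.random(k)
        for r in range(k):
            i = death_idx[r]
            dead = slots[i]
            counts[dead] -= 1
            lw[dead] -= w[dead]
            if migrate[r]:
                new = int(np.searchsorted(src_cum, u[r]))
            else:
                c = np.cumsum(lw)
                if c[-1] <= 0:  # N_T == 1: no local parent remains
                    new = int(np.searchsorted(src_cum, u[r]))
                else:
                    new = int(np.searchsorted(c, u[r] * c[-1]))
            counts[new] += 1
            lw[new] += w[new]
            slots[i] = new
            if do_tally and done + r >= tally_after:
                tally[counts[0], counts[1]] += 1
        done += k
    return counts


def assemble_moran(
    source: SourcePool,
    config: SimulationConfig,
    fitness: np.ndarray | None = None,
) -> CommunityEnsemble:
    """Assemble replicate communities by the Moran process with immigration.

    Each community is initialized by N_T multinomial draws from the source
    pool and then evolved for n_generations × N_T replacement events.
    """
    p = source.rel_abundance
    n_taxa = source.n_taxa
    if fitness is None:
        fitness = np.ones((config.n_communities, n_taxa))
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape != (config.n_communities, n_taxa):
        raise ConfigurationError(
            "fitness must have shape (n_communities, n_taxa)"
        )
    if (fitness < 0).any():
        raise ConfigurationError("fitness weights must be >= 0")
    n_events = config.n_generations * config.community_size
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_communities)
    rows = np.empty((config.n_communities, n_taxa), dtype=np.int64)
    for c in range(config.n_communities):
        rng = np.random.default_rng(seeds[c])
        counts = rng.multinomial(config.community_size, p).astype(np.int64)
        _run_moran(counts, p, fitness[c], config.migration_rate, n_events, rng)
        rows[c] = counts
    index = [f"community_{c:02d}" for c in range(config.n_communities)]
    counts_df = pd.DataFrame(rows, index=index, columns=list(source.taxon_ids))
    counts_df.index.name = "sample_id"
    return CommunityEnsemble(counts=counts_df, config=config, fitness=fitness)


def moran_occupancy(
    source_p: np.ndarray,
    community_size: int,
    migration_rate: float,
    n_events: int,
    burn_in: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Empirical stationary occupancy of a 3-taxon Moran chain.

    Runs a single community for burn_in + n_events replacement events and
    tallies the state (c_0, c_1) after every post-burn-in event. Returns a
    (N+1, N+1) matrix of visit frequencies summing to 1.
    """
    p = np.asarray(source_p, dtype=float)
    if p.size != 3:
        raise ConfigurationError("moran_occupancy is specialized to 3 taxa")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(community_size, p).astype(np.int64)
    tally = np.zeros((community_size + 1, community_size + 1), dtype=np.int64)
    _run_moran(
        counts,
        p,
        np.ones(3),
        migration_rate,
        burn_in + n_events,
        rng,
        tally=tally,
        tally_after=burn_in,
    )
    return tally / tally.sum()


def moran_stationary_exact(
    source_p: np.ndarray, community_size: int, migration_rate: float
) -> dict[tuple[int, ...], float]:
    """Exact stationary distribution of the small Moran chain.

    Enumerates all compositions of `community_size` individuals over the
    taxa, builds the one-event transition matrix and solves for its
    stationary vector. Intended for <= 3 taxa and small N_T, where the
    state space (N+1)(N+2)/2 stays tiny; serves as the independent oracle
    for the stochastic simulator.
    """
    p = np.asarray(source_p, dtype=float)
    n = community_size
    m = migration_rate
    k = p.size

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    states = list(compositions(n, k))
    index = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for s in states:
        si = index[s]
        for i in range(k):  # taxon of the dying individual
            if s[i] == 0:
                continue
            p_death = s[i] / n
            for j in range(k):  # taxon of the replacement
                if n > 1:
                    local = (s[j] - (1 if j == i else 0)) / (n - 1)
                    p_repl = m * p[j] + (1 - m) * local
                else:
                    p_repl = p[j]
                if p_repl == 0:
                    continue
                t = list(s)
                t[i] -= 1
                t[j] += 1
                T[si, index[tuple(t)]] += p_death * p_repl
    # stationary vector: left eigenvector of T for eigenvalue 1
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    return {s: float(pi[i]) for i, s in enumerate(states)}


def assemble_dirichlet(
    source: SourcePool,
    ntm: float,
    n_communities: int,
    seed: int = 0,
    community_size: int = 1_000_000,
) -> CommunityEnsemble:
    """Draw communities from the Moran model's stationary approximation.

    Compositions are sampled jointly from Dirichlet(N_T·m·p), so the
    marginal relative abundance of taxon i is Beta(N_T·m·p_i,
    N_T·m·(1−p_i)) — the distribution the neutral community model fits.
    Integer cell counts are realized by a multinomial of `community_size`
    cells per community.
    """
    if ntm <= 0:
        raise ConfigurationError("ntm must be > 0")
    rng = np.random.default_rng(seed)
    alpha = ntm * source.rel_abundance
    comps = rng.dirichlet(alpha, size=n_communities)
    rows = np.vstack(
        [rng.multinomial(community_size, comps[c]) for c in range(n_communities)]
    ).astype(np.int64)
    index = [f"community_{c:02d}" for c in range(n_communities)]
    counts = pd.DataFrame(rows, index=index, columns=list(source.taxon_ids))
    counts.index.name = "sample_id"
    config = SimulationConfig(
        n_taxa=source.n_taxa,
        community_size=community_size,
        migration_rate=min(1.0, ntm / community_size),
        n_communities=n_communities,
        seed=seed,
    )
    fitness = np.ones((n_communities, source.n_taxa))
    return CommunityEnsemble(counts=counts, config=config, fitness=fitness)


def _clade_subsets(tree: TreeNode) -> list[tuple[TreeNode, list[str]]]:
    out = []
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        out.append((node, tips))
    return out


def apply_selection_regime(
    pool: SourcePool,
    tree: TreeNode | None,
    config: SimulationConfig,
) -> np.ndarray:
    """Build per-community fitness vectors for the configured regime.

    habitat_filter: one clade holding ≈ filter_clade_fraction of the tips
    is favoured (weight w) identically in every community. homogeneous_
    selection: one random taxon subset favoured in every community.
    variable_selection: an independent random subset per community.
    neutral: all weights 1.
    """
    n = pool.n_taxa
    w = config.fitness_advantage
    regime = config.selection_regime
    fitness = np.ones((config.n_communities, n))
    if regime == "neutral":
        return fitness

    rng = np.random.default_rng([config.seed, 7919])
    idx_of = {t: i for i, t in enumerate(pool.taxon_ids)}
    n_favoured = max(1, int(round(config.filter_clade_fraction * n)))

    if regime == "habitat_filter":
        if tree is None:
            raise ConfigurationError("habitat_filter needs a phylogeny")
        target = config.filter_clade_fraction
        best, best_frac = None, None
        for node, tips in _clade_subsets(tree):
            frac = len(tips) / n
            if best is None or abs(frac - target) < abs(best_frac - target):
                best, best_frac = tips, frac
        if best is None or not (0.5 * target <= best_frac <= 1.5 * target):
            raise ConfigurationError(
                f"no clade holds ~{target:.0%} of tips "
                f"(closest: {0.0 if best_frac is None else best_frac:.1%})"
            )
        cols = [idx_of[t] for t in best]
        fitness[:, cols] = w
    elif regime == "homogeneous_selection":
        cols = rng.choice(n, size=n_favoured, replace=False)
        fitness[:, cols] = w
    elif regime == "variable_selection":
        for c in range(config.n_communities):
            cols = rng.choice(n, size=n_favoured, replace=False)
            fitness[c, cols] = w
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ConfigurationError(f"unknown selection_regime {regime!r}")
    return fitness


def draw_copy_numbers(
    taxon_ids, copy_number_range: tuple[int, int] = (1, 15), seed: int = 0
) -> pd.Series:
    """Per-taxon 16S operon copy numbers, uniform on an integer interval."""
    lo, hi = copy_number_range
    rng = np.random.default_rng([seed, 104729])
    values = rng.integers(lo, hi + 1, size=len(taxon_ids)).astype(float)
    return pd.Series(values, index=list(taxon_ids), name="copy_number")


def sequence_communities(
    ensemble: CommunityEnsemble,
    depth: int,
    copy_numbers: pd.Series,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Forward sequencing model: cells → gene copies → multinomial reads.

    The sampling weight of taxon i is cells_i × c_i (amplicon reads are
    drawn from gene copies, not cells), and the qPCR total is
    Σ_i cells_i × c_i exactly.
    """
    if depth < 1:
        raise ConfigurationError("sequencing depth must be >= 1")
    c = copy_numbers.reindex(ensemble.counts.columns)
    if c.isna().any():
        raise ConfigurationError("copy_numbers missing for some taxa")
    if (c < 1).any():
        raise ConfigurationError("copy numbers must be >= 1")
    cells = ensemble.counts.to_numpy()
    if (cells.sum(axis=1) == 0).any():
        raise ConfigurationError("cannot sequence an empty community")
    weights = cells * c.to_numpy()
    qpcr = pd.Series(
        weights.sum(axis=1), index=ensemble.counts.index, name="qpcr_copies"
    )
    rng = np.random.default_rng([seed, 15485863])
    reads = np.vstack(
        [rng.multinomial(depth, w / w.sum()) for w in weights]
    ).astype(np.int64)
    reads_df = pd.DataFrame(
        reads, index=ensemble.counts.index, columns=ensemble.counts.columns
    )
    return reads_df, qpcr


def sequence_source_samples(
    pool: SourcePool,
    n_samples: int,
    depth: int,
    copy_numbers: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequence the influent pool itself (reads weighted by p_i × c_i)."""
    c = copy_numbers.reindex(list(pool.taxon_ids)).to_numpy()
    w = pool.rel_abundance * c
    w = w / w.sum()
    rng = np.random.default_rng([seed, 32452843])
    reads = np.vstack([rng.multinomial(depth, w) for _ in range(n_samples)])
    index = [f"INF_{i:02d}" for i in range(n_samples)]
    df = pd.DataFrame(reads.astype(np.int64), index=index, columns=list(pool.taxon_ids))
    df.index.name = "sample_id"
    return df


def simulate_study(
    configs: SimulationConfig | Mapping[str, SimulationConfig],
    n_source_samples: int = 5,
    surface_area_cm2: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Simulate a full influent→biofilm dataset, optionally with groups.

    All groups share one source pool and one phylogeny (drawn from the
    first config); each group assembles its communities under its own
    size, migration rate and selection regime — mirroring one influent
    feeding carriers of several maximum thicknesses.

    Returns a dict with counts (source + target samples), tree, metadata,
    copy_numbers and a truth record.
    """
    if isinstance(configs, SimulationConfig):
        configs = {"G1": configs}
    first = next(iter(configs.values()))
    master = first.seed if seed is None else seed
    pool = make_source_pool(
        first.n_taxa, first.source_distribution, first.source_params, seed=master
    )
    tree = simulate_phylogeny(first.n_taxa, seed=master)
    copy_numbers = draw_copy_numbers(
        pool.taxon_ids, first.copy_number_range, seed=master
    )

    source_counts = sequence_source_samples(
        pool, n_source_samples, first.sequencing_depth, copy_numbers, seed=master
    )
    meta_rows = [
        {
            "sample_id": s,
            "role": "source",
            "group": "influent",
            "timepoint": 0,
            "qpcr_copies": np.nan,
            "surface_area_cm2": np.nan,
        }
        for s in source_counts.index
    ]

    blocks = [source_counts]
    truth_fitness = {}
    for g, (group, cfg) in enumerate(configs.items()):
        if cfg.n_taxa != first.n_taxa:
            raise ConfigurationError("all groups must share the taxon pool")
        group_seed = (master * 1009 + 31 * g + cfg.seed) % (2**31)
        cfg_g = dataclasses.replace(cfg, seed=group_seed)
        fitness = apply_selection_regime(pool, tree, cfg_g)
        ensemble = assemble_moran(pool, cfg_g, fitness)
        reads, qpcr = sequence_communities(
            ensemble, cfg.sequencing_depth, copy_numbers, seed=group_seed
        )
        reads = reads.rename(index=lambda s: f"{group}_{s.split('_')[-1]}")
        qpcr = qpcr.rename(index=lambda s: f"{group}_{s.split('_')[-1]}")
        blocks.append(reads)
        truth_fitness[group] = fitness.tolist()
        for s in reads.index:
            meta_rows.append(
                {
                    "sample_id": s,
                    "role": "target",
                    "group": group,
                    "timepoint": 0,
                    "qpcr_copies": float(qpcr[s]),
                    "surface_area_cm2": surface_area_cm2,
                }
            )

    counts = pd.concat(blocks, axis=0).fillna(0).astype(np.int64)
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "master_seed": master,
        "n_source_samples": n_source_samples,
        "groups": {g: c.to_dict() for g, c in configs.items()},
        "source_rel_abundance": pool.rel_abundance.tolist(),
        "fitness": truth_fitness,
    }
    return {
        "counts": counts,
        "tree": tree,
        "metadata": metadata,
        "copy_numbers": copy_numbers,
        "truth": truth,
    }


def write_dataset(dataset: dict, out_dir: str | Path) -> None:
    """Write a simulate_study() dataset as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _pkgio.write_counts(dataset["counts"], out / "counts.tsv")
    _pkgio.write_tree(dataset["tree"], out / "tree.nwk")
    _pkgio.write_metadata(dataset["metadata"], out / "metadata.tsv")
    _pkgio.write_copy_numbers(dataset["copy_numbers"], out / "copy_numbers.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset["truth"], fh, indent=1)
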