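"""Phylogenetic diversity metrics and richness-null standardized effect sizes.

Observed metrics:

* Faith's PD — total branch length of the minimal subtree connecting a
  sample's taxa to the root (rooted convention).
* βMPD — abundance-weighted mean pairwise patristic distance between two
  communities, Σ_i Σ_j f_i^a f_j^b d_ij.
* βMNTD — abundance-weighted mean nearest-taxon distance,
  ½[Σ_i f_i^a min_{j∈b} d_ij + Σ_j f_j^b min_{i∈a} d_ij].

Null model: the *richness* null reassigns each sample's observed
abundance values to a uniformly random taxon subset (of the same size)
drawn from a fixed taxon pool, preserving per-sample richness and the
multiset of abundance values exactly. Standardized effect sizes are

    ses = (observed − null_mean) / null_sd

over 999 randomizations by default, reported unnegated so that negative
values mean phylogenetic clustering and positive values overdispersion;
|ses| > 2 is flagged significant. SES of βMNTD is the βNTI and SES of
βMPD the βNRI.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from skbio import TreeNode

DEFAULT_N_NULL = 999
SES_SIGNIFICANCE = 2.0


def branch_incidence(tree: TreeNode, taxa) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and a branch x taxon descendant-incidence matrix.

    Row b of the boolean matrix marks the taxa (restricted to `taxa`)
    descending from branch b; the root itself carries no branch. This is
    the workhorse behind Faith's PD and weighted UniFrac: any per-branch
    abundance fraction is an incidence-matrix product away.
    """
    order = {t: i for i, t in enumerate(taxa)}
    tips_in_tree = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips_in_tree]
    if missing:
        raise ValueError(f"taxa not on the tree: {missing[:5]}...")
    lengths = []
    rows = []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            mask = np.zeros(len(taxa), dtype=bool)
            if node.name in order:
                mask[order[node.name]] = True
        else:
            mask = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                mask |= masks.pop(id(child))
        masks[id(node)] = mask
        lengths.append(0.0 if node.length is None else float(node.length))
        rows.append(mask)
    return np.asarray(lengths), np.vstack(rows)


def patristic_matrix(tree: TreeNode, taxa=None) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix."""
    dm = tree.tip_tip_distances()
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    if taxa is not None:
        df = df.loc[list(taxa), list(taxa)]
    return df


def faith_pd(taxa_present, tree: TreeNode) -> float:
    """Faith's PD of one sample: branch length of the minimal rooted subtree."""
    present = list(taxa_present)
    if not present:
        raise ValueError("Faith's PD of an empty sample is undefined")
    lengths, incidence = branch_incidence(tree, present)
    mask = np.ones(len(present), dtype=bool)
    return float(lengths @ (incidence @ mask > 0))


def _faith_pd_matrix(presence: np.ndarray, lengths: np.ndarray, incidence: np.ndarray):
    """PD for many samples at once; presence is samples x taxa boolean."""
    covered = incidence @ presence.T > 0  # branches x samples
    return lengths @ covered


def comdist_mpd(abund_a: pd.Series, abund_b: pd.Series, dist: pd.DataFrame) -> float:
    """Abundance-weighted between-community mean pairwise distance (βMPD)."""
    fa = abund_a / abund_a.sum()
    fb = abund_b / abund_b.sum()
    missing = set(fa.index).union(fb.index) - set(dist.index)
    if missing:
        raise ValueError(f"taxa missing from the distance matrix: {sorted(missing)[:5]}")
    d = dist.loc[fa.index, fb.index].to_numpy()
    return float(fa.to_numpy() @ d @ fb.to_numpy())


def comdistnt_mntd(abund_a: pd.Series, abund_b: pd.Series, dist: pd.DataFrame) -> float:
    """Abundance-weighted between-community mean nearest-taxon distance (βMNTD)."""
    fa = abund_a[abund_a > 0] / abund_a.sum()
    fb = abund_b[abund_b > 0] / abund_b.sum()
    missing = set(fa.index).union(fb.index) - set(dist.index)
    if missing:
        raise ValueError(f"taxa missing from the distance matrix: {sorted(missing)[:5]}")
    d_ab = dist.loc[fa.index, fb.index].to_numpy()
    term_a = float(fa.to_numpy() @ d_ab.min(axis=1))
    term_b = float(fb.to_numpy() @ d_ab.min(axis=0))
    return 0.5 * (term_a + term_b)


def richness_null(
    counts: pd.DataFrame, pool, seed_or_rng=0
) -> pd.DataFrame:
    """One richness-null randomization of a count table.

    Per sample, the nonzero abundance values are shuffled onto a
    uniformly random subset of pool taxa of the same size; per-sample
    richness and the multiset of abundance values (hence row sums) are
    preserved exactly.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    pool = list(pool)
    observed = set(counts.columns[(counts.sum(axis=0) > 0).to_numpy()])
    if not observed.issubset(pool):
        raise ValueError("pool must contain every observed taxon")
    arr = counts.reindex(columns=pool, fill_value=0).to_numpy()
    out = np.zeros_like(arr)
    for r in range(arr.shape[0]):
        vals = arr[r][arr[r] > 0]
        if vals.size > len(pool):
            raise ValueError("pool smaller than a sample's richness")
        idx = rng.choice(len(pool), size=vals.size, replace=False)
        out[r, idx] = rng.permutation(vals)
    return pd.DataFrame(out, index=counts.index, columns=pool)


def _null_randomize(arr: np.ndarray, pool_size: int, rng: np.random.Generator):
    out = np.zeros((arr.shape[0], pool_size), dtype=arr.dtype)
    for r in range(arr.shape[0]):
        vals = arr[r][arr[r] > 0]
        idx = rng.choice(pool_size, size=vals.size, replace=False)
        out[r, idx] = rng.permutation(vals)
    return out


def _ses_table(observed, null_values, unit_ids):
    """Assemble SES rows from observed values and a (n_null, units) array."""
    null_mean = null_values.mean(axis=0)
    null_sd = null_values.std(axis=0, ddof=1)
    # a constant null distribution leaves the SES undefined; the tolerance
    # absorbs float noise from the mean subtraction
    defined = null_sd > 1e-10 * np.maximum(1.0, np.abs(null_mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = (observed - null_mean) / null_sd
    ses = np.where(defined, ses, np.nan)
    df = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses,
            "n_null": null_values.shape[0],
        }
    )
    df["significant"] = np.abs(df["ses"]) > SES_SIGNIFICANCE
    return df


def ses_pd(
    counts: pd.DataFrame,
    tree: TreeNode,
    pool=None,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> pd.DataFrame:
    """SES of Faith's PD per sample against the richness null."""
    if pool is None:
        pool = list(counts.columns[(counts.sum(axis=0) > 0).to_numpy()])
    pool = list(pool)
    lengths, incidence = branch_incidence(tree, pool)
    arr = counts.reindex(columns=pool, fill_value=0).to_numpy()
    observed = _faith_pd_matrix(arr > 0, lengths, incidence)
    seeds = np.random.SeedSequence(seed).spawn(n_null)
    nulls = np.empty((n_null, arr.shape[0]))
    for k in range(n_null):
        rnd = _null_randomize(arr, len(pool), np.random.default_rng(seeds[k]))
        nulls[k] = _faith_pd_matrix(rnd > 0, lengths, incidence)
    return _ses_table(observed, nulls, list(counts.index))


def _pair_metrics(arr: np.ndarray, dist: np.ndarray, pairs_idx, metric: str):
    sums = arr.sum(axis=1, keepdims=True).astype(float)
    F = arr / np.where(sums > 0, sums, 1.0)
    if metric == "mpd":
        M = F @ dist @ F.T
        return np.array([M[a, b] for a, b in pairs_idx])
    # mntd: nearest-taxon distance vectors per sample
    mins = np.empty((arr.shape[0], dist.shape[0]))
    for s in range(arr.shape[0]):
        present = arr[s] > 0
        if not present.any():
            raise ValueError("cannot compute MNTD for an empty sample")
        mins[s] = dist[:, present].min(axis=1)
    return np.array(
        [0.5 * (F[a] @ mins[b] + F[b] @ mins[a]) for a, b in pairs_idx]
    )


def ses_beta(
    counts: pd.DataFrame,
    tree: TreeNode,
    metric: str,
    pairs=None,
    pool=None,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> pd.DataFrame:
    """SES of βMPD (βNRI) or βMNTD (βNTI) for sample pairs.

    Every null replicate randomizes the whole count table once and
    recomputes the metric for all pairs, so pair values within a
    replicate share the same randomized matrix (the picante convention).
    """
    if metric not in ("mpd", "mntd"):
        raise ValueError("metric must be 'mpd' or 'mntd'")
    if pool is None:
        pool = list(counts.columns[(counts.sum(axis=0) > 0).to_numpy()])
    pool = list(pool)
    if pairs is None:
        pairs = list(combinations(counts.index, 2))
    pos = {s: i for i, s in enumerate(counts.index)}
    pairs_idx = [(pos[a], pos[b]) for a, b in pairs]
    dist = patristic_matrix(tree, pool).to_numpy()
    arr = counts.reindex(columns=pool, fill_value=0).to_numpy()
    observed = _pair_metrics(arr, dist, pairs_idx, metric)
    seeds = np.random.SeedSequence(seed).spawn(n_null)
    nulls = np.empty((n_null, len(pairs_idx)))
    for k in range(n_null):
        rnd = _null_randomize(arr, len(pool), np.random.default_rng(seeds[k]))
        nulls[k] = _pair_metrics(rnd, dist, pairs_idx, metric)
    df = _ses_table(observed, nulls, [f"{a}|{b}" for a, b in pairs])
    df.insert(1, "sample_a", [a for a, _ in pairs])
    df.insert(2, "sample_b", [b for _, b in pairs])
    return df


def ses_metric(
    metric: str,
    counts: pd.DataFrame,
    tree: TreeNode,
    metadata: pd.DataFrame,
    comparison: str,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    pooled_source: bool = False,
) -> pd.DataFrame:
    """SES of pd/mpd/mntd under the study's two comparison designs.

    vs_source: each target group is compared against the influent — the
    null pool is every taxon present in the source plus that group's
    samples; units are source–target sample pairs (or per target sample
    for PD). With pooled_source the source samples are first summed into
    one pooled influent profile.

    within_group: units are unordered sample pairs inside each target
    group (per sample for PD) and the pool is that group's own taxa —
    separating homogeneous from variable selection among replicates.
    """
    if metric not in ("pd", "mpd", "mntd"):
        raise ValueError("metric must be one of pd, mpd, mntd")
    if comparison not in ("vs_source", "within_group"):
        raise ValueError("comparison must be vs_source or within_group")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    source_ids = [s for s in counts.index if meta.loc[s, "role"] == "source"]
    target_meta = meta.loc[[s for s in counts.index if meta.loc[s, "role"] == "target"]]
    results = []
    for group, gmeta in target_meta.groupby("group"):
        gids = list(gmeta.index)
        if comparison == "vs_source":
            block = counts.loc[source_ids + gids]
            if pooled_source and metric != "pd":
                pooled = counts.loc[source_ids].sum(axis=0).to_frame("influent_pool").T
                block = pd.concat([pooled, counts.loc[gids]])
                src = ["influent_pool"]
            else:
                src = source_ids
            pool = list(block.columns[(block.sum(axis=0) > 0).to_numpy()])
            if metric == "pd":
                res = ses_pd(counts.loc[gids], tree, pool=pool, n_null=n_null, seed=seed)
            else:
                pairs = [(s, t) for s in src for t in gids]
                res = ses_beta(
                    block, tree, metric, pairs=pairs, pool=pool, n_null=n_null, seed=seed
                )
        else:
            block = counts.loc[gids]
            pool = list(block.columns[(block.sum(axis=0) > 0).to_numpy()])
            if metric == "pd":
                res = ses_pd(block, tree, pool=pool, n_null=n_null, seed=seed)
            else:
                res = ses_beta(block, tree, metric, pool=pool, n_null=n_null, seed=seed)
        res.insert(0, "group", group)
        results.append(res)
    return pd.concat(results, ignore_index=True)
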