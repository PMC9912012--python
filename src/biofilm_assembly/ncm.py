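"""Sloan neutral community model: fitting, classification, migration rates.

The neutral community model predicts how often a taxon occurs across
replicate local communities from nothing but its relative abundance p in
the source pool and one composite parameter N_T·m (local community size
times migration rate). At stationarity the local relative abundance x of
a taxon follows Beta(N_T·m·p, N_T·m·(1−p)); with detection limit
d = 1/N_s (one read at sequencing depth N_s) the predicted occurrence
frequency is

    F(p) = P(x > d) = 1 − I_d(N_T·m·p, N_T·m·(1−p))

where I is the regularized incomplete beta function. Fitting minimizes
the squared error between observed and predicted occurrence frequencies
over N_T·m; taxa are then classified against binomial (Wilson score)
95% confidence bands around the prediction as neutrally distributed,
more frequent than predicted ("above", selected for in the local
communities) or less frequent ("below", selected against).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG10_NTM_BOUNDS = (-2.0, 9.0)
CLASS_LABELS = ("below", "neutral", "above")


@dataclass
class NCMFit:
    """A fitted neutral community model."""

    ntm: float
    detection_limit: float
    n_target_samples: int
    n_modelled: int
    spearman_rho: float
    r_squared: float
    per_taxon: pd.DataFrame  # p, observed_freq, predicted_freq, ci_low, ci_high, classification
    class_counts: dict = field(default_factory=dict)
    class_rel_abundance: dict = field(default_factory=dict)
    at_bound: bool = False

    def summary(self) -> dict:
        return {
            "ntm": self.ntm,
            "detection_limit": self.detection_limit,
            "n_target_samples": self.n_target_samples,
            "n_modelled": self.n_modelled,
            "spearman_rho": self.spearman_rho,
            "r_squared": self.r_squared,
            "class_counts": dict(self.class_counts),
            "class_rel_abundance": dict(self.class_rel_abundance),
            "at_bound": self.at_bound,
        }


@dataclass
class ReplicateScheme:
    """Repeated-subsample fitting scheme: n_runs random target subsets."""

    n_runs: int = 10
    samples_per_run: int = 5


@dataclass
class ReplicatedNCMFit:
    """Across-run mean of repeated NCM fits, with per-run fits retained."""

    ntm: float
    spearman_rho: float
    r_squared: float
    class_counts: dict
    class_rel_abundance: dict
    per_taxon: pd.DataFrame
    runs: list = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "ntm": self.ntm,
            "spearman_rho": self.spearman_rho,
            "r_squared": self.r_squared,
            "class_counts": dict(self.class_counts),
            "class_rel_abundance": dict(self.class_rel_abundance),
            "n_runs": len(self.runs),
            "per_run_ntm": [r.ntm for r in self.runs],
            "per_run_rho": [r.spearman_rho for r in self.runs],
        }


@dataclass
class MigrationEstimate:
    """Migration rate under sample-size and true-community-size conventions."""

    ntm: float
    n_s: float
    n_t: float
    m_sample: float
    m_true: float
    surface_area: float | None = None
    m_per_area: float | None = None

    def summary(self) -> dict:
        return {
            "ntm": self.ntm,
            "N_s": self.n_s,
            "N_T": self.n_t,
            "m_sample": self.m_sample,
            "m_true": self.m_true,
            "surface_area_cm2": self.surface_area,
            "m_per_area": self.m_per_area,
        }


def shared_taxa_filter(source: pd.DataFrame, target: pd.DataFrame) -> list:
    """Taxa with nonzero total count in both the source and target tables.

    The model only describes taxa present on both sides of the
    source→target comparison; order follows the source table's columns.
    """
    if source.empty or target.empty:
        raise ValueError("source and target count tables must be nonempty")
    in_source = source.columns[(source.sum(axis=0) > 0).to_numpy()]
    in_target = set(target.columns[(target.sum(axis=0) > 0).to_numpy()])
    shared = [t for t in in_source if t in in_target]
    if not shared:
        raise ValueError("no taxa shared between source and target; cannot fit")
    return shared


def predict_freq(p, ntm: float, d: float):
    """Predicted occurrence frequency F(p) = 1 − BetaCDF(d; ntm·p, ntm·(1−p)).

    Defined limits F(0) = 0 and F(1) = 1; increasing in p.
    """
    if ntm <= 0:
        raise ValueError("ntm must be > 0")
    if not 0.0 < d < 1.0:
        raise ValueError("detection limit d must lie strictly in (0, 1)")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("source abundances must lie in [0, 1]")
    out = np.empty_like(p_arr, dtype=float)
    interior = (p_arr > 0) & (p_arr < 1)
    out[p_arr == 0.0] = 0.0
    out[p_arr == 1.0] = 1.0
    pi = p_arr[interior]
    out[interior] = stats.beta.sf(d, ntm * pi, ntm * (1.0 - pi))
    return out if out.ndim else float(out)


def fit_ntm(
    observed_freq,
    p,
    d: float,
    log10_bounds: tuple[float, float] = LOG10_NTM_BOUNDS,
) -> dict:
    """Least-squares fit of the composite parameter N_T·m.

    One-dimensional bounded minimization of Σ_i (obs_i − F(p_i))² over
    log10(N_T·m); reports Spearman ρ (average ranks on ties) and
    R² = 1 − SSE/SST between observed and predicted frequencies.
    """
    obs = np.asarray(observed_freq, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if obs.size != p_arr.size:
        raise ValueError("observed_freq and p must have equal length")
    if obs.size < 5:
        raise ValueError("need at least 5 taxa to fit the model")
    if ((obs < 0) | (obs > 1)).any():
        raise ValueError("observed frequencies must lie in [0, 1]")

    def sse(log_ntm: float) -> float:
        pred = predict_freq(p_arr, 10.0**log_ntm, d)
        return float(np.sum((obs - pred) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=log10_bounds, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:  # pragma: no cover - bounded search rarely fails
        raise RuntimeError(
            f"ntm search failed on log10 interval {log10_bounds}: {res.message}"
        )
    lo, hi = log10_bounds
    at_bound = res.x < lo + 0.05 or res.x > hi - 0.05
    ntm = float(10.0**res.x)
    pred = predict_freq(p_arr, ntm, d)
    sse_val = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    rho = float(stats.spearmanr(obs, pred).statistic) if np.ptp(pred) > 0 else np.nan
    r2 = 1.0 - sse_val / sst if sst > 0 else np.nan
    return {
        "ntm": ntm,
        "predicted_freq": pred,
        "spearman_rho": rho,
        "r_squared": r2,
        "sse": sse_val,
        "at_bound": at_bound,
    }


def wilson_interval(p, n: int, alpha: float = 0.05):
    """Wilson score confidence interval for a proportion p seen in n trials."""
    if n < 2:
        raise ValueError("need at least 2 samples for a useful interval")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p_arr = np.asarray(p, dtype=float)
    denom = 1.0 + z**2 / n
    centre = (p_arr + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_arr * (1 - p_arr) / n + z**2 / (4 * n**2)) / denom
    return np.clip(centre - half, 0.0, 1.0), np.clip(centre + half, 0.0, 1.0)


def midp_band(p, n: int, alpha: float = 0.05):
    """Mid-P binomial acceptance band around a predicted frequency.

    For each predicted frequency p̃ the band is the set of observable
    frequencies k/n whose two-sided mid-P binomial test against p̃ is not
    rejected at level alpha. Unlike a score (Wilson) interval recentred
    on the prediction, this acceptance region keeps the false-positive
    rate of the neutral/above/below partition at ≈ alpha across the full
    range of predicted frequencies, including rare taxa where k·p̃ is
    small and normal approximations are badly anti-conservative.
    """
    if n < 2:
        raise ValueError("need at least 2 samples for a useful band")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k[None, :], n, p_arr[:, None])
    cdf = np.cumsum(pmf, axis=1)
    sf = 1.0 - cdf + pmf
    midp = 2.0 * np.minimum(cdf - 0.5 * pmf, sf - 0.5 * pmf)
    accept = midp >= alpha
    # the most probable k is always accepted; guard against float edge cases
    accept[np.arange(len(p_arr)), np.argmax(pmf, axis=1)] = True
    lo = np.array([k[row].min() for row in accept]) / n
    hi = np.array([k[row].max() for row in accept]) / n
    # the acceptance region lives on the k/n grid; widen it to include the
    # continuous prediction so an observation between the prediction and
    # the grid is never called non-neutral
    lo = np.minimum(lo, p_arr)
    hi = np.maximum(hi, p_arr)
    if np.ndim(p) == 0:
        return float(lo[0]), float(hi[0])
    return lo, hi


def classify_taxa(
    observed_freq,
    predicted_freq,
    n_samples: int,
    alpha: float = 0.05,
    band: str = "midp",
):
    """Three-way classification against confidence bands on the prediction.

    band="midp" (default) uses the calibrated mid-P binomial acceptance
    band; band="wilson" reproduces the Wilson-score convention of widely
    used neutral-model implementations.
    """
    if band == "midp":
        lo, hi = midp_band(predicted_freq, n_samples, alpha)
    elif band == "wilson":
        lo, hi = wilson_interval(predicted_freq, n_samples, alpha)
    else:
        raise ValueError("band must be 'midp' or 'wilson'")
    obs = np.asarray(observed_freq, dtype=float)
    labels = np.where(obs > hi, "above", np.where(obs < lo, "below", "neutral"))
    return labels, lo, hi


def fit_ncm(
    source: pd.DataFrame,
    target: pd.DataFrame,
    depth: int | None = None,
    alpha: float = 0.05,
    band: str = "midp",
) -> NCMFit:
    """Fit the neutral model to source and target count tables.

    p_i is the mean relative abundance of taxon i across source samples;
    observed frequency is the fraction of target samples in which the
    taxon is detected (>= 1 read); d = 1/depth with `depth` the common
    rarefaction depth (median target sample total when not given).
    Aggregate relative abundances per class are reported against the full
    (not shared-only) target communities.
    """
    shared = shared_taxa_filter(source, target)
    if depth is None:
        depth = int(round(float(target.sum(axis=1).median())))
    d = 1.0 / depth

    src_rel = source.div(source.sum(axis=1), axis=0)
    p = src_rel[shared].mean(axis=0).to_numpy()
    tgt = target[shared]
    obs = (tgt > 0).mean(axis=0).to_numpy()
    n_samples = target.shape[0]

    fit = fit_ntm(obs, p, d)
    labels, ci_lo, ci_hi = classify_taxa(
        obs, fit["predicted_freq"], n_samples, alpha, band=band
    )

    per_taxon = pd.DataFrame(
        {
            "p": p,
            "observed_freq": obs,
            "predicted_freq": fit["predicted_freq"],
            "ci_low": ci_lo,
            "ci_high": ci_hi,
            "classification": labels,
        },
        index=pd.Index(shared, name="taxon_id"),
    )
    class_counts = {c: int((labels == c).sum()) for c in CLASS_LABELS}
    total_reads = float(target.to_numpy().sum())
    class_rel = {
        c: float(target[per_taxon.index[labels == c]].to_numpy().sum()) / total_reads
        for c in CLASS_LABELS
    }
    return NCMFit(
        ntm=fit["ntm"],
        detection_limit=d,
        n_target_samples=n_samples,
        n_modelled=len(shared),
        spearman_rho=fit["spearman_rho"],
        r_squared=fit["r_squared"],
        per_taxon=per_taxon,
        class_counts=class_counts,
        class_rel_abundance=class_rel,
        at_bound=fit["at_bound"],
    )


def run_replicated(
    source: pd.DataFrame,
    target: pd.DataFrame,
    scheme: ReplicateScheme = ReplicateScheme(),
    seed: int = 0,
    depth: int | None = None,
    alpha: float = 0.05,
    band: str = "midp",
    strata: pd.Series | None = None,
) -> ReplicatedNCMFit:
    """Fit the model on repeated random target subsets and average.

    Each run fits on `samples_per_run` target samples drawn without
    replacement; reported N_T·m, ρ, R², class counts and per-taxon
    quantities are across-run means. When `strata` (a group label per
    target sample) is given and the number of groups equals
    samples_per_run, each run takes one sample per group.
    """
    n_targets = target.shape[0]
    if scheme.samples_per_run > n_targets:
        raise ValueError(
            f"samples_per_run={scheme.samples_per_run} exceeds the "
            f"{n_targets} available target samples"
        )
    rng = np.random.default_rng(seed)
    runs: list[NCMFit] = []
    for _ in range(scheme.n_runs):
        if strata is not None and strata.nunique() == scheme.samples_per_run:
            chosen = [
                str(rng.choice(strata.index[strata == g]))
                for g in sorted(strata.unique())
            ]
        else:
            chosen = list(
                rng.choice(target.index, size=scheme.samples_per_run, replace=False)
            )
        runs.append(
            fit_ncm(source, target.loc[chosen], depth=depth, alpha=alpha, band=band)
        )

    per_taxon = (
        pd.concat([r.per_taxon[["p", "observed_freq", "predicted_freq"]] for r in runs])
        .groupby(level=0)
        .mean()
    )
    # majority class across the runs in which the taxon was modelled
    label_mode = (
        pd.concat([r.per_taxon["classification"] for r in runs])
        .groupby(level=0)
        .agg(lambda s: s.mode().iloc[0])
    )
    per_taxon["classification"] = label_mode
    mean_counts = {
        c: float(np.mean([r.class_counts[c] for r in runs])) for c in CLASS_LABELS
    }
    mean_rel = {
        c: float(np.mean([r.class_rel_abundance[c] for r in runs]))
        for c in CLASS_LABELS
    }
    return ReplicatedNCMFit(
        ntm=float(np.mean([r.ntm for r in runs])),
        spearman_rho=float(np.nanmean([r.spearman_rho for r in runs])),
        r_squared=float(np.nanmean([r.r_squared for r in runs])),
        class_counts=mean_counts,
        class_rel_abundance=mean_rel,
        per_taxon=per_taxon,
        runs=runs,
    )


def migration_rates(
    ntm: float,
    n_s: float,
    n_t: float,
    surface_area: float | None = None,
) -> MigrationEstimate:
    """Convert fitted N_T·m into migration rates.

    m_sample = ntm/N_s treats the sequencing sample as the community (the
    convention most studies report); m_true = ntm/N_T uses the measured
    cell number of the real community, exploiting that the composite
    parameter, not m alone, is what the occurrence-frequency fit pins
    down. m_per_area further normalizes by carrier surface area.
    """
    if ntm <= 0 or n_s <= 0 or n_t <= 0:
        raise ValueError("ntm, N_s and N_T must all be > 0")
    if n_t < n_s:
        warnings.warn(
            f"N_T={n_t:g} is smaller than the sequencing sample N_s={n_s:g}; "
            "the claimed community is smaller than its sample",
            stacklevel=2,
        )
    m_sample = ntm / n_s
    m_true = ntm / n_t
    m_per_area = None
    if surface_area is not None:
        if surface_area <= 0:
            raise ValueError("surface_area must be > 0")
        m_per_area = m_true / surface_area
    return MigrationEstimate(
        ntm=ntm,
        n_s=n_s,
        n_t=n_t,
        m_sample=m_sample,
        m_true=m_true,
        surface_area=surface_area,
        m_per_area=m_per_area,
    )
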