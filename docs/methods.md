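# Methods

This note records the models implemented, the conventions chosen where
the literature is not explicit, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Neutral community model

### Model and fitting

The model treats each local (biofilm) community as `N_T` individuals
undergoing death–replacement: with probability `m` the vacancy is filled
by an immigrant drawn from the source pool (taxon *i* with probability
`p_i`), otherwise by local reproduction. At stationarity the local
relative abundance `x_i` is approximately Beta(`N_T·m·p_i`,
`N_T·m·(1−p_i)`); only the composite `N_T·m` is identifiable from
compositional data. With detection limit `d` the occurrence frequency
across replicate communities is predicted as
`F(p) = 1 − I_d(N_T·m·p, N_T·m·(1−p))`, with limits `F(0)=0`, `F(1)=1`,
and `F` increasing in `p`.

Fitting minimizes `Σ_i (obs_i − F(p_i))²` by bounded scalar search over
`log10(N_T·m) ∈ [−2, 9]` (SciPy `minimize_scalar`, `xatol = 1e-8`); the
log scale keeps the one-dimensional search well conditioned across the
seven decades the parameter can span. A fit that lands within 0.05
decades of either bound is flagged `at_bound` (this happens when all
observed frequencies saturate at 1). Goodness of fit is reported as
Spearman ρ (average ranks on ties) and `R² = 1 − SSE/SST`; R² can be
negative when the model fits worse than a constant.

Conventions adopted where the standard workflow leaves them open:

* `p_i` is the mean of per-sample relative abundances across source
  samples (not pooled counts).
* `d = 1/N_s`, `N_s` the common rarefaction depth: a taxon is "detected"
  at one read.
* Only taxa with nonzero counts in both the source and the target
  tables are modelled; the model has nothing to say about taxa absent
  from either side.
* The replicated scheme (default ten runs of five target samples drawn
  without replacement, means across runs) is available for comparability
  across groups of unequal size; per-run fits are retained. When group
  labels permit, the "all targets" run draws one sample per group per
  run.

### Classification band

Each taxon's observed frequency (a count `k` out of `n` target samples)
is compared to an acceptance band around its predicted frequency. The
default band is the two-sided **mid-P binomial acceptance region**: the
set of `k/n` whose mid-P binomial test against `F(p_i)` is not rejected
at `α = 0.05`, widened if necessary to include the continuous
prediction itself. The familiar alternative — a Wilson score interval
recentred on the prediction (`band="wilson"`) — is retained for
compatibility with widely used implementations, but it is not a
calibrated test region: computing the exact acceptance probability over
a realistic spectrum of predicted frequencies gives a 9–10% non-neutral
rate at `n = 10..50` samples under perfect neutrality (the normal
approximation fails for the many taxa with small `n·F`). The mid-P
region holds the rate at ≈ 5% (computed: 0.052 at `n = 30`), which is
what a 95% band should do; that calibration is verified end-to-end by
the test suite and the reproduction script.

The aggregate per-class relative abundances are computed against the
full target table (shared and non-shared taxa), so "fraction of reads
neutral" refers to the whole community.

### Detection at finite sequencing depth

The beta-CDF prediction assumes a hard detection threshold at `d`.
Real detection through `N_s` multinomial reads is soft:
`P(detect) = 1 − (1−x)^{N_s}`, a smoothed step around `d`. Taxa sitting
just below the threshold are therefore detected more often than the
model predicts, which biases the least-squares `N_T·m` upward — by
roughly 13% at a true value of 50 and up to ~37% at 5000 under the
package's simulation conditions (depth 10⁴, 30 communities, 500 taxa;
measured by `benchmarks.ncm_recovery_reads`). This is a property of the
occurrence-frequency method, not of this implementation: under the
model's own detection process (`benchmarks.ncm_recovery`, thresholding
the stationary compositions at `d`) recovery is accurate to ≈ 1% across
`N_T·m ∈ {50, 500, 5000}`. Estimating `p_i` from a finite number of
source samples partially offsets the inflation (noise in `p` flattens
the fitted curve). Users comparing fitted `N_T·m` across groups
sequenced to the same depth are unaffected; absolute values carry this
depth-dependent bias.

### Migration rates

`m_sample = N_T·m / N_s` reproduces the convention of studies that
treat the sequencing sample as the community; `m_true = N_T·m / N_T`
exploits the fact that the fit pins down the composite, so a measured
community size (from qPCR-derived cell counts) converts it into a true
per-capita immigration probability. `m_per_area` divides `m_true` by
carrier surface area. A warning (not an error) is raised when
`N_T < N_s`, i.e. when the claimed community is smaller than its own
sample.

## Cell counts from qPCR

The community-average copy number is `Ĉ = Σ_i f̃_i c_i` with `f̃` the
read fractions and `c_i` the operon copy number from the deepest
matching taxonomic rank (semicolon-delimited paths are walked upward;
global table mean as final fallback). Cells are `total_copies / Ĉ`.

Read fractions are themselves copy-number weighted (a genome with more
operons yields proportionally more amplicons), so the arithmetic Ĉ
overestimates the per-cell average by exactly `1 + CV²(c)` under cell
weighting, and cell numbers are underestimated by the same factor
(≈ 20–30% for copy numbers uniform on 1..15). The package implements
the arithmetic form as the default because that is how the established
workflow behaves, and offers `weighting="harmonic"`
(`Ĉ = 1/Σ_i f̃_i/c_i`), which inverts the weighting exactly: with true
per-taxon copy numbers it recovers cell counts up to read-sampling
noise (the round-trip test verifies both the harmonic identity and the
arithmetic bias bound). Migration-rate conclusions are insensitive at
this scale because `m_true` spans orders of magnitude.

## Phylogenetic metrics and the richness null

Observed metrics (abundance weights are within-sample relative
abundances):

* Faith's PD: total branch length of the minimal subtree connecting a
  sample's taxa **and the root** (rooted convention). The shared
  root-path constant cancels in the SES because the null preserves
  richness.
* βMPD(a,b) = `Σ_i Σ_j f_i^a f_j^b d_ij` over the patristic matrix.
* βMNTD(a,b) = `½[Σ_i f_i^a min_{j∈b} d_ij + Σ_j f_j^b min_{i∈a} d_ij]`;
  shared taxa contribute zero (a taxon's nearest neighbour in the other
  community is itself).

All three are computed from a branch × taxon incidence matrix built
once per pool, which makes the 999-replicate null loops matrix products.

The richness null reassigns each sample's multiset of abundance values
to a uniformly random subset of pool taxa of the same size — per-sample
richness, row sums and the value multiset are preserved exactly. The
pool is the taxon set of the communities being compared: source ∪ group
for source-vs-biofilm comparisons, the group's own taxa for
within-group comparisons. Each null replicate randomizes the whole
matrix once and re-evaluates every unit on it.

`ses = (observed − null_mean)/null_sd`, reported unnegated: negative =
clustering, positive = overdispersion, |ses| > 2 significant. A null
distribution with (numerically) zero variance leaves the SES undefined
(NaN, never significant). Null replicate seeds are spawned from one
master `SeedSequence`, so results do not depend on evaluation order.
Note the richness null is deliberately sensitive (it randomizes
abundance structure onto the tree) and is known to be prone to type-I
clustering calls on strongly uneven communities; the self-null
calibration below shows it is exact when the data really are generated
by the null, which is the property the SES construction requires.

## Ordination

DPCoA: taxa are embedded by classical PCoA of the **square roots** of
patristic distances (tree metrics are generally not Euclidean-
embeddable; their square roots are, so the Gram matrix
`−½ J √D∘√D J = −½ J D J` is PSD up to round-off; eigenvalues below
`−10⁻⁸·λ_max` raise an error naming the offender). Samples sit at the
abundance-weighted centroids of their taxa; a final PCA of the sample
cloud weighted by sample totals (uniform after rarefaction) orders the
axes. Squared inter-sample distances equal the Rao DISC dissimilarity
`d_ab − ½(d_aa + d_bb)` exactly — verified against the definition on
small instances — and axis variance fractions are eigenvalue ratios.

Weighted UniFrac: `Σ_b l_b |A_b − B_b|` over branches, with `A_b` the
fraction of a sample's abundance descending from branch `b`; the raw
(unnormalized) variant is the default, `normalized=True` divides by
`Σ_b l_b (A_b + B_b)`. The implementation shares the branch-incidence
machinery and is cross-checked against scikit-bio's reference in the
test suite.

## Pipeline

Rarefaction subsamples each sample to exactly the target depth without
replacement (multivariate hypergeometric); samples below depth are
dropped with a warning, and the default depth is the smallest sample
total. Rarefaction happens once, before the source/target split. Stage
seeds derive from one master seed by hashing the stage name, so any
stage can be re-run in isolation and reproduce its section of the
report; reports carry a config hash and the package version, and contain
no timestamps, so identical inputs give byte-identical outputs.

## Synthetic data: what it emulates, what it does not

The generator mirrors the influent→biofilm design: one source pool and
one phylogeny shared by all groups, five sequenced source samples,
replicate target communities per group, per-taxon operon copy numbers,
and exact qPCR totals (`Σ cells_i·c_i`).

Default study conditions (chosen once, desk scale): 500 taxa; lognormal
(μ=0, σ=2) source abundances — the skew typical of amplicon surveys;
Yule (pure-birth, clocklike) tree with tip labels shuffled so clade
membership is independent of abundance rank; `N_T = 2000` cells,
`m = 0.1` (composite `N_T·m = 200`, the order implied by reported
sample-scale migration rates of ~3–7×10⁻³ at depths of ~4×10⁴); 25
communities; 25 generations (50 000 replacement events per community)
from a multinomial-of-`p` start; sequencing depth 10⁴; copy numbers
uniform on 1..15, spanning the real bacterial range.

The Moran assembler implements the model's generative process exactly:
per event one uniformly chosen individual dies; with probability `m`
the slot is refilled from the source (weight `p_i·w_i`), else by local
birth (weight `count_i·w_i`, counts taken after the death). Fitness
`w` acts multiplicatively on both channels — selection is not modelled
mechanistically, only strongly enough to produce the phylogenetic
signatures the SES metrics are meant to detect. Selection regimes:
`habitat_filter` favours the clade whose tip fraction is closest to the
requested fraction (error if no clade is within ±50% of it), the same
in every community; `homogeneous_selection` favours one random taxon
subset everywhere; `variable_selection` favours an independent subset
per community. The Dirichlet generator draws stationary compositions
directly (`Dirichlet(N_T·m·p)`) and is the fast path for
neutral-by-construction data; the two generators agree on occurrence
frequencies at matched `N_T·m` (cross-checked in the tests).

Not emulated: sequence-level artefacts (errors, chimeras), spatial
structure within biofilms, time series, taxonomy databases. Passing
tests therefore demonstrate correctness of the inference machinery on
data satisfying the model's assumptions plus realistic sampling — they
do not certify behaviour under PCR bias, compositional artefacts or
non-stationary dynamics.

## Validation experiment design

All experiments live in `biofilm_assembly.benchmarks`, seeded by a
single integer; `scripts/acceptance.py` re-runs them all.

* **Parameter recovery** — stationary compositions, detection by
  thresholding at `d` (the estimator's own model), true `p`; median
  fitted `N_T·m` over 10 replicate simulations at 50/500/5000. The
  read-path bias is reported separately (see above).
* **Classification calibration** — same design at `N_T·m = 200`,
  non-neutral fraction averaged over 5 replicate simulations (single
  simulations scatter ±0.8 percentage points around 3.8%).
* **Selection detection** — full read path (Moran, habitat filter
  `w = 5` on a ~10% clade, sequenced source samples): enrichment of the
  `above` class among truly favoured taxa, and the drop in Spearman ρ
  relative to a matched neutral run.
* **Moran chain oracle** — the 3-taxon, `N_T = 10` chain has 66 states;
  its transition matrix is built exactly and the stationary vector
  solved by eigendecomposition. The simulator's occupancy over 10⁶
  post-burn-in events (burn-in 10⁵) is compared by total variation;
  10⁶ events put the sampling error of the TV estimate near 0.01,
  comfortably inside the 0.05 tolerance (at 10⁵ events the estimate
  itself fluctuates between 0.025 and 0.05).
* **SES self-null** — count matrices are replaced by one richness-null
  draw, making every sample exchangeable with its own null; SES of PD
  is collected over 24 independent datasets × 25 samples = 600 units at
  999 nulls (600 units bring the standard error of the grand mean to
  ≈ 0.04).
* **Clustering/overdispersion recovery** — within-group βNTI/βNRI
  medians under neutral, habitat-filter and variable-selection regimes,
  pooled over 5 independent pools/trees (the clustering signal depends
  on how much source mass the filtered clade happens to carry; pooling
  5 trees makes the median robust to that draw).
* **Metric oracles** — PD/MPD/MNTD against brute-force enumeration on
  trees of ≤ 10 tips; DPCoA squared sample distances against the Rao
  definition on ≤ 6-taxon instances.

## Known limitations

* The NCM's absolute `N_T·m` inherits the finite-depth detection bias
  discussed above; cross-group comparisons at equal depth are safe.
* The arithmetic copy-number correction (the field's convention) under-
  counts cells by `1 + CV²(c)`; use `weighting="harmonic"` when the
  copy-number table is trusted.
* The richness null's sensitivity means strongly uneven neutral
  communities can show |βNTI| > 2 clustering; within-study contrasts
  (between groups, or against matched neutral simulations) are the
  reliable readout, as the directional experiments here illustrate.
* The Moran simulator is event-sequential (pure Python inner loop):
  practical up to ~10⁷ events per call, far beyond the desk-scale
  defaults but not a substitute for large-`N_T` production simulation.
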