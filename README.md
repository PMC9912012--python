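# biofilm-assembly

Tools for asking how much of a microbial community's composition is
explained by chance. The package targets the source→biofilm design used
in engineered systems such as moving bed biofilm reactors (MBBRs): a
planktonic influent community continuously seeds replicate biofilm
communities, and the analyst wants to know whether those biofilms
assembled by drift and migration (neutrally) or were shaped by
selection — and, if selected, by what kind.

It is aimed at microbial ecologists working with 16S rRNA amplicon count
tables, a phylogeny over the ASVs, and (optionally) qPCR totals of the
16S gene for absolute abundance.

## What it computes

**Sloan's neutral community model (NCM).** At stationarity of a local
community of `N_T` individuals receiving immigrants at rate `m` from a
source pool where taxon *i* has relative abundance `p_i`, the local
relative abundance of taxon *i* follows Beta(`N_T·m·p_i`,
`N_T·m·(1−p_i)`). With detection limit `d = 1/N_s` (one read at
sequencing depth `N_s`), the predicted occurrence frequency across
communities is

```
F(p) = 1 − I_d(N_T·m·p, N_T·m·(1−p))
```

(`I` the regularized incomplete beta function). The package fits the
single composite parameter `N_T·m` by least squares over observed
occurrence frequencies, reports Spearman ρ and R², and classifies each
taxon against a 95% acceptance band around its prediction as `neutral`,
`above` (more frequent than neutrality predicts — selected for) or
`below` (selected against). Replicated fitting on random target subsets
(ten runs of five samples, the usual design) is built in. With measured
cell numbers the composite parameter converts into migration rates:
`m_sample = N_T·m / N_s` (sample-as-community convention) and
`m_true = N_T·m / N_T` (true community size from qPCR), optionally
normalized per carrier surface area.

**Cell counting.** qPCR counts 16S gene copies, not cells; genomes carry
1–15+ rRNA operons. `cell_counts` assigns per-taxon operon numbers by
taxonomic match (with rank fallback), forms the community-average copy
number Ĉ per sample, and converts copies to cells `N_T = copies / Ĉ`.

**Phylogenetic null models.** Faith's PD, between-community βMPD and
βMNTD (abundance-weighted), and their standardized effect sizes against
the *richness* null model, which reassigns each sample's abundance
values to random taxa from a fixed pool while preserving per-sample
richness exactly. SES of βMNTD is the βNTI, SES of βMPD the βNRI;
negative values mean phylogenetic clustering, positive overdispersion,
and |SES| > 2 is flagged significant (999 randomizations by default).
Comparisons against the source community diagnose habitat filtering;
comparisons within replicate groups separate homogeneous from variable
selection.

**Ordination.** Double principal coordinate analysis (DPCoA: samples at
the abundance-weighted centroids of phylogenetically embedded taxa;
squared inter-sample distances equal Rao dissimilarities) and weighted
UniFrac.

**Synthetic data.** A fully seeded generator produces ground-truth
datasets in the same design: lognormal source pools, Yule phylogenies,
neutral Moran assembly with immigration (the NCM's exact generative
process, with an exactly solvable small-chain oracle), a fast
Dirichlet stationary sampler, habitat-filter / homogeneous / variable
selection regimes, and a forward sequencing model (cells → gene copies →
multinomial reads) with exact qPCR totals.

## Worked example

```python
import biofilm_assembly as ba
from biofilm_assembly.simulate import draw_copy_numbers, sequence_source_samples
from biofilm_assembly import cell_counts

pool = ba.make_source_pool(n_taxa=300, seed=7)
copy_numbers = draw_copy_numbers(pool.taxon_ids, (1, 15), seed=7)

# 20 biofilm communities of 10^6 cells at N_T*m = 200, sequenced to 10^4 reads
ensemble = ba.assemble_dirichlet(pool, ntm=200.0, n_communities=20, seed=7,
                                 community_size=1_000_000)
target, qpcr = ba.sequence_communities(ensemble, 10_000, copy_numbers, seed=8)
source = sequence_source_samples(pool, 5, 10_000, copy_numbers, seed=9)

fit = ba.fit_ncm(source, target, depth=10_000)
print(f"N_T*m = {fit.ntm:.1f}   Spearman rho = {fit.spearman_rho:.3f}")
print("classification:", fit.class_counts)

cells = cell_counts.estimate_cells(target, qpcr, copy_numbers)
n_t = cells["cells"].mean()
est = ba.migration_rates(fit.ntm, n_s=10_000, n_t=n_t, surface_area=1.0)
print(f"N_T = {n_t:.3g} cells   m_sample = {est.m_sample:.2e}   "
      f"m_true = {est.m_true:.2e}")
```

prints

```
N_T*m = 265.2   Spearman rho = 0.899
classification: {'below': 29, 'neutral': 208, 'above': 33}
N_T = 7.18e+05 cells   m_sample = 2.65e-02   m_true = 3.69e-04
```

The communities here are neutral by construction. The fit is good
(ρ ≈ 0.9) and most taxa and most reads are classified neutral; the
fitted `N_T·m` of 265 against a true 200, and the taxa spilling outside
the band, reflect finite sequencing depth — reads detect taxa slightly
below the nominal detection limit — a property of the occurrence-
frequency method discussed in `docs/methods.md`. The two migration rates
differ because they answer different questions: `m_sample` treats the
10⁴-read sample as the community, `m_true` uses the ~7×10⁵ measured
cells.

A command-line interface mirrors the library
(`biofilm-assembly simulate | ncm-fit | cells | ses | ordinate |
pipeline`); `biofilm-assembly pipeline --config config.yaml --out-dir out`
runs rarefaction → NCM (overall and per group) → cell counts and
migration rates → SES metrics → ordination from a counts TSV, a Newick
tree and a metadata TSV, writing every intermediate as TSV/JSON.

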