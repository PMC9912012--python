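"""Unit tests for the synthetic influent→biofilm generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import biofilm_assembly as ba
from biofilm_assembly.simulate import (
    ConfigurationError,
    draw_copy_numbers,
    moran_stationary_exact,
    sequence_source_samples,
    simulate_study,
)


class TestSourcePool:
    def test_single_taxon_is_everything(self):
        pool = ba.make_source_pool(1, seed=0)
        assert pool.rel_abundance.tolist() == [1.0]

    @pytest.mark.parametrize("distribution", ["lognormal", "logseries"])
    def test_valid_probability_vector(self, distribution):
        pool = ba.make_source_pool(1000, distribution, seed=3)
        assert pool.rel_abundance.size == 1000
        assert pool.rel_abundance.min() >= 0
        assert abs(pool.rel_abundance.sum() - 1.0) < 1e-9
        assert len(set(pool.taxon_ids)) == 1000

    def test_degenerate_lognormal_is_uniform(self):
        pool = ba.make_source_pool(100, params={"sigma": 0.0}, seed=1)
        np.testing.assert_allclose(pool.rel_abundance, 0.01)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            ba.make_source_pool(10, "zipf")

    def test_seed_reproducibility(self):
        a = ba.make_source_pool(50, seed=7)
        b = ba.make_source_pool(50, seed=7)
        np.testing.assert_array_equal(a.rel_abundance, b.rel_abundance)


class TestPhylogeny:
    def test_two_tips_form_cherry_with_clock(self):
        tree = ba.simulate_phylogeny(2, seed=5)
        tips = list(tree.tips())
        assert len(tips) == 2
        height = tree.height(include_self=False) if hasattr(tree, "height") else None
        dm = tree.tip_tip_distances()
        depths = [tip.accumulate_to_ancestor(tree) for tip in tips]
        assert depths[0] == pytest.approx(depths[1])
        assert dm.data.max() == pytest.approx(2 * depths[0])

    def test_ultrametric(self):
        tree = ba.simulate_phylogeny(64, seed=9)
        depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
        np.testing.assert_allclose(depths, depths[0], rtol=1e-9)

    def test_newick_determinism(self):
        a = str(ba.simulate_phylogeny(16, seed=2))
        b = str(ba.simulate_phylogeny(16, seed=2))
        assert a == b

    def test_needs_two_taxa(self):
        with pytest.raises(ConfigurationError):
            ba.simulate_phylogeny(1)


class TestMoran:
    def test_community_size_conserved(self):
        pool = ba.make_source_pool(20, seed=1)
        cfg = ba.SimulationConfig(
            n_taxa=20, community_size=77, n_communities=4, n_generations=8, seed=1
        )
        ens = ba.assemble_moran(pool, cfg)
        assert (ens.counts.sum(axis=1) == 77).all()

    def test_no_immigration_drifts_to_monodominance(self):
        pool = ba.make_source_pool(3, seed=2)
        cfg = ba.SimulationConfig(
            n_taxa=3,
            community_size=10,
            migration_rate=0.0,
            n_communities=10,
            n_generations=500,
            seed=2,
        )
        ens = ba.assemble_moran(pool, cfg)
        assert (ens.counts.max(axis=1) == 10).all()

    def test_full_immigration_tracks_source(self):
        # m=1: every replacement is a source draw, so the across-community
        # mean composition converges to p.
        pool = ba.make_source_pool(10, seed=3)
        cfg = ba.SimulationConfig(
            n_taxa=10,
            community_size=100,
            migration_rate=1.0,
            n_communities=40,
            n_generations=10,
            seed=3,
        )
        ens = ba.assemble_moran(pool, cfg)
        mean_comp = (ens.counts / 100).mean(axis=0).to_numpy()
        assert np.abs(mean_comp - pool.rel_abundance).max() < 0.03

    def test_invalid_migration_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ba.SimulationConfig(n_taxa=5, migration_rate=1.5)

    def test_all_zero_fitness_rejected(self):
        pool = ba.make_source_pool(5, seed=1)
        cfg = ba.SimulationConfig(
            n_taxa=5, community_size=10, n_communities=2, n_generations=1, seed=1
        )
        with pytest.raises(ConfigurationError):
            ba.assemble_moran(pool, cfg, np.zeros((2, 5)))

    def test_bit_reproducible(self):
        pool = ba.make_source_pool(15, seed=4)
        cfg = ba.SimulationConfig(
            n_taxa=15, community_size=50, n_communities=3, n_generations=5, seed=4
        )
        a = ba.assemble_moran(pool, cfg).counts
        b = ba.assemble_moran(pool, cfg).counts
        pd.testing.assert_frame_equal(a, b)

    def test_exact_chain_single_individual_matches_source(self):
        # with N_T=1 every replacement is an immigration, so the chain's
        # stationary law over pure states equals p
        p = np.array([0.6, 0.3, 0.1])
        pi = moran_stationary_exact(p, 1, 0.5)
        assert pi[(1, 0, 0)] == pytest.approx(0.6, abs=1e-12)
        assert pi[(0, 1, 0)] == pytest.approx(0.3, abs=1e-12)
        assert pi[(0, 0, 1)] == pytest.approx(0.1, abs=1e-12)


class TestDirichlet:
    def test_large_concentration_pins_to_source(self):
        pool = ba.make_source_pool(50, seed=5)
        ens = ba.assemble_dirichlet(pool, 1e6, 10, seed=5, community_size=1_000_000)
        comps = ens.counts.to_numpy() / 1_000_000
        assert np.abs(comps - pool.rel_abundance).max() < 0.01

    def test_two_taxon_marginal_is_uniform(self):
        # Beta(1, 1) marginal: p = (1/2, 1/2) with ntm = 2
        pool = ba.SourcePool(("a", "b"), np.array([0.5, 0.5]))
        ens = ba.assemble_dirichlet(pool, 2.0, 4000, seed=6, community_size=1_000_000)
        x = ens.counts["a"].to_numpy() / 1_000_000
        assert stats.kstest(x, "uniform").pvalue > 1e-3

    def test_nonpositive_ntm_rejected(self):
        pool = ba.make_source_pool(5, seed=0)
        with pytest.raises(ConfigurationError):
            ba.assemble_dirichlet(pool, 0.0, 3)

    def test_agrees_with_moran_occurrence(self):
        # cross-generator check: occurrence frequencies at matched N_T·m
        pool = ba.make_source_pool(40, seed=8)
        cfg = ba.SimulationConfig(
            n_taxa=40,
            community_size=500,
            migration_rate=0.2,
            n_communities=30,
            n_generations=60,
            seed=8,
        )
        moran = ba.assemble_moran(pool, cfg)
        diri = ba.assemble_dirichlet(
            pool, 100.0, 30, seed=9, community_size=500
        )
        occ_m = (moran.counts > 0).mean(axis=0).to_numpy()
        occ_d = (diri.counts > 0).mean(axis=0).to_numpy()
        # binomial sampling error at 30 communities: ~2.5 sd tolerance
        tol = 2.5 * np.sqrt(occ_d * (1 - occ_d) / 30 + occ_m * (1 - occ_m) / 30) + 0.05
        assert (np.abs(occ_m - occ_d) <= tol).mean() > 0.9


class TestSelectionRegimes:
    def _setup(self, regime, n_taxa=64, n_comm=10, fraction=0.1):
        pool = ba.make_source_pool(n_taxa, seed=10)
        tree = ba.simulate_phylogeny(n_taxa, seed=10)
        cfg = ba.SimulationConfig(
            n_taxa=n_taxa,
            n_communities=n_comm,
            selection_regime=regime,
            filter_clade_fraction=fraction,
            fitness_advantage=5.0,
            seed=10,
        )
        return pool, tree, cfg

    def test_neutral_gives_unit_weights(self):
        pool, tree, cfg = self._setup("neutral")
        fitness = ba.apply_selection_regime(pool, tree, cfg)
        assert (fitness == 1.0).all()

    def test_habitat_filter_favours_a_clade(self):
        pool, tree, cfg = self._setup("habitat_filter")
        fitness = ba.apply_selection_regime(pool, tree, cfg)
        favoured = [t for t, w in zip(pool.taxon_ids, fitness[0]) if w > 1]
        assert favoured
        # monophyly: the favoured set is exactly the tip set of its LCA
        lca = tree.lca([tree.find(t) for t in favoured])
        assert {t.name for t in lca.tips()} == set(favoured)
        # identical in every community
        assert (fitness == fitness[0]).all()

    def test_variable_selection_differs_between_communities(self):
        pool, tree, cfg = self._setup("variable_selection")
        fitness = ba.apply_selection_regime(pool, tree, cfg)
        assert any((fitness[c] != fitness[0]).any() for c in range(1, len(fitness)))

    def test_unmatchable_clade_fraction_raises(self):
        pool, tree, cfg = self._setup("habitat_filter", n_taxa=16, fraction=0.001)
        with pytest.raises(ConfigurationError, match="clade"):
            ba.apply_selection_regime(pool, tree, cfg)


class TestSequencing:
    def _ensemble(self, n_taxa=10, size=1000, n_comm=3):
        pool = ba.make_source_pool(n_taxa, seed=12)
        cfg = ba.SimulationConfig(
            n_taxa=n_taxa,
            community_size=size,
            n_communities=n_comm,
            n_generations=2,
            seed=12,
        )
        return pool, ba.assemble_moran(pool, cfg)

    def test_unit_copy_numbers_give_cell_totals(self):
        pool, ens = self._ensemble()
        cn = pd.Series(1.0, index=list(pool.taxon_ids))
        reads, qpcr = ba.sequence_communities(ens, 500, cn, seed=1)
        assert (qpcr == 1000).all()
        assert (reads.sum(axis=1) == 500).all()

    def test_single_taxon_community(self):
        pool = ba.SourcePool(("only",), np.array([1.0]))
        cfg = ba.SimulationConfig(
            n_taxa=1, community_size=1000, n_communities=1, n_generations=1, seed=0
        )
        ens = ba.assemble_moran(pool, cfg)
        cn = pd.Series([4.0], index=["only"])
        reads, qpcr = ba.sequence_communities(ens, 200, cn, seed=0)
        assert qpcr.iloc[0] == 4000
        assert reads.iloc[0, 0] == 200

    def test_copy_number_scale_invariance(self):
        pool, ens = self._ensemble()
        cn = draw_copy_numbers(pool.taxon_ids, (1, 15), seed=3)
        reads1, qpcr1 = ba.sequence_communities(ens, 500, cn, seed=4)
        reads2, qpcr2 = ba.sequence_communities(ens, 500, 2 * cn, seed=4)
        pd.testing.assert_frame_equal(reads1, reads2)
        np.testing.assert_allclose(qpcr2, 2 * qpcr1)


class TestStudySimulation:
    def test_dataset_shapes_and_metadata(self):
        cfg = ba.SimulationConfig(
            n_taxa=30, community_size=200, n_communities=4, n_generations=3,
            sequencing_depth=300, seed=1,
        )
        ds = simulate_study({"Z50": cfg, "Z300": dataclasses.replace(cfg, seed=2)})
        meta = ds["metadata"]
        assert (meta["role"] == "source").sum() == 5
        assert (meta["role"] == "target").sum() == 8
        assert set(ds["counts"].index) == set(meta["sample_id"])
        assert ds["counts"].shape[1] == 30
        qpcr = meta.loc[meta["role"] == "target", "qpcr_copies"]
        assert (qpcr > 0).all()

    def test_source_samples_reflect_copy_bias(self):
        pool = ba.make_source_pool(3, params={"sigma": 0.0}, seed=0)
        cn = pd.Series([1.0, 1.0, 8.0], index=list(pool.taxon_ids))
        reads = sequence_source_samples(pool, 20, 3000, cn, seed=1)
        frac = reads.sum(axis=0) / reads.to_numpy().sum()
        assert frac.iloc[2] > 0.7  # 8/10 of the copy-weighted mass
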