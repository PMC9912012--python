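"""Unit tests for phylogenetic metrics and the richness-null SES machinery."""

import numpy as np
import pandas as pd
import pytest

import biofilm_assembly as ba
from conftest import random_counts


# --- independent brute-force oracles --------------------------------------

def brute_faith_pd(taxa_present, tree):
    """Union of the edges on every root-to-tip path, summed once."""
    edges = {}
    for name in taxa_present:
        node = tree.find(name)
        while node.parent is not None:
            edges[id(node)] = node.length or 0.0
            node = node.parent
    return sum(edges.values())


def brute_mpd(fa, fb, dist):
    total = 0.0
    for i in fa.index:
        for j in fb.index:
            total += fa[i] * fb[j] * dist.loc[i, j]
    return total


def brute_mntd(fa, fb, dist):
    a = fa[fa > 0]
    b = fb[fb > 0]
    term_a = sum(a[i] * min(dist.loc[i, j] for j in b.index) for i in a.index)
    term_b = sum(b[j] * min(dist.loc[i, j] for i in a.index) for j in b.index)
    return 0.5 * (term_a + term_b)


class TestFaithPD:
    def test_star_tree_full_sample(self, star_tree):
        assert ba.faith_pd(["A", "B", "C"], star_tree) == pytest.approx(3.0)

    def test_single_tip_includes_root_path(self, cherry_tree):
        assert ba.faith_pd(["A"], cherry_tree) == pytest.approx(2.0)

    def test_empty_sample_rejected(self, star_tree):
        with pytest.raises(ValueError):
            ba.faith_pd([], star_tree)

    def test_matches_brute_force_on_random_subsets(self, rng):
        for trial in range(15):
            n = int(rng.integers(4, 11))
            tree = ba.simulate_phylogeny(n, seed=trial)
            tips = [t.name for t in tree.tips()]
            k = int(rng.integers(1, n + 1))
            subset = list(rng.choice(tips, size=k, replace=False))
            assert ba.faith_pd(subset, tree) == pytest.approx(
                brute_faith_pd(subset, tree), abs=1e-9
            )


class TestBetaMetrics:
    def test_distinct_singletons(self, star_tree):
        dist = ba.patristic_matrix(star_tree)
        a = pd.Series({"A": 1.0})
        b = pd.Series({"B": 1.0})
        assert ba.comdist_mpd(a, b, dist) == pytest.approx(2.0)
        assert ba.comdistnt_mntd(a, b, dist) == pytest.approx(2.0)

    def test_identical_singletons_are_zero(self, star_tree):
        dist = ba.patristic_matrix(star_tree)
        a = pd.Series({"A": 1.0})
        assert ba.comdist_mpd(a, a, dist) == 0.0
        assert ba.comdistnt_mntd(a, a, dist) == 0.0

    def test_mntd_zero_when_all_taxa_shared(self, cherry_tree):
        dist = ba.patristic_matrix(cherry_tree)
        a = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
        b = pd.Series({"A": 0.1, "B": 0.1, "C": 0.8})
        assert ba.comdistnt_mntd(a, b, dist) == pytest.approx(0.0)

    def test_missing_taxon_rejected(self, star_tree):
        dist = ba.patristic_matrix(star_tree)
        with pytest.raises(ValueError, match="missing"):
            ba.comdist_mpd(pd.Series({"Z": 1.0}), pd.Series({"A": 1.0}), dist)

    def test_match_brute_force_and_symmetry(self, rng):
        for trial in range(10):
            n = int(rng.integers(3, 11))
            tree = ba.simulate_phylogeny(n, seed=100 + trial)
            tips = sorted(t.name for t in tree.tips())
            dist = ba.patristic_matrix(tree, tips)
            raw = rng.random(n) * (rng.random(n) < 0.7)
            raw2 = rng.random(n) * (rng.random(n) < 0.7)
            raw[int(rng.integers(n))] += 0.5
            raw2[int(rng.integers(n))] += 0.5
            fa = pd.Series(raw / raw.sum(), index=tips)
            fb = pd.Series(raw2 / raw2.sum(), index=tips)
            assert ba.comdist_mpd(fa, fb, dist) == pytest.approx(
                brute_mpd(fa, fb, dist), abs=1e-9
            )
            assert ba.comdistnt_mntd(fa, fb, dist) == pytest.approx(
                brute_mntd(fa, fb, dist), abs=1e-9
            )
            assert ba.comdist_mpd(fa, fb, dist) == pytest.approx(
                ba.comdist_mpd(fb, fa, dist)
            )
            assert ba.comdistnt_mntd(fa, fb, dist) == pytest.approx(
                ba.comdistnt_mntd(fb, fa, dist)
            )


class TestRichnessNull:
    def test_own_taxa_pool_permutes_rows(self, rng):
        counts = random_counts(rng, 4, [f"t{i}" for i in range(8)])
        null = ba.richness_null(counts, list(counts.columns), seed_or_rng=5)
        for s in counts.index:
            orig = sorted(counts.loc[s][counts.loc[s] > 0])
            randomized = sorted(null.loc[s][null.loc[s] > 0])
            assert orig == randomized
        assert (null.sum(axis=1) == counts.sum(axis=1)).all()
        assert ((null > 0).sum(axis=1) == (counts > 0).sum(axis=1)).all()

    def test_richness_preserved_with_larger_pool(self, rng):
        counts = random_counts(rng, 5, [f"t{i}" for i in range(6)])
        pool = [f"t{i}" for i in range(30)]
        null = ba.richness_null(counts, pool, seed_or_rng=6)
        assert ((null > 0).sum(axis=1).to_numpy()
                == (counts > 0).sum(axis=1).to_numpy()).all()

    def test_pool_must_cover_observed_taxa(self, rng):
        counts = random_counts(rng, 3, ["a", "b", "c"])
        with pytest.raises(ValueError, match="pool"):
            ba.richness_null(counts, ["a", "b"], seed_or_rng=0)


class TestSES:
    def test_fixed_seed_reproducible(self, rng):
        tree = ba.simulate_phylogeny(12, seed=3)
        counts = random_counts(rng, 6, sorted(t.name for t in tree.tips()))
        a = ba.ses_pd(counts, tree, n_null=99, seed=11)
        b = ba.ses_pd(counts, tree, n_null=99, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = ba.ses_beta(counts, tree, "mntd", n_null=99, seed=11)
        d = ba.ses_beta(counts, tree, "mntd", n_null=99, seed=11)
        pd.testing.assert_frame_equal(c, d)

    def test_degenerate_null_flagged_not_significant(self):
        # richness equal to the pool size: every randomization is a
        # permutation of the same full row -> PD null has zero variance
        tree = ba.simulate_phylogeny(5, seed=4)
        tips = sorted(t.name for t in tree.tips())
        counts = pd.DataFrame([[1, 2, 3, 4, 5]], index=["s0"], columns=tips)
        res = ba.ses_pd(counts, tree, n_null=25, seed=0)
        assert np.isnan(res["ses"].iloc[0])
        assert not res["significant"].iloc[0]

    def test_clade_confined_communities_are_clustered(self, rng):
        # all abundance restricted to one small clade of a large tree:
        # PD and MNTD fall far below the richness-null expectation
        n = 64
        tree = ba.simulate_phylogeny(n, seed=6)
        tips = sorted(t.name for t in tree.tips())
        node = next(
            nd for nd in tree.non_tips() if 6 <= nd.count(tips=True) <= 10
        )
        clade = sorted(t.name for t in node.tips())
        counts = pd.DataFrame(0, index=[f"s{i}" for i in range(6)], columns=tips)
        for i in range(6):
            chosen = rng.choice(clade, size=5, replace=False)
            counts.loc[f"s{i}", chosen] = rng.integers(5, 50, size=5)
        pd_res = ba.ses_pd(counts, tree, pool=tips, n_null=399, seed=7)
        assert (pd_res["ses"] < -2).all()
        nti = ba.ses_beta(counts, tree, "mntd", pool=tips, n_null=399, seed=7)
        assert nti["ses"].median() < -2

    def test_vs_source_and_within_group_designs(self, rng):
        tree = ba.simulate_phylogeny(20, seed=8)
        tips = sorted(t.name for t in tree.tips())
        counts = random_counts(rng, 8, tips)
        meta = pd.DataFrame(
            {
                "sample_id": counts.index,
                "role": ["source"] * 2 + ["target"] * 6,
                "group": ["influent"] * 2 + ["Z50"] * 3 + ["Z300"] * 3,
            }
        )
        vs = ba.ses_metric("mntd", counts, tree, meta, "vs_source", n_null=49, seed=9)
        assert len(vs) == 2 * 3 * 2  # two groups x (2 sources x 3 targets)
        within = ba.ses_metric("mpd", counts, tree, meta, "within_group", n_null=49, seed=9)
        assert len(within) == 2 * 3  # two groups x C(3,2)
        pd_units = ba.ses_metric("pd", counts, tree, meta, "within_group", n_null=49, seed=9)
        assert len(pd_units) == 6
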