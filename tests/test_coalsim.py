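"""Coalescent correctness and determinism of the simulation layer."""

import itertools

import msprime
import numpy as np
import pytest
import scipy.stats

from dcfs.coalsim import (
    NonCoalescingError,
    SampleConfig,
    drop_mutations,
    mutate_replicates,
    simulate_genealogy,
    simulate_replicates,
)
from dcfs.demography import AdmixtureParams, Deme, SpatialParams, build_spatial_model
from dcfs.stats import site_dcfs

from conftest import bare_demography, chain_demography


def pair_tmrcas(demog, sample, n, seed):
    """TMRCA of the two European chromosomes per replicate."""
    out = np.empty(n)
    for i, gen in enumerate(simulate_replicates(demog, sample, n, seed)):
        tree = gen.tree
        eur = np.flatnonzero(gen.roles == 3)
        out[i] = tree.tmrca(int(eur[0]), int(eur[1]))
    return out


class TestCoalescentCorrectness:
    def test_single_deme_pair_tmrca_mean_and_distribution(self, single_deme, pair_sample):
        """A sampled pair in one deme of size N coalesces in Exp(mean 2N)."""
        demog, N = single_deme
        times = pair_tmrcas(demog, pair_sample, 20_000, seed=11)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 2 * N) <= 2 * se
        # exponential shape, not just the mean
        stat = scipy.stats.kstest(times[:10_000], "expon", args=(0, 2 * N))
        assert stat.pvalue > 0.01

    @pytest.mark.parametrize("m", [0.02, 0.2])
    def test_strobeck_invariance_on_symmetric_chain(self, m, pair_sample):
        """Deme-averaged within-deme pair TMRCA equals the panmictic 2kN,
        independent of the migration rate (conservative migration)."""
        k, N = 3, 200.0
        per_deme = 4_000
        times = []
        for d in range(k):
            demog = chain_demography(k, N, m)
            sample = SampleConfig(n_chimp=1, n_neandertal=1, n_african=1,
                                  n_european=2, neandertal_time=0.0,
                                  demes={r: f"d{d}" for r in
                                         ("chimp", "neandertal", "african", "european")})
            times.append(pair_tmrcas(demog, sample, per_deme, seed=37 + d))
        times = np.concatenate(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 2 * k * N) <= 3 * se

    def test_ancient_sample_sits_at_its_sampling_time(self):
        demog = build_spatial_model(SpatialParams())
        gen = simulate_genealogy(demog, SampleConfig(), seed=3)
        nea = int(np.flatnonzero(gen.roles == 1)[0])
        assert gen.ts.node(nea).time == pytest.approx(2_000.0)  # 50 ky / 25


class TestDeterminism:
    def test_same_seed_same_tree_different_seed_different_tree(self, single_deme, pair_sample):
        demog, _ = single_deme
        a = simulate_genealogy(demog, pair_sample, seed=5)
        b = simulate_genealogy(demog, pair_sample, seed=5)
        c = simulate_genealogy(demog, pair_sample, seed=6)
        assert a.newick() == b.newick()
        assert a.newick() != c.newick()

    def test_replicates_reproducible_and_start_with_single_draw(self, single_deme, pair_sample):
        demog, _ = single_deme
        first = simulate_genealogy(demog, pair_sample, seed=9)
        reps1 = [g.newick() for g in simulate_replicates(demog, pair_sample, 5, seed=9)]
        reps2 = [g.newick() for g in simulate_replicates(demog, pair_sample, 5, seed=9)]
        assert reps1 == reps2
        assert reps1[0] == first.newick()
        assert len(set(reps1)) > 1

    def test_bad_n_loci_rejected(self, single_deme, pair_sample):
        demog, _ = single_deme
        with pytest.raises(ValueError):
            list(simulate_replicates(demog, pair_sample, 0, seed=1))


class TestNonCoalescing:
    def test_disconnected_demes_raise(self):
        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=100)
        dem.add_population(name="b", initial_size=100)
        demog = bare_demography(
            dem, [Deme("a", 100, "ancestral"), Deme("b", 100, "ancestral")],
            sampling={"chimp": "a", "neandertal": "a", "african": "b", "european": "b"})
        sample = SampleConfig(n_european=2, neandertal_time=0.0)
        with pytest.raises(NonCoalescingError):
            simulate_genealogy(demog, sample, seed=2)

    def test_max_time_horizon_enforced(self, single_deme, pair_sample):
        demog, _ = single_deme
        with pytest.raises(NonCoalescingError, match="horizon"):
            simulate_genealogy(demog, pair_sample, seed=2, max_time=1.0)


class TestMutations:
    def test_site_count_matches_poisson_mean(self, single_deme, pair_sample):
        """Total mutation count over replicates ~ Poisson(mu * total length)."""
        demog, _ = single_deme
        mu = 5e-4
        total_sites = 0
        total_length = 0.0
        for i, gen in enumerate(simulate_replicates(demog, pair_sample, 2_000, seed=21)):
            table = drop_mutations(gen, mu, seed=100 + i)
            total_sites += table.n_sites
            total_length += gen.total_branch_length
        mean = mu * total_length
        assert abs(total_sites - mean) <= 4 * np.sqrt(mean)

    def test_sites_are_biallelic_and_zero_one_coded(self, single_deme, pair_sample):
        demog, _ = single_deme
        gen = simulate_genealogy(demog, pair_sample, seed=8)
        table = drop_mutations(gen, 5e-3, seed=8)
        values = table.data[table.sample_columns].to_numpy()
        assert set(np.unique(values)) <= {0, 1}

    def test_mutate_replicates_concatenates_loci(self, single_deme, pair_sample):
        demog, _ = single_deme
        trees = simulate_replicates(demog, pair_sample, 50, seed=13)
        table = mutate_replicates(trees, 5e-3, seed=13)
        assert "locus" in table.data.columns
        assert table.data["locus"].nunique() > 1

    def test_zero_rate_rejected(self, single_deme, pair_sample):
        demog, _ = single_deme
        gen = simulate_genealogy(demog, pair_sample, seed=8)
        with pytest.raises(ValueError):
            drop_mutations(gen, 0.0, seed=1)


class TestExchangeability:
    def test_european_label_permutation_leaves_dcfs_unchanged(self):
        """Statistics treat the European panel exchangeably."""
        demog = build_spatial_model(
            SpatialParams(N_mod=500, N_anc=200, founder_size=200))
        sample = SampleConfig(n_european=4)
        trees = simulate_replicates(demog, sample, 30, seed=17)
        tables = [drop_mutations(g, 2e-3, seed=40 + i) for i, g in enumerate(trees)]
        table = next(t for t in tables if t.n_sites > 0)
        permuted = table.data.rename(columns={
            "eur_0": "eur_2", "eur_2": "eur_0", "eur_1": "eur_3", "eur_3": "eur_1"})
        from dcfs.stats import GenotypeTable

        a = site_dcfs(table)
        b = site_dcfs(GenotypeTable(permuted))
        np.testing.assert_array_equal(a.weights, b.weights)
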