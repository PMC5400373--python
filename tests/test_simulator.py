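"""Coalescent and mutation-model oracles.

Monte-Carlo expectations used here: the mean pairwise coalescence time in a
panmictic population of diploid size N is 2N generations; under the strict
stepwise mutation model at equilibrium the expected gene diversity is
1 - 1/sqrt(1 + 8*N*mu) (Ohta-Kimura); (δμ)² grows linearly with divergence
time; bottlenecks depress diversity. msprime serves as an independent
implementation of the structured coalescent for a divergence scenario.
"""

import numpy as np
import pytest

import invasion_abc as ia
from invasion_abc.simulator import GSMModel, drop_mutations, simulate_genealogies


def _one_pop(n_diploids, ne=1000):
    return ia.Scenario("one", ["A"], {"A": ne}, [ia.Sample("A", n_diploids)])


class TestGenealogies:
    def test_pairwise_tmrca_matches_2n(self):
        sc = _one_pop(1, ne=1000)
        tm = np.array(
            [simulate_genealogies(sc, {}, s, n_loci=1).trees[0].tmrca
             for s in range(20_000)]
        )
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - 2000.0) < 3 * se

    def test_admixture_r1_equals_divergence(self):
        """ADMIX with r=1 sends every lineage to source1, so mean TMRCA
        matches the corresponding DIVERGE scenario."""
        common = dict(populations=["A", "B", "C"], ne={"A": 500, "B": 500, "C": 500})
        samples = [ia.Sample("A", 5), ia.Sample("B", 5), ia.Sample("C", 5)]
        div = ia.Scenario(
            "div", events=samples + [ia.Diverge("C", "A", 50.0),
                                     ia.Diverge("B", "A", 2000.0)], **common)
        adm = ia.Scenario(
            "adm", events=samples + [ia.Admix("C", "A", "B", 1.0, 50.0),
                                     ia.Diverge("B", "A", 2000.0)], **common)
        t_div = np.array(
            [simulate_genealogies(div, {}, s, n_loci=1).trees[0].tmrca
             for s in range(4000)]
        )
        t_adm = np.array(
            [simulate_genealogies(adm, {}, 10_000 + s, n_loci=1).trees[0].tmrca
             for s in range(4000)]
        )
        se = np.sqrt(t_div.var() / len(t_div) + t_adm.var() / len(t_adm))
        assert abs(t_div.mean() - t_adm.mean()) < 3 * se

    def test_single_diploid_gives_two_leaves(self):
        gen = simulate_genealogies(_one_pop(1), {}, 0, n_loci=3)
        for tree in gen.trees:
            assert tree.n_leaves == 2
            assert np.all(tree.branch_lengths()[: tree.n_leaves] >= 0)

    def test_leaf_count_conservation(self):
        sc = ia.Scenario(
            "two", ["A", "B"], {"A": 300, "B": 400},
            [ia.Sample("A", 4), ia.Sample("B", 7), ia.Diverge("B", "A", 100.0)],
        )
        gen = simulate_genealogies(sc, {}, 5, n_loci=2)
        assert all(t.n_leaves == 2 * (4 + 7) for t in gen.trees)

    def test_unreachable_ancestor_raises(self):
        sc = ia.Scenario(
            "island", ["A", "B"], {"A": 100, "B": 100},
            [ia.Sample("A", 2), ia.Sample("B", 2)],  # never merged
        )
        with pytest.raises(ia.simulator.ScenarioSimulationError):
            simulate_genealogies(sc, {}, 0, n_loci=1)

    def test_msprime_cross_check_divergence_tmrca(self):
        """Independent structured-coalescent implementation agrees on the
        mean TMRCA of a two-population divergence scenario."""
        msprime = pytest.importorskip("msprime")
        ne_a, ne_b, t_split, n = 800.0, 400.0, 500.0, 4
        sc = ia.Scenario(
            "split", ["A", "B"], {"A": ne_a, "B": ne_b},
            [ia.Sample("A", n), ia.Sample("B", n), ia.Diverge("B", "A", t_split)],
        )
        ours = np.array(
            [simulate_genealogies(sc, {}, s, n_loci=1).trees[0].tmrca
             for s in range(3000)]
        )
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=ne_a)
        dem.add_population(name="B", initial_size=ne_b)
        # explicit ancestral deme of A's size: in msprime a sampled population
        # reused as the split ancestor would be inactive before the split
        dem.add_population(name="ANC", initial_size=ne_a)
        dem.add_population_split(time=t_split, derived=["A", "B"], ancestral="ANC")
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples={"A": n, "B": n}, demography=dem,
                    num_replicates=3000, random_seed=7, ploidy=2,
                )
            ]
        )
        se = np.sqrt(ours.var() / len(ours) + theirs.var() / len(theirs))
        assert abs(ours.mean() - theirs.mean()) < 3 * se


class TestMutations:
    def test_zero_rate_gives_monomorphic_data(self):
        gen = simulate_genealogies(_one_pop(10), {}, 1, n_loci=5)
        ds = drop_mutations(gen, GSMModel(mu=0.0), 2)
        for j in range(5):
            assert len(np.unique(ds.genotypes["A"][:, j, :])) == 1

    def test_alleles_stay_inside_window(self):
        model = GSMModel(mu=5e-3, p_geom=0.6, window_lo=20, window_hi=29)
        gen = simulate_genealogies(_one_pop(10, ne=5000), {}, 3, n_loci=10)
        ds = drop_mutations(gen, model, 4)
        alleles = ds.genotypes["A"]
        assert alleles.min() >= 20 and alleles.max() <= 29

    def test_smm_equilibrium_gene_diversity(self):
        """Strict stepwise model (p_geom = 0): equilibrium gene diversity
        matches the Ohta-Kimura closed form 1 - 1/sqrt(1 + 8*N*mu)."""
        ne, mu = 1000.0, 5e-4
        expected = 1.0 - 1.0 / np.sqrt(1.0 + 8.0 * ne * mu)
        model = GSMModel(mu=mu, p_geom=0.0, window_lo=0, window_hi=200,
                         locus_rates=np.full(20, mu))
        hets = []
        for s in range(25):
            gen = simulate_genealogies(_one_pop(25, ne=ne), {}, s, n_loci=20)
            ds = drop_mutations(gen, model, 1000 + s)
            hets.append(ia.one_sample_stats(ds, "A")["HET"])
        mean_h = np.mean(hets)
        se = np.std(hets) / np.sqrt(len(hets))
        assert abs(mean_h - expected) < 3 * se

    def test_delta_mu_squared_grows_with_divergence_time(self):
        """(δμ)² is linear in divergence time under stepwise mutation: its
        mean must increase along a divergence-time grid (rank correlation)."""
        from scipy.stats import spearmanr

        model = GSMModel(mu=5e-4, p_geom=0.0, window_lo=0, window_hi=400,
                         locus_rates=np.full(10, 5e-4))
        times = [100.0, 1000.0, 4000.0, 12_000.0]
        means = []
        for k, t in enumerate(times):
            sc = ia.Scenario(
                "d", ["A", "B"], {"A": 500, "B": 500},
                [ia.Sample("A", 10), ia.Sample("B", 10), ia.Diverge("B", "A", t)],
            )
            vals = []
            for s in range(60):
                gen = simulate_genealogies(sc, {}, 5000 * k + s, n_loci=10)
                ds = drop_mutations(gen, model, 777 + s)
                vals.append(ia.two_sample_stats(ds, "A", "B")["DM2"])
            means.append(np.mean(vals))
        rho, _ = spearmanr(times, means)
        assert rho > 0
        assert means[-1] > means[0]


class TestSimulateDataset:
    def test_sample_config_respected(self):
        sc = ia.Scenario(
            "two", ["A", "B"], {"A": 2000, "B": 2000},
            [ia.Sample("A"), ia.Sample("B"), ia.Diverge("B", "A", 100.0)],
        )
        ds = ia.simulate_dataset(sc, {}, {"A": 15, "B": 44}, 9, n_loci=5)
        assert ds.sample_sizes() == {"A": 15, "B": 44}

    def test_seed_reproducibility(self):
        sc = _one_pop(8)
        d1 = ia.simulate_dataset(sc, {"mu": 5e-4}, None, 77, n_loci=6)
        d2 = ia.simulate_dataset(sc, {"mu": 5e-4}, None, 77, n_loci=6)
        assert d1.equals(d2)
        d3 = ia.simulate_dataset(sc, {"mu": 5e-4}, None, 78, n_loci=6)
        assert not d1.equals(d3)

    def test_stronger_bottleneck_lowers_diversity(self):
        """A 100x more severe founding bottleneck lowers mean gene diversity
        in the founded population (one-sided Monte-Carlo comparison)."""
        def founded(nb):
            return ia.Scenario(
                "f", ["S", "T"], {"S": 5000, "T": 5000},
                [
                    ia.Sample("S", 15), ia.Sample("T", 15),
                    ia.SizeChange("T", nb, 40.0),
                    ia.Diverge("T", "S", 60.0),
                ],
            )
        h_weak, h_strong = [], []
        for s in range(60):
            for nb, acc in ((500.0, h_weak), (5.0, h_strong)):
                ds = ia.simulate_dataset(founded(nb), {"mu": 5e-4}, None, 100 + s, n_loci=10)
                acc.append(ia.one_sample_stats(ds, "T")["HET"])
        assert np.mean(h_strong) < np.mean(h_weak)
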