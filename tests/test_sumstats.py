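"""Summary-statistic definitions, catalog counting rules, and invariances.

The Weir-Cockerham FST oracle here goes through the ANOVA mean-squares route
(sums of squares over allele indicators at the gene-copy level), an
algebraically different path from the package's direct variance-component
formulas.
"""

import itertools
import warnings

import numpy as np
import pytest

import invasion_abc as ia
from invasion_abc.genotype_data import GenotypeDataset


def _dataset(pop_genotypes: dict, n_loci: int | None = None) -> GenotypeDataset:
    pops = list(pop_genotypes)
    arrs = {p: np.asarray(g, dtype=np.int64) for p, g in pop_genotypes.items()}
    n_loci = n_loci or next(iter(arrs.values())).shape[1]
    return GenotypeDataset(pops, [f"L{j}" for j in range(n_loci)], arrs)


def anova_fst(dataset: GenotypeDataset) -> float:
    """Weir-Cockerham theta via ANOVA mean squares on allele indicators.

    For each allele, gene copies y (0/1 indicators) are grouped by
    individual within population; the three mean squares (among populations,
    among individuals within populations, within individuals) give the
    variance components. Summed over alleles and loci before taking the
    ratio (multi-locus ratio estimator).
    """
    num = den = 0.0
    for j in range(dataset.n_loci):
        per_pop = []
        for p in dataset.populations:
            g = dataset.genotypes[p][:, j, :]
            g = g[np.all(g != ia.MISSING, axis=1)]
            if len(g):
                per_pop.append(g)
        if len(per_pop) < 2:
            continue
        alleles = np.unique(np.concatenate([g.ravel() for g in per_pop]))
        if len(alleles) < 2:
            continue
        n_i = np.array([len(g) for g in per_pop], dtype=float)
        r = len(per_pop)
        n_tot = n_i.sum()
        nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
        for a in alleles:
            # y[i][k, l] = indicator that copy l of individual k in pop i is a
            ybar_pop = [np.mean(g == a) for g in per_pop]
            ybar_ind = [np.mean(g == a, axis=1) for g in per_pop]
            ybar = sum((g == a).sum() for g in per_pop) / (2 * n_tot)
            ss_p = sum(2 * n * (yp - ybar) ** 2 for n, yp in zip(n_i, ybar_pop))
            ss_i = sum(
                2 * ((yi - yp) ** 2).sum()
                for yp, yi in zip(ybar_pop, ybar_ind)
            )
            ss_g = sum(
                (((g == a).astype(float) - yi[:, None]) ** 2).sum()
                for g, yi in zip(per_pop, ybar_ind)
            )
            ms_p = ss_p / (r - 1)
            ms_i = ss_i / (n_tot - r)
            ms_g = ss_g / n_tot
            sa = (ms_p - ms_i) / (2 * nc)
            sb = (ms_i - ms_g) / 2
            sc = ms_g
            num += sa
            den += sa + sb + sc
    return num / den if den else float("nan")


class TestOneSample:
    def test_monomorphic_locus(self):
        ds = _dataset({"a": [[[10, 10]], [[10, 10]]]})
        s = ia.one_sample_stats(ds, "a")
        assert s == {"NAL": 1.0, "HET": 0.0, "VAR": 0.0, "MGW": 1.0}

    def test_garza_williamson_with_gap(self):
        # alleles {10, 12}: M = 2 / (range 2 + 1)
        ds = _dataset({"a": [[[10, 12]], [[10, 12]]]})
        assert ia.one_sample_stats(ds, "a")["MGW"] == pytest.approx(2 / 3)

    def test_unbiased_diversity_single_heterozygote(self):
        ds = _dataset({"a": [[[10, 11]]]})
        assert ia.one_sample_stats(ds, "a")["HET"] == pytest.approx(1.0)

    def test_missing_alleles_skipped(self):
        ds = _dataset({"a": [[[10, 11]], [[0, 0]], [[10, 10]]]})
        # only 2 usable individuals -> 4 copies, p = (3/4, 1/4)
        expected = 4 / 3 * (1 - (0.75**2 + 0.25**2))
        assert ia.one_sample_stats(ds, "a")["HET"] == pytest.approx(expected)


class TestTwoSample:
    def test_full_fixation_gives_fst_one(self):
        ds = _dataset({
            "a": [[[10, 10], [20, 20]]] * 8,
            "b": [[[14, 14], [26, 26]]] * 8,
        }, n_loci=2)
        assert ia.two_sample_stats(ds, "a", "b")["FST"] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        g = rng.integers(10, 16, size=(20, 5, 2))
        ds = _dataset({"a": g, "b": g.copy()})
        s = ia.two_sample_stats(ds, "a", "b")
        assert abs(s["FST"]) < 0.05
        assert s["DM2"] == 0.0

    def test_wc_oracle_on_toy_table(self):
        # A: 6 copies of allele 10, 2 of 11; B: 2 of 10, 6 of 11
        ds = _dataset({
            "a": [[[10, 10]], [[10, 10]], [[10, 10]], [[10, 11]]],
            "b": [[[11, 11]], [[11, 11]], [[11, 11]], [[11, 10]]],
        })
        ours = ia.two_sample_stats(ds, "a", "b")["FST"]
        assert ours == pytest.approx(anova_fst(ds), abs=1e-12)

    def test_wc_oracle_exhaustive_small_tables(self):
        """Random sweep of 2-population, 1-locus tables with <= 6 allele
        states: direct variance components agree with the ANOVA route."""
        rng = np.random.default_rng(42)
        for trial in range(150):
            k = rng.integers(2, 7)
            na, nb = rng.integers(2, 9, size=2)
            ga = rng.integers(10, 10 + k, size=(na, 1, 2))
            gb = rng.integers(10, 10 + k, size=(nb, 1, 2))
            ds = _dataset({"a": ga, "b": gb})
            oracle = anova_fst(ds)
            ours = ia.wc_fst(ds)
            if np.isnan(oracle):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-10), f"trial {trial}"

    def test_delta_mu_squared_definition(self):
        ds = _dataset({
            "a": [[[10, 10]]] * 4,
            "b": [[[13, 13]]] * 4,
        })
        assert ia.two_sample_stats(ds, "a", "b")["DM2"] == pytest.approx(9.0)

    def test_das_bounds_and_sharing(self):
        ds = _dataset({
            "a": [[[10, 11]]] * 3,
            "b": [[[10, 11]]] * 3,
        })
        assert ia.two_sample_stats(ds, "a", "b")["DAS"] == pytest.approx(0.0)
        ds2 = _dataset({
            "a": [[[10, 10]]] * 3,
            "b": [[[11, 11]]] * 3,
        })
        assert ia.two_sample_stats(ds2, "a", "b")["DAS"] == pytest.approx(1.0)


class TestThreeSample:
    def test_pure_source1(self):
        ds = _dataset({
            "adm": [[[10, 10]]] * 6,
            "s1": [[[10, 10]]] * 6,
            "s2": [[[20, 20]]] * 6,
        })
        r, flag = ia.three_sample_stats(ds, "adm", "s1", "s2")
        assert r == pytest.approx(1.0)
        assert not flag

    def test_symmetric_mixture(self):
        adm = [[[10, 20]]] * 10  # every individual carries one copy of each
        ds = _dataset({
            "adm": adm,
            "s1": [[[10, 10]]] * 6,
            "s2": [[[20, 20]]] * 6,
        })
        r, _ = ia.three_sample_stats(ds, "adm", "s1", "s2")
        assert r == pytest.approx(0.5)

    def test_degenerate_sources_flagged(self):
        same = [[[10, 10]]] * 5
        ds = _dataset({"adm": same, "s1": same, "s2": same})
        r, flag = ia.three_sample_stats(ds, "adm", "s1", "s2")
        assert flag and r == 0.5

    def test_estimator_consistency_under_sampling(self):
        """Genotypes drawn from a true 75:25 frequency mixture: the mean
        estimate over replicates approaches 0.75."""
        rng = np.random.default_rng(3)
        f1 = np.array([0.8, 0.15, 0.05])
        f2 = np.array([0.05, 0.15, 0.8])
        fm = 0.75 * f1 + 0.25 * f2
        vals = []
        for _ in range(200):
            def draw(freqs, n=60):
                return rng.choice([10, 11, 12], size=(n, 1, 2), p=freqs)
            ds = _dataset({"adm": draw(fm), "s1": draw(f1), "s2": draw(f2)})
            vals.append(ia.three_sample_stats(ds, "adm", "s1", "s2")[0])
        assert abs(np.mean(vals) - 0.75) < 0.05


class TestCatalog:
    @pytest.mark.parametrize("p,expected", [(1, 4), (3, 39), (5, 130),
                                            (6, 204), (7, 301), (8, 424)])
    def test_counting_rule(self, p, expected):
        names, _ = ia.catalog_names([f"p{i}" for i in range(p)])
        assert len(names) == expected
        assert len(set(names)) == expected

    def test_estimation_subset_counts(self):
        pops = [f"p{i}" for i in range(12)]
        triplets = [tuple(pops[k:k + 3]) for k in range(5)]
        names, _ = ia.estimation_subset_names(pops, triplets)
        assert len(names) == 95
        pops2 = ["a", "b"]
        names2, _ = ia.estimation_subset_names(pops2, [])
        assert len(names2) == 5

    def test_complement_count_for_12_populations(self):
        pops = [f"p{i}" for i in range(12)]
        triplets = [tuple(pops[k:k + 3]) for k in range(5)]
        est, _ = ia.estimation_subset_names(pops, triplets)
        comp = ia.test_statistic_complement(pops, est)
        assert len(comp) == 1141

    def test_full_catalog_values_match_individual_functions(self):
        rng = np.random.default_rng(8)
        ds = _dataset({
            p: rng.integers(10, 20, size=(6, 3, 2)) for p in ("x", "y", "z")
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv = ia.full_catalog(ds)
        assert len(sv) == 39
        d = sv.as_dict()
        one = ia.one_sample_stats(ds, "x")
        assert d["NAL_x"] == pytest.approx(one["NAL"])
        assert d["MGW_x"] == pytest.approx(one["MGW"])
        two = ia.two_sample_stats(ds, "x", "y")
        assert d["FST_x_y"] == pytest.approx(two["FST"])
        assert d["LIKAB_x_y"] == pytest.approx(two["LIKAB"])
        aml, _ = ia.three_sample_stats(ds, "y", "x", "z")
        assert d["AML_y_x_z"] == pytest.approx(aml)

    def test_invariance_to_individual_and_allele_order(self):
        rng = np.random.default_rng(5)
        geno = {p: rng.integers(10, 25, size=(8, 4, 2)) for p in ("x", "y", "z")}
        ds = _dataset(geno)
        shuffled = {}
        for p, g in geno.items():
            g2 = g[rng.permutation(len(g))].copy()
            flip = rng.random(g2.shape[:2]) < 0.5
            g2[flip] = g2[flip][:, ::-1]
            shuffled[p] = g2
        ds2 = _dataset(shuffled)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v1 = ia.full_catalog(ds)
            v2 = ia.full_catalog(ds2)
        # DAS involves individual pairings but is an average -> identical
        np.testing.assert_allclose(v1.values, v2.values, rtol=1e-12)

    def test_bounded_statistics(self, small_world):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv = ia.full_catalog(small_world.dataset)
        d = sv.as_dict()
        for name, v in d.items():
            if name.startswith(("HET", "H2P", "DAS")):
                assert 0.0 <= v <= 1.0, name
            if name.startswith("AML"):
                assert 0.0 <= v <= 1.0, name

    def test_unknown_triplet_population_rejected(self):
        ds = _dataset({"a": [[[10, 10]]], "b": [[[10, 10]]], "c": [[[10, 10]]]})
        with pytest.raises(KeyError):
            ia.estimation_subset(ds, [("a", "b", "nope")])
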