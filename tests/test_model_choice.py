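"""ABC-RF and ABC-LDA model-choice behaviour.

Two engineered baselines drive these checks: a pair of *identically defined*
scenarios, where any correct method must be at chance (prior error ~ 1/2,
posterior ~ 1/2, votes ~ 50:50), and a *separable* pair with non-overlapping
effective-size regimes, where the error must be near zero and the vote share
for the generating scenario near one.
"""

import math
import warnings

import numpy as np
import pytest

import invasion_abc as ia
from invasion_abc.abc_rf import append_lda_axes


class TestLDAAxes:
    def test_k_minus_one_axes(self, identical_pair_table, small_table):
        t2 = append_lda_axes(identical_pair_table)
        assert sum(c.startswith("LDA") for c in t2.stat_names) == 1
        t3 = append_lda_axes(small_table)
        assert sum(c.startswith("LDA") for c in t3.stat_names) == 2

    def test_observed_row_projects_to_its_axis_values(self, small_table):
        t = append_lda_axes(small_table)
        from invasion_abc.abc_rf import _observed_matrix

        base_cols = [c for c in small_table.stat_names]
        row = small_table.stats.iloc[5]
        sv = ia.StatVector(base_cols, row.to_numpy(), [0] * len(base_cols))
        x = _observed_matrix(t, sv).ravel()
        np.testing.assert_allclose(x, t.stats.iloc[5].to_numpy(), rtol=1e-9)

    def test_idempotent(self, identical_pair_table):
        once = append_lda_axes(identical_pair_table)
        assert append_lda_axes(once) is once


class TestRF:
    def test_vote_conservation(self, small_table, observed_stats):
        mc = ia.rf_model_choice(small_table, observed_stats, n_trees=150, rng_seed=0)
        assert mc.votes.sum() == 150
        assert 0.0 <= mc.posterior_probability <= 1.0

    def test_identical_scenarios_are_chance_level(self, identical_pair_table):
        ds = ia.simulate_dataset(
            ia.Scenario("A", ["P"], {"P": 5000}, [ia.Sample("P")]),
            {"mu": 5e-4}, {"P": 15}, 99, n_loci=10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = ia.full_catalog(ds)
        mc = ia.rf_model_choice(
            identical_pair_table, obs, n_trees=300, rng_seed=1, n_replicates=3
        )
        share = mc.votes.max() / mc.votes.sum()
        assert share < 0.5 + 0.12
        assert abs(mc.prior_error_rate - 0.5) < 0.1
        assert abs(mc.posterior_probability - 0.5) < 0.2

    def test_separable_pair_recovers_truth(self, separable_pair):
        table, observed, truth = separable_pair
        mc = ia.rf_model_choice(table, observed, n_trees=300, rng_seed=2)
        assert mc.best_scenario == truth
        assert mc.votes[mc.scenario_names.index(truth)] / mc.votes.sum() > 0.9
        assert mc.prior_error_rate < 0.05
        assert mc.posterior_probability > 0.9

    def test_replicates_report_spread(self, separable_pair):
        table, observed, _ = separable_pair
        mc = ia.rf_model_choice(table, observed, n_trees=100, rng_seed=3,
                                n_replicates=4)
        assert len(mc.replicate_posteriors) == 4
        assert mc.posterior_sd >= 0.0
        assert mc.prior_error_sd >= 0.0

    def test_mismatched_observed_names_rejected(self, small_table):
        bad = ia.StatVector(["nope"], np.array([1.0]), [1])
        with pytest.raises(KeyError):
            ia.rf_model_choice(small_table, bad, n_trees=10, rng_seed=0)

    def test_prior_error_shrinks_with_table_size(self, separable_pair):
        """On a separable pair, the out-of-bag prior error at a larger table
        is no worse (within Monte-Carlo slack) than at a small one."""
        table, _, _ = separable_pair
        rng = np.random.default_rng(0)
        small_rows = rng.choice(table.n_rows, size=80, replace=False)
        small = ia.ReferenceTable(
            scenario_names=list(table.scenario_names),
            scenario_idx=table.scenario_idx[small_rows],
            params=table.params.iloc[small_rows].reset_index(drop=True),
            stats=table.stats.iloc[small_rows].reset_index(drop=True),
        )
        e_small = ia.prior_error_rate_rf(small, n_trees=200, rng_seed=1)
        e_big = ia.prior_error_rate_rf(table, n_trees=200, rng_seed=1)
        assert e_big <= e_small + 0.05

    def test_holdout_error_method(self, separable_pair):
        table, _, _ = separable_pair
        e = ia.prior_error_rate_rf(table, n_trees=100, rng_seed=5, method="holdout")
        assert e < 0.1


class TestLDA:
    def test_probability_simplex(self, small_table, observed_stats):
        res = ia.lda_model_choice(small_table, observed_stats, tolerance=0.05)
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.probabilities >= 0)

    def test_accepted_count_contract(self, small_table, observed_stats):
        res = ia.lda_model_choice(small_table, observed_stats, tolerance=0.01)
        assert res.n_accepted == math.ceil(0.01 * small_table.n_rows)

    def test_identical_scenarios_near_half(self, identical_pair_table):
        ds = ia.simulate_dataset(
            ia.Scenario("A", ["P"], {"P": 5000}, [ia.Sample("P")]),
            {"mu": 5e-4}, {"P": 15}, 101, n_loci=10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = ia.full_catalog(ds)
        res = ia.lda_model_choice(identical_pair_table, obs, tolerance=0.1)
        assert abs(res.probabilities[0] - 0.5) < 0.25

    def test_separable_pair(self, separable_pair):
        table, observed, truth = separable_pair
        res = ia.lda_model_choice(table, observed, tolerance=0.05)
        assert res.best_scenario == truth
        assert res.probability_of(truth) > 0.9

    def test_prior_error_identical_near_half(self, identical_pair_table):
        e = ia.prior_error_rate_lda(
            identical_pair_table, tolerance=0.1, n_pseudo=80, rng_seed=2
        )
        assert abs(e - 0.5) < 0.2

    def test_prior_error_separable_low(self, separable_pair):
        table, _, _ = separable_pair
        e = ia.prior_error_rate_lda(table, tolerance=0.05, n_pseudo=80, rng_seed=3)
        assert e < 0.05

    def test_single_pseudo_gives_zero_or_one(self, separable_pair):
        table, _, _ = separable_pair
        e = ia.prior_error_rate_lda(table, tolerance=0.05, n_pseudo=1, rng_seed=4)
        assert e in (0.0, 1.0)

    def test_ci_brackets_probability(self, separable_pair):
        table, observed, truth = separable_pair
        res = ia.lda_model_choice(table, observed, tolerance=0.05, with_ci=True)
        lo, hi = res.best_ci
        assert 0.0 <= lo <= res.probability_of(res.best_scenario) <= hi <= 1.0


def test_lda_choice_less_stable_on_small_tables():
    """Rejection+regression model choice on a hard pair: the winning
    scenario varies across replicate reference tables more often when the
    tables are small than when they are larger (reduced-scale instability
    check, 20 table seeds per size)."""
    from collections import Counter

    sc_a = ia.Scenario("const", ["P"], {"P": "N_P"}, [ia.Sample("P")])
    sc_b = ia.Scenario(
        "shift", ["P"], {"P": "N_P"},
        [ia.Sample("P"), ia.SizeChange("P", "Nb_P", 60.0)],
    )
    prior = ia.PriorSpec(
        {
            "N_P": ia.Distribution("uniform", 1_000, 10_000),
            "Nb_P": ia.Distribution("uniform", 20, 2_000),
            "mu": ia.Distribution("loguniform", 1e-4, 1e-3),
        }
    )
    obs_ds = ia.simulate_dataset(
        sc_b, {"N_P": 5000, "Nb_P": 800, "mu": 4e-4}, {"P": 15}, 555, n_loci=10
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = ia.full_catalog(obs_ds)

    def instability(rows):
        winners = []
        for seed in range(20):
            table = ia.build_reference_table(
                [sc_a, sc_b], prior, rows, {"P": 15}, stat_set="full",
                rng_seed=1000 + seed, n_loci=10,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                winners.append(
                    ia.lda_model_choice(
                        table, obs, tolerance=0.05, with_ci=False
                    ).best_scenario
                )
        counts = Counter(winners)
        return 1.0 - counts.most_common(1)[0][1] / len(winners)

    assert instability(80) >= instability(400)


def test_prior_error_rate_rf_k4_identical():
    """Four identically defined scenarios: prior error ~ (K-1)/K = 0.75."""
    scs = [
        ia.Scenario(f"S{k}", ["P"], {"P": "N_P"}, [ia.Sample("P")])
        for k in range(4)
    ]
    prior = ia.PriorSpec(
        {
            "N_P": ia.Distribution("uniform", 1_000, 10_000),
            "mu": ia.Distribution("loguniform", 1e-4, 1e-3),
        }
    )
    table = ia.build_reference_table(
        scs, prior, 150, {"P": 15}, stat_set="full", rng_seed=9, n_loci=10
    )
    e = ia.prior_error_rate_rf(table, n_trees=200, rng_seed=0)
    assert abs(e - 0.75) < 0.1
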