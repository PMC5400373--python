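"""Shared fixtures: toy worlds and reference tables are expensive, so they
are built once per session and reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import invasion_abc as ia


@pytest.fixture(scope="session")
def small_world() -> ia.ToyWorld:
    return ia.make_toy_invasion("small", rng_seed=1)


@pytest.fixture(scope="session")
def small_table(small_world) -> ia.ReferenceTable:
    """Full-catalog table over the small world's 3 competing scenarios."""
    return ia.build_reference_table(
        small_world.competing,
        small_world.prior,
        500,
        small_world.sample_config,
        stat_set="full",
        rng_seed=11,
        n_loci=small_world.n_loci,
    )


@pytest.fixture(scope="session")
def observed_stats(small_world) -> ia.StatVector:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ia.full_catalog(small_world.dataset)


@pytest.fixture(scope="session")
def identical_pair_table() -> ia.ReferenceTable:
    """Two scenarios defined identically: the indistinguishable baseline."""
    sc_a = ia.Scenario("A", ["P"], {"P": "N_P"}, [ia.Sample("P")])
    sc_b = ia.Scenario("B", ["P"], {"P": "N_P"}, [ia.Sample("P")])
    prior = ia.PriorSpec(
        {
            "N_P": ia.Distribution("uniform", 1_000, 10_000),
            "mu": ia.Distribution("loguniform", 1e-4, 1e-3),
        }
    )
    return ia.build_reference_table(
        [sc_a, sc_b], prior, 400, {"P": 15}, stat_set="full",
        rng_seed=5, n_loci=10,
    )


@pytest.fixture(scope="session")
def separable_pair():
    """Two one-population scenarios with non-overlapping effective sizes,
    trivially separable from diversity statistics alone."""
    sc_low = ia.Scenario("low", ["P"], {"P": 200}, [ia.Sample("P")])
    sc_high = ia.Scenario("high", ["P"], {"P": 50_000}, [ia.Sample("P")])
    prior = ia.PriorSpec({"mu": ia.Distribution("uniform", 4e-4, 6e-4)})
    table = ia.build_reference_table(
        [sc_low, sc_high], prior, 300, {"P": 15}, stat_set="full",
        rng_seed=7, n_loci=10,
    )
    ds = ia.simulate_dataset(sc_low, {"mu": 5e-4}, {"P": 15}, 123, n_loci=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = ia.full_catalog(ds)
    return table, observed, "low"


@pytest.fixture(scope="session")
def truth_table(small_world) -> ia.ReferenceTable:
    """Single-scenario (the truth) table with estimation-subset statistics,
    for parameter-recovery and posterior-predictive tests."""
    return ia.build_reference_table(
        [small_world.scenario],
        small_world.prior,
        1500,
        small_world.sample_config,
        stat_set=("estimation", small_world.triplets),
        rng_seed=23,
        n_loci=small_world.n_loci,
    )


@pytest.fixture(scope="session")
def observed_simulator():
    return simulate_observed_stats


def simulate_observed_stats(world, seed, stat="estimation", mu_factor=1.0):
    """Observed statistic vector drawn under the world's true parameters."""
    params = dict(world.params.values)
    params["mu"] = params["mu"] * mu_factor
    ds = ia.simulate_dataset(
        world.scenario, params, world.sample_config, seed, n_loci=world.n_loci
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if stat == "estimation":
            return ia.estimation_subset(ds, world.triplets)
        return ia.full_catalog(ds)
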