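"""Toy invasion histories with known truth.

These worlds emulate the structure of a multi-site microsatellite invasion
study — several population samples of diploid individuals, unlinked loci,
nested divergences with founding bottlenecks, and an admixture event whose
rate is to be recovered — at sizes where every pipeline stage runs at desk
scale. Effect sizes (divergence depths, bottleneck severities, admixture
rates) are deliberately large so that recovery is statistically comfortable;
all values live in this one file so tests are auditable. The worlds make no
attempt to match any real dataset's allele-frequency spectra.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .demography import (
    Admix,
    Distribution,
    Diverge,
    ParameterVector,
    PriorSpec,
    Sample,
    Scenario,
    SizeChange,
    first_record_to_generations,
)
from .genotype_data import GenotypeDataset
from .simulator import simulate_dataset
from .sumstats import estimation_subset_names, full_catalog


@dataclass
class ToyWorld:
    """A complete synthetic study: truth, data, and the competing models."""

    profile: str
    scenario: Scenario                     # the true model
    params: ParameterVector                # the true parameter values
    dataset: GenotypeDataset               # the "observed" sample
    competing: list[Scenario]              # enumeration containing the truth
    prior: PriorSpec
    first_records: dict[str, int]          # year of first record per invader
    sampling_year: int
    sample_config: dict[str, int]
    n_loci: int
    triplets: list[tuple[str, str, str]]   # declared admixture triplets
    target: str = ""
    severity_truth: dict[str, float] = field(default_factory=dict)


def _bottleneck(pop: str, t_intro: float) -> SizeChange:
    return SizeChange(pop, f"Nb_{pop}", f"{t_intro} - db_{pop}")


def _competing_set(
    base_pops: list[str],
    base_ne: dict[str, str],
    base_events: list,
    target: str,
    sources: list[str],
    t_intro: float,
) -> list[Scenario]:
    """Single-source and pairwise-admixture scenarios for one target over a
    fixed demographic backbone (k + C(k,2) competing models)."""
    out: list[Scenario] = []
    for src in sources:
        events = base_events + [_bottleneck(target, t_intro), Diverge(target, src, t_intro)]
        out.append(Scenario(f"{target}<-{src}", list(base_pops), dict(base_ne), events))
    for s1, s2 in itertools.combinations(sources, 2):
        events = base_events + [
            _bottleneck(target, t_intro),
            Admix(target, s1, s2, f"r_{target}", t_intro),
        ]
        out.append(
            Scenario(f"{target}<-{s1}+{s2}", list(base_pops), dict(base_ne), events)
        )
    return out


def _small_world(rng: np.random.Generator, seed: int) -> ToyWorld:
    sampling_year = 2013
    first_records = {"inv1": 2003, "inv2": 2009}
    t_inv1 = first_record_to_generations(first_records["inv1"], sampling_year)
    t_inv2 = first_record_to_generations(first_records["inv2"], sampling_year)

    pops = ["nat1", "nat2", "inv1", "inv2"]
    ne = {p: f"N_{p}" for p in pops}
    base_events = (
        [Sample(p) for p in pops]
        + [_bottleneck("inv2", t_inv2), Diverge("inv2", "inv1", t_inv2)]
        + [Diverge("nat2", "nat1", "t_anc")]
    )
    competing = _competing_set(pops, ne, base_events, "inv1", ["nat1", "nat2"], t_inv1)
    truth = next(s for s in competing if s.name == "inv1<-nat1+nat2")

    prior = PriorSpec(
        distributions={
            **{f"N_{p}": Distribution("uniform", 1_000, 20_000) for p in pops},
            "Nb_inv1": Distribution("uniform", 2, 200),
            "db_inv1": Distribution("uniform", 1, 40),
            "Nb_inv2": Distribution("uniform", 2, 200),
            "db_inv2": Distribution("uniform", 1, 40),
            "r_inv1": Distribution("uniform", 0.05, 0.95),
            "t_anc": Distribution("uniform", 500, 6_000),
            "mu": Distribution("loguniform", 1e-4, 1e-3),
            "p_geom": Distribution("uniform", 1e-6, 0.5),
        },
        name="set1",
    )
    true_values = {
        "N_nat1": 4_000.0, "N_nat2": 4_000.0, "N_inv1": 4_000.0, "N_inv2": 4_000.0,
        "Nb_inv1": 50.0, "db_inv1": 25.0,      # severity 0.5 (strong class)
        "Nb_inv2": 200.0, "db_inv2": 1.0,      # severity 0.005 (weak class)
        "r_inv1": 0.5,
        "t_anc": 4_000.0,
        "mu": 5e-4,
        "p_geom": 0.22,
    }
    params = ParameterVector(true_values, prior_set="set1", seed=seed)
    sample_config = {p: 20 for p in pops}
    n_loci = 10
    dataset = simulate_dataset(
        truth, params, sample_config, rng_seed=int(rng.integers(2**31)), n_loci=n_loci
    )
    return ToyWorld(
        profile="small",
        scenario=truth,
        params=params,
        dataset=dataset,
        competing=competing,
        prior=prior,
        first_records=first_records,
        sampling_year=sampling_year,
        sample_config=sample_config,
        n_loci=n_loci,
        triplets=[("inv1", "nat1", "nat2")],
        target="inv1",
        severity_truth={
            "inv1": true_values["db_inv1"] / true_values["Nb_inv1"],
            "inv2": true_values["db_inv2"] / true_values["Nb_inv2"],
        },
    )


def _paper_like_world(rng: np.random.Generator, seed: int) -> ToyWorld:
    sampling_year = 2013
    first_records = {
        "haw": 1980, "us_w": 2008, "us_e": 2010, "eur": 2008, "bra": 2011,
    }
    t = {
        p: first_record_to_generations(y, sampling_year)
        for p, y in first_records.items()
    }
    pops = ["nat1", "nat2", "nat3", "haw", "us_w", "us_e", "eur", "bra"]
    ne = {p: f"N_{p}" for p in pops}
    base_events = (
        [Sample(p) for p in pops]
        + [_bottleneck("eur", t["eur"]), Diverge("eur", "nat3", t["eur"])]
        + [_bottleneck("us_e", t["us_e"]), Diverge("us_e", "us_w", t["us_e"])]
        + [_bottleneck("us_w", t["us_w"]),
           Admix("us_w", "nat2", "haw", "r_us_w", t["us_w"])]
        + [_bottleneck("haw", t["haw"]), Diverge("haw", "nat1", t["haw"])]
        + [Diverge("nat3", "nat2", "t_anc2"), Diverge("nat2", "nat1", "t_anc1")]
    )
    competing = _competing_set(pops, ne, base_events, "bra", ["us_w", "us_e"], t["bra"])
    truth = next(s for s in competing if s.name == "bra<-us_w+us_e")

    dists = {f"N_{p}": Distribution("uniform", 1_000, 20_000) for p in pops}
    for p in ("haw", "us_w", "us_e", "eur", "bra"):
        dists[f"Nb_{p}"] = Distribution("uniform", 2, 200)
        dists[f"db_{p}"] = Distribution("uniform", 1, 30)
    dists["r_us_w"] = Distribution("uniform", 0.05, 0.95)
    dists["r_bra"] = Distribution("uniform", 0.05, 0.95)
    dists["t_anc2"] = Distribution("uniform", 500, 3_000)
    dists["t_anc1"] = Distribution("uniform", 1_000, 8_000)
    dists["mu"] = Distribution("loguniform", 1e-4, 1e-3)
    dists["p_geom"] = Distribution("uniform", 1e-6, 0.5)
    prior = PriorSpec(dists, constraints=[("t_anc1", "t_anc2")], name="set1")

    true_values = {
        **{f"N_{p}": 5_000.0 for p in pops},
        "Nb_haw": 5.0, "db_haw": 20.0,        # strong founding bottleneck
        "Nb_us_w": 30.0, "db_us_w": 10.0,
        "Nb_us_e": 80.0, "db_us_e": 8.0,
        "Nb_eur": 40.0, "db_eur": 15.0,
        "Nb_bra": 50.0, "db_bra": 8.0,
        "r_us_w": 0.75, "r_bra": 0.5,
        "t_anc2": 2_000.0, "t_anc1": 4_000.0,
        "mu": 5e-4, "p_geom": 0.22,
    }
    params = ParameterVector(true_values, prior_set="set1", seed=seed)
    sample_config = {p: int(rng.integers(15, 45)) for p in pops}
    n_loci = 25
    dataset = simulate_dataset(
        truth, params, sample_config, rng_seed=int(rng.integers(2**31)), n_loci=n_loci
    )
    return ToyWorld(
        profile="paper-like",
        scenario=truth,
        params=params,
        dataset=dataset,
        competing=competing,
        prior=prior,
        first_records=first_records,
        sampling_year=sampling_year,
        sample_config=sample_config,
        n_loci=n_loci,
        triplets=[("us_w", "nat2", "haw"), ("bra", "us_w", "us_e")],
        target="bra",
        severity_truth={
            p: true_values[f"db_{p}"] / true_values[f"Nb_{p}"]
            for p in ("haw", "us_w", "us_e", "eur", "bra")
        },
    )


def make_toy_invasion(profile: str = "small", rng_seed: int = 0) -> ToyWorld:
    """Generate a reproducible synthetic invasion study.

    ``"small"``: 4 populations (a native pair plus two invasive), 10 loci,
    20 diploids per sample — sized for fast end-to-end tests. ``"paper-like"``:
    8 populations, 25 loci, samples of 15–44 diploids, with an admixture
    between a native source and an earlier invasive population and a serial
    intra-continental colonization.
    """
    rng = np.random.default_rng(rng_seed)
    if profile == "small":
        return _small_world(rng, rng_seed)
    if profile == "paper-like":
        return _paper_like_world(rng, rng_seed)
    raise ValueError(f"unknown profile {profile!r}")


def end_to_end_smoke(
    world: ToyWorld,
    budget: int,
    rng_seed: int = 0,
    n_trees: int = 200,
    acceptance_fraction: float = 0.1,
    n_ppc: int = 200,
    observed: GenotypeDataset | None = None,
    workers: int = 1,
) -> dict:
    """Run reference table -> ABC-RF -> estimation -> checking on a toy world.

    ``budget`` is the number of simulated rows per scenario (>= 500 for a
    meaningful vote). Returns a report with the vote outcome, posterior
    summaries for the admixture rate and bottleneck severities, and the
    posterior-predictive flags.
    """
    import warnings as _warnings

    from .abc_rf import rf_model_choice
    from .checking import posterior_predictive_check, test_statistic_complement
    from .estimation import classify_severity, local_linear_estimate, severity_posterior
    from .reftable import build_reference_table

    if budget < 500:
        raise ValueError("budget must be >= 500 rows per scenario")
    observed = observed if observed is not None else world.dataset
    report: dict = {"stage": "reftable"}
    table = build_reference_table(
        world.competing, world.prior, budget, world.sample_config,
        stat_set="full", rng_seed=rng_seed, n_loci=world.n_loci, workers=workers,
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        obs_stats = full_catalog(observed)

    report["stage"] = "model_choice"
    mc = rf_model_choice(table, obs_stats, n_trees=n_trees, rng_seed=rng_seed)
    report["votes"] = dict(zip(mc.scenario_names, mc.votes.tolist()))
    report["best_scenario"] = mc.best_scenario
    report["truth_won"] = mc.best_scenario == world.scenario.name
    report["posterior_probability"] = mc.posterior_probability
    report["prior_error_rate"] = mc.prior_error_rate

    report["stage"] = "estimation"
    pops = list(world.dataset.populations)
    est_names, _ = estimation_subset_names(pops, world.triplets)
    best_scenario = next(s for s in world.competing if s.name == mc.best_scenario)
    sub = table.restrict_to_scenario(mc.best_scenario).subset_stats(est_names)
    posterior = local_linear_estimate(
        sub, obs_stats.subset(est_names), world.prior,
        acceptance_fraction=acceptance_fraction,
    )
    report["posterior_summaries"] = posterior.summaries
    severities = {}
    for pop in world.severity_truth:
        db, nb = f"db_{pop}", f"Nb_{pop}"
        if db in posterior.draws.columns and nb in posterior.draws.columns:
            s = severity_posterior(posterior, db, nb)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                s["class"] = classify_severity(s["median"]).label
            severities[pop] = s
    report["severity"] = severities

    report["stage"] = "checking"
    test_names = test_statistic_complement(pops, est_names)
    ppc = posterior_predictive_check(
        best_scenario, posterior, observed, n_ppc, test_names, est_names,
        rng_seed=rng_seed, sample_config=world.sample_config,
    )
    report["ppc_n_below_005"] = ppc.n_below_005
    report["ppc_n_flagged_fdr"] = int(ppc.fdr_flags.sum())
    report["ppc_depth_rank"] = ppc.obs_depth_rank
    report["stage"] = "done"
    return report
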