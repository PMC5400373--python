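"""Sequential nested ABC analyses over a multi-site genotype dataset.

An analysis plan mirrors the step-by-step reconstruction of an invasion
history: each analysis names a target genetic group and its candidate
source groups, enumerates the competing single-source / pairwise-admixture
scenarios, runs model choice on every combination of representative sample
sites for the groups involved, and forwards its winner to later analyses
(referenced as ``winner:<analysis-name>``). The consensus winner across
site combinations is the modal winner; disagreements are listed verbatim,
never reconciled automatically.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abc_lda import lda_model_choice, prior_error_rate_lda
from .abc_rf import prior_error_rate_rf, rf_model_choice
from .demography import default_prior, Distribution, enumerate_target_scenarios
from .genotype_data import GenotypeDataset, subset_populations
from .reftable import build_reference_table
from .sumstats import full_catalog

logger = logging.getLogger(__name__)

WINNER_PREFIX = "winner:"


@dataclass
class AnalysisSpec:
    """One model-choice analysis in a nested plan."""

    name: str
    target_group: str
    source_groups: list[str]          # group names or "winner:<analysis>"
    engine: str = "rf"                # rf | lda | both
    n_per_scenario: int = 500
    n_replicates: int = 1
    n_trees: int = 200
    tolerance: float = 0.01
    t_intro: float | None = None      # generations; fixed by first record
    explicit_scenarios: list | None = None  # Scenario objects; bypasses
                                            # auto-enumeration when given


@dataclass
class AnalysisPlan:
    """Ordered analyses plus the group -> representative-sites mapping."""

    analyses: list[AnalysisSpec]
    groups: dict[str, list[str]]      # group -> alternate sample sites

    def site_to_group(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g, sites in self.groups.items():
            for s in sites:
                out[s] = g
        return out


@dataclass
class PipelineReport:
    rows: pd.DataFrame                # one row per analysis x combination
    consensus: dict[str, str]         # analysis -> canonical winner
    disagreements: dict[str, list[str]]
    root_seed: int
    config_digest: str


class PlanValidationError(ValueError):
    pass


def validate_plan(plan: AnalysisPlan, population_labels: list[str]) -> None:
    """Whole-plan validation before any simulation starts."""
    seen: list[str] = []
    names = [a.name for a in plan.analyses]
    if len(set(names)) != len(names):
        raise PlanValidationError("duplicate analysis names")
    for group, sites in plan.groups.items():
        if not sites:
            raise PlanValidationError(f"group {group!r} has no sample sites")
        for s in sites:
            if s not in population_labels:
                raise PlanValidationError(
                    f"group {group!r} references unknown sample site {s!r}"
                )
    for a in plan.analyses:
        if a.target_group not in plan.groups:
            raise PlanValidationError(
                f"analysis {a.name!r}: unknown target group {a.target_group!r}"
            )
        if not a.source_groups:
            raise PlanValidationError(f"analysis {a.name!r}: no source groups")
        for g in a.source_groups:
            if g.startswith(WINNER_PREFIX):
                ref = g[len(WINNER_PREFIX):]
                if ref not in seen:
                    raise PlanValidationError(
                        f"analysis {a.name!r} references {g!r} before it is resolved"
                    )
            elif g not in plan.groups:
                raise PlanValidationError(
                    f"analysis {a.name!r}: unknown source group {g!r}"
                )
        if a.engine not in ("rf", "lda", "both"):
            raise PlanValidationError(f"analysis {a.name!r}: bad engine {a.engine!r}")
        seen.append(a.name)


def _canonical_winner(
    winner_scenario: str, site_to_group: dict[str, str]
) -> tuple[str, tuple[str, ...]]:
    """Map a winner like ``siteT<-siteA+siteB`` to group space."""
    target, _, src = winner_scenario.partition("<-")
    groups = tuple(sorted(site_to_group.get(s, s) for s in src.split("+")))
    return site_to_group.get(target, target), groups


def _with_mutation_prior(prior):
    if "mu" not in prior.distributions:
        prior.distributions["mu"] = Distribution("loguniform", 1e-4, 1e-3)
    if "p_geom" not in prior.distributions:
        prior.distributions["p_geom"] = Distribution("uniform", 1e-6, 0.5)
    return prior


def run_plan(
    plan: AnalysisPlan,
    genotypes: GenotypeDataset,
    rng_seed: int = 0,
    workers: int = 1,
) -> PipelineReport:
    """Execute the analyses in order, forwarding winners.

    All randomness derives from ``rng_seed``; every table build and model
    choice is logged. The plan is validated whole before any simulation.
    """
    validate_plan(plan, genotypes.populations)
    site_to_group = plan.site_to_group()
    digest = hashlib.sha256(
        json.dumps(
            {
                "groups": plan.groups,
                "analyses": [a.__dict__ for a in plan.analyses],
            },
            sort_keys=True, default=str,
        ).encode()
    ).hexdigest()[:16]

    winners: dict[str, tuple[str, ...]] = {}  # analysis -> winner source groups
    rows: list[dict] = []
    consensus: dict[str, str] = {}
    disagreements: dict[str, list[str]] = {}

    for ai, a in enumerate(plan.analyses):
        source_groups: list[str] = []
        for g in a.source_groups:
            if g.startswith(WINNER_PREFIX):
                for gg in winners[g[len(WINNER_PREFIX):]]:
                    if gg not in source_groups:
                        source_groups.append(gg)
            elif g not in source_groups:
                source_groups.append(g)
        combos = list(
            itertools.product(
                *[plan.groups[g] for g in source_groups], plan.groups[a.target_group]
            )
        )
        logger.info(
            "analysis %s: %d source groups, %d site combinations",
            a.name, len(source_groups), len(combos),
        )
        combo_winners: list[tuple[str, tuple[str, ...]]] = []
        for ci, combo in enumerate(combos):
            *source_sites, target_site = combo
            if target_site in source_sites:
                continue
            sub = subset_populations(genotypes, list(source_sites) + [target_site])
            if a.explicit_scenarios is not None:
                scenarios = list(a.explicit_scenarios)
            else:
                scenarios = enumerate_target_scenarios(
                    list(source_sites), target_site, t_intro=a.t_intro
                )
            prior = _with_mutation_prior(default_prior(scenarios))
            seed = int(
                np.random.SeedSequence([rng_seed, ai, ci]).generate_state(1)[0]
            ) & 0x7FFFFFFF
            table = build_reference_table(
                scenarios, prior, a.n_per_scenario, sub.sample_sizes(),
                stat_set="full", rng_seed=seed, n_loci=sub.n_loci, workers=workers,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                observed = full_catalog(sub)
            row = {
                "analysis": a.name, "combination": "+".join(combo),
                "target_site": target_site, "n_scenarios": len(scenarios),
            }
            if a.engine in ("rf", "both"):
                mc = rf_model_choice(
                    table, observed, n_trees=a.n_trees,
                    rng_seed=seed, n_replicates=a.n_replicates,
                )
                row.update(
                    winner=mc.best_scenario,
                    votes=int(mc.votes.max()),
                    posterior_probability=mc.posterior_probability,
                    prior_error_rate=mc.prior_error_rate,
                )
            if a.engine in ("lda", "both"):
                lr = lda_model_choice(table, observed, tolerance=a.tolerance,
                                      rng_seed=seed, with_ci=False)
                row["lda_winner"] = lr.best_scenario
                row["lda_probability"] = float(lr.probabilities.max())
                if a.engine == "lda":
                    row["winner"] = lr.best_scenario
            rows.append(row)
            combo_winners.append(_canonical_winner(row["winner"], site_to_group))
        tallied = Counter(w for _, w in combo_winners)
        best_groups, _ = tallied.most_common(1)[0]
        winners[a.name] = best_groups
        consensus[a.name] = f"{a.target_group}<-{'+'.join(best_groups)}"
        other = [
            f"{t}<-{'+'.join(w)}" for t, w in combo_winners if w != best_groups
        ]
        if other:
            disagreements[a.name] = other
        logger.info("analysis %s consensus: %s", a.name, consensus[a.name])

    return PipelineReport(
        rows=pd.DataFrame(rows),
        consensus=consensus,
        disagreements=disagreements,
        root_seed=rng_seed,
        config_digest=digest,
    )


def plan_from_dict(d: dict) -> AnalysisPlan:
    """Build a plan from a YAML/JSON-friendly dict (see the CLI `run`)."""
    from .demography import scenario_from_dict

    analyses = []
    for ad in d["analyses"]:
        ad = dict(ad)
        if ad.get("explicit_scenarios"):
            ad["explicit_scenarios"] = [
                scenario_from_dict(s) for s in ad["explicit_scenarios"]
            ]
        analyses.append(AnalysisSpec(**ad))
    return AnalysisPlan(
        analyses=analyses,
        groups={g: list(v) for g, v in d["groups"].items()},
    )


def compare_engines(
    plan: AnalysisPlan,
    genotypes: GenotypeDataset,
    small_n: int,
    large_n: int,
    seeds: list[int],
    n_trees: int = 200,
    tolerance: float = 0.05,
    n_pseudo: int = 100,
) -> pd.DataFrame:
    """Prior-error comparison of ABC-RF vs ABC-LDA at two table sizes.

    For each analysis (literal source groups only; first site combination),
    and for every seed: the RF out-of-bag prior error on the small table,
    the LDA pseudo-observed prior error on the small and the large table,
    and the chosen scenario, to measure choice stability across seeds.
    """
    if small_n >= large_n:
        raise ValueError("small_n must be < large_n")
    validate_plan(plan, genotypes.populations)
    records: list[dict] = []
    for ai, a in enumerate(plan.analyses):
        if any(g.startswith(WINNER_PREFIX) for g in a.source_groups):
            raise PlanValidationError(
                f"analysis {a.name!r}: compare_engines needs literal source groups"
            )
        source_sites = [plan.groups[g][0] for g in a.source_groups]
        target_site = plan.groups[a.target_group][0]
        sub = subset_populations(genotypes, source_sites + [target_site])
        scenarios = enumerate_target_scenarios(source_sites, target_site, t_intro=a.t_intro)
        prior = _with_mutation_prior(default_prior(scenarios))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            observed = full_catalog(sub)
        for seed in seeds:
            tables = {
                n: build_reference_table(
                    scenarios, prior, n, sub.sample_sizes(),
                    stat_set="full", rng_seed=seed, n_loci=sub.n_loci,
                )
                for n in (small_n, large_n)
            }
            rf_err = prior_error_rate_rf(tables[small_n], n_trees=n_trees, rng_seed=seed)
            lda_err_small = prior_error_rate_lda(
                tables[small_n], tolerance=tolerance, n_pseudo=n_pseudo, rng_seed=seed
            )
            lda_err_large = prior_error_rate_lda(
                tables[large_n], tolerance=tolerance, n_pseudo=n_pseudo, rng_seed=seed
            )
            mc = rf_model_choice(tables[small_n], observed, n_trees=n_trees, rng_seed=seed)
            lr = lda_model_choice(
                tables[small_n], observed, tolerance=tolerance,
                rng_seed=seed, with_ci=False,
            )
            records.append(
                {
                    "analysis": a.name,
                    "seed": seed,
                    "rf_error_small": rf_err,
                    "lda_error_small": lda_err_small,
                    "lda_error_large": lda_err_large,
                    "rf_winner_small": mc.best_scenario,
                    "lda_winner_small": lr.best_scenario,
                }
            )
    return pd.DataFrame(records)
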