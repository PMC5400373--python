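"""Reference tables: scenario index + parameter draws + summary statistics.

The training object for ABC. Rows are simulated independently with per-row
seeds derived from a root seed, the scenario index, the row index and a
retry counter, so tables are reproducible and independent of the worker
count. Rows whose dataset yields non-finite statistics (e.g., zero
polymorphism making FST undefined) are resimulated with the next derived
seed and the event is logged.

Storage is a columnar parquet file plus a JSON metadata sidecar (statistic
names, prior-set label, seed ledger); CSV export is offered for
interoperability.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import ParameterVector, PriorSpec, Scenario, draw_parameters
from .simulator import GSMModel, drop_mutations, simulate_genealogies
from .sumstats import StatVector, estimation_subset, full_catalog

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


class TableFormatError(RuntimeError):
    """Stored table is missing, truncated, or of an incompatible version."""


@dataclass
class ReferenceTable:
    """Simulated training table for ABC model choice and estimation."""

    scenario_names: list[str]
    scenario_idx: np.ndarray          # (n,) int
    params: pd.DataFrame              # (n, P) float, NaN where not applicable
    stats: pd.DataFrame               # (n, S) float
    prior_set: str = "set1"
    root_seed: int | None = None
    seed_ledger: np.ndarray | None = None  # (n,) retry counter per row
    stat_arity: list[int] = field(default_factory=list)
    lda: object | None = None         # in-memory discriminant projector

    def __post_init__(self) -> None:
        self.scenario_idx = np.asarray(self.scenario_idx, dtype=np.int64)
        n = len(self.scenario_idx)
        if len(self.params) != n or len(self.stats) != n:
            raise ValueError("params/stats row counts must match scenario_idx")
        if not np.all(np.isfinite(self.stats.to_numpy())):
            raise ValueError("reference table contains non-finite statistics")

    @property
    def n_rows(self) -> int:
        return len(self.scenario_idx)

    @property
    def stat_names(self) -> list[str]:
        return list(self.stats.columns)

    def rows_per_scenario(self) -> dict[str, int]:
        counts = np.bincount(self.scenario_idx, minlength=len(self.scenario_names))
        return dict(zip(self.scenario_names, counts.tolist()))

    def restrict_to_scenario(self, name: str) -> "ReferenceTable":
        """Rows of one scenario only (statistics and parameters kept)."""
        if name not in self.scenario_names:
            raise KeyError(name)
        k = self.scenario_names.index(name)
        mask = self.scenario_idx == k
        return ReferenceTable(
            scenario_names=[name],
            scenario_idx=np.zeros(int(mask.sum()), dtype=np.int64),
            params=self.params.loc[mask].reset_index(drop=True),
            stats=self.stats.loc[mask].reset_index(drop=True),
            prior_set=self.prior_set,
            root_seed=self.root_seed,
            seed_ledger=self.seed_ledger[mask] if self.seed_ledger is not None else None,
            stat_arity=list(self.stat_arity),
        )

    def subset_stats(self, names: Sequence[str]) -> "ReferenceTable":
        missing = [n for n in names if n not in self.stats.columns]
        if missing:
            raise KeyError(f"unknown statistics: {missing}")
        return ReferenceTable(
            scenario_names=list(self.scenario_names),
            scenario_idx=self.scenario_idx.copy(),
            params=self.params.copy(),
            stats=self.stats.loc[:, list(names)].copy(),
            prior_set=self.prior_set,
            root_seed=self.root_seed,
            seed_ledger=self.seed_ledger,
            stat_arity=[],
        )


def _simulate_row(
    scenario: Scenario,
    prior: PriorSpec,
    sample_config: Mapping[str, int] | None,
    stat_fn: Callable,
    n_loci: int,
    model: GSMModel | None,
    fixed_params: Mapping[str, float],
    root_seed: int,
    scenario_index: int,
    row_index: int,
    max_retries: int,
) -> tuple[dict[str, float], np.ndarray, int]:
    for attempt in range(max_retries):
        ss = np.random.SeedSequence([root_seed, scenario_index, row_index, attempt])
        s_prior, s_trees, s_muts = ss.spawn(3)
        pv = draw_parameters(prior, np.random.default_rng(s_prior))
        merged = dict(fixed_params)
        merged.update(pv.values)
        gen = simulate_genealogies(
            scenario, merged, np.random.default_rng(s_trees),
            sample_config=sample_config, n_loci=n_loci,
        )
        row_model = model
        if row_model is None:
            kwargs = {}
            if "mu" in merged:
                kwargs["mu"] = merged["mu"]
            if "p_geom" in merged:
                kwargs["p_geom"] = merged["p_geom"]
            row_model = GSMModel(**kwargs)
        ds = drop_mutations(gen, row_model, np.random.default_rng(s_muts))
        sv: StatVector = stat_fn(ds)
        if np.all(np.isfinite(sv.values)):
            return pv.values, sv.values, attempt
        logger.info(
            "scenario %s row %d attempt %d: non-finite statistics, resimulating",
            scenario.name, row_index, attempt,
        )
    raise RuntimeError(
        f"scenario {scenario.name!r}: simulation kept producing non-finite "
        f"statistics after {max_retries} retries (row {row_index})"
    )


def default_table_rows(
    n_scenarios: int,
    per_scenario: int = 10_000,
    total_when_many: int = 100_000,
) -> int:
    """Default rows per scenario: a fixed per-scenario budget up to ten
    scenarios, a fixed total split across scenarios beyond that (large
    multi-scenario tables are capped to keep the forest's bootstrap
    machinery in memory)."""
    if n_scenarios <= 10:
        return per_scenario
    return max(1, total_when_many // n_scenarios)


def build_reference_table(
    scenarios: Sequence[Scenario],
    prior: PriorSpec,
    n_per_scenario: int,
    sample_config: Mapping[str, int] | None,
    stat_set: str | tuple = "full",
    rng_seed: int = 0,
    workers: int = 1,
    n_loci: int = 25,
    model: GSMModel | None = None,
    fixed_params: Mapping[str, float] | None = None,
    max_retries: int = 20,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` accepted rows for every scenario.

    ``stat_set`` is ``"full"`` (whole catalog), ``("estimation", triplets)``
    (reduced subset), or a callable ``dataset -> StatVector``. The result is
    deterministic given ``rng_seed`` and identical for any worker count.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    fixed_params = dict(fixed_params or {})
    if stat_set == "full":
        stat_fn = full_catalog
    elif isinstance(stat_set, tuple) and stat_set[0] == "estimation":
        triplets = stat_set[1]
        stat_fn = lambda ds: estimation_subset(ds, triplets)  # noqa: E731
    elif callable(stat_set):
        stat_fn = stat_set
    else:
        raise ValueError(f"unknown stat_set {stat_set!r}")

    import warnings as _warnings

    jobs = [
        (si, ri)
        for si in range(len(scenarios))
        for ri in range(n_per_scenario)
    ]

    def run_job(si: int, ri: int):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # degenerate-AML warnings in bulk
            return _simulate_row(
                scenarios[si], prior, sample_config, stat_fn, n_loci, model,
                fixed_params, rng_seed, si, ri, max_retries,
            )

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(run_job)(si, ri) for si, ri in jobs
        )
    else:
        results = [run_job(si, ri) for si, ri in jobs]

    # a probe dataset fixes the statistic name order
    probe_names, probe_arity = _stat_names_for(scenarios[0], sample_config, stat_set)
    param_names: list[str] = []
    for pvals, _, _ in results:
        for k in pvals:
            if k not in param_names:
                param_names.append(k)

    n = len(jobs)
    scenario_idx = np.array([si for si, _ in jobs], dtype=np.int64)
    stats = np.vstack([sv for _, sv, _ in results])
    if stats.shape[1] != len(probe_names):
        raise RuntimeError("statistic vector length mismatch across scenarios")
    params = pd.DataFrame(np.nan, index=range(n), columns=param_names)
    for i, (pvals, _, _) in enumerate(results):
        for k, v in pvals.items():
            params.iloc[i, param_names.index(k)] = v
    ledger = np.array([att for _, _, att in results], dtype=np.int64)
    return ReferenceTable(
        scenario_names=[sc.name for sc in scenarios],
        scenario_idx=scenario_idx,
        params=params,
        stats=pd.DataFrame(stats, columns=probe_names),
        prior_set=prior.name,
        root_seed=rng_seed,
        seed_ledger=ledger,
        stat_arity=probe_arity,
    )


def _stat_names_for(scenario: Scenario, sample_config, stat_set) -> tuple[list[str], list[int]]:
    from .sumstats import catalog_names, estimation_subset_names

    pops = scenario.sampled_populations()
    if stat_set == "full":
        return catalog_names(pops)
    if isinstance(stat_set, tuple) and stat_set[0] == "estimation":
        return estimation_subset_names(pops, stat_set[1])
    # callable: probe with a tiny simulation is avoidable — require names later
    return [], []


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_table(table: ReferenceTable, path: str) -> None:
    """Write the table as ``<path>/table.parquet`` + ``<path>/meta.json``."""
    os.makedirs(path, exist_ok=True)
    df = pd.concat(
        [
            pd.DataFrame({"scenario_idx": table.scenario_idx}),
            table.params.add_prefix("param:"),
            table.stats.add_prefix("stat:"),
        ],
        axis=1,
    )
    if table.seed_ledger is not None:
        df["retry"] = table.seed_ledger
    df.to_parquet(os.path.join(path, "table.parquet"))
    meta = {
        "format_version": FORMAT_VERSION,
        "scenario_names": table.scenario_names,
        "param_names": list(table.params.columns),
        "stat_names": table.stat_names,
        "stat_arity": list(table.stat_arity),
        "prior_set": table.prior_set,
        "root_seed": table.root_seed,
        "n_rows": table.n_rows,
    }
    with open(os.path.join(path, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def load_table(path: str) -> ReferenceTable:
    meta_path = os.path.join(path, "meta.json")
    data_path = os.path.join(path, "table.parquet")
    if not (os.path.exists(meta_path) and os.path.exists(data_path)):
        raise TableFormatError(f"{path!r} does not contain a saved reference table")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise TableFormatError(
            f"table format version {meta.get('format_version')} "
            f"!= supported {FORMAT_VERSION}"
        )
    try:
        df = pd.read_parquet(data_path)
    except Exception as exc:
        raise TableFormatError(f"cannot read {data_path!r}: {exc}") from exc
    if len(df) != meta["n_rows"]:
        raise TableFormatError(
            f"row count {len(df)} != recorded {meta['n_rows']} (truncated file?)"
        )
    params = df[[f"param:{p}" for p in meta["param_names"]]].copy()
    params.columns = meta["param_names"]
    stats = df[[f"stat:{s}" for s in meta["stat_names"]]].copy()
    stats.columns = meta["stat_names"]
    return ReferenceTable(
        scenario_names=meta["scenario_names"],
        scenario_idx=df["scenario_idx"].to_numpy(),
        params=params,
        stats=stats,
        prior_set=meta["prior_set"],
        root_seed=meta["root_seed"],
        seed_ledger=df["retry"].to_numpy() if "retry" in df else None,
        stat_arity=meta.get("stat_arity", []),
    )


def export_csv(table: ReferenceTable, path: str) -> None:
    """Flat CSV export (scenario name, parameters, statistics)."""
    df = pd.concat(
        [
            pd.DataFrame(
                {"scenario": [table.scenario_names[i] for i in table.scenario_idx]}
            ),
            table.params,
            table.stats,
        ],
        axis=1,
    )
    df.to_csv(path, index=False)


def checksum(table: ReferenceTable) -> str:
    """Stable content hash of scenario index, parameters and statistics."""
    import hashlib

    h = hashlib.sha256()
    h.update(table.scenario_idx.tobytes())
    h.update(np.ascontiguousarray(table.params.to_numpy()).tobytes())
    h.update(np.ascontiguousarray(table.stats.to_numpy()).tobytes())
    return h.hexdigest()
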