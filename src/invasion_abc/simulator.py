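"""Backward-in-time structured coalescent for unlinked microsatellite loci.

Within each population, pairs of lineages coalesce at rate 1/(2Ne) per pair
per generation (continuous-time approximation, appropriate for the large
effective sizes considered here). Demographic events are applied at their
scheduled backward times: a divergence moves all lineages of the derived
population into its source, an admixture sends each lineage to one of two
sources with probability r / 1-r, and a size change switches the active Ne.
Mutations are then dropped on the genealogies under a generalized stepwise
model (GSM): Poisson counts per branch, geometric step lengths, equal-sign
probability, and a contiguous window of allowed repeat counts with
reflecting boundaries. All loci are independent given the demography, and
every stage is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .demography import Admix, Diverge, Sample, Scenario, SizeChange, resolve
from .genotype_data import GenotypeDataset


class ScenarioSimulationError(RuntimeError):
    """Lineages could not find a common ancestor under the event schedule."""


@dataclass
class GSMModel:
    """Generalized stepwise mutation model for microsatellites.

    Parameters
    ----------
    mu
        Mean per-locus mutation rate (mutations / locus / generation).
    p_geom
        Geometric parameter for step length: a mutation moves the repeat
        count by ±k with P(k) = (1 - p_geom) * p_geom**(k-1); p_geom = 0 is
        the strict stepwise model.
    window_lo, window_hi
        Contiguous window of allowed repeat counts (reflecting boundaries);
        the default 40-state window [10, 49] follows common practice for
        microsatellite simulation.
    rate_shape
        Shape of the Gamma distribution from which per-locus rate
        multipliers are drawn (mean 1); heterogeneity across loci.
    locus_rates
        Optional explicit per-locus rates (overrides the Gamma draw).
    """

    mu: float = 5e-4
    p_geom: float = 0.22
    window_lo: int = 10
    window_hi: int = 49
    rate_shape: float = 2.0
    locus_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")
        if not 0.0 <= self.p_geom < 1.0:
            raise ValueError("p_geom must lie in [0, 1)")
        if self.window_hi - self.window_lo + 1 < 2:
            raise ValueError("allele window must span at least 2 states")

    @property
    def root_allele(self) -> int:
        return (self.window_lo + self.window_hi) // 2

    def draw_locus_rates(self, n_loci: int, rng: np.random.Generator) -> np.ndarray:
        if self.locus_rates is not None:
            rates = np.asarray(self.locus_rates, dtype=float)
            if len(rates) != n_loci:
                raise ValueError("locus_rates length must equal n_loci")
            return rates
        if self.mu == 0:
            return np.zeros(n_loci)
        mult = rng.gamma(self.rate_shape, 1.0 / self.rate_shape, size=n_loci)
        return self.mu * mult


@dataclass
class LocusTree:
    """One coalescent tree: leaves 0..n_leaves-1, internal nodes appended.

    ``parent[i]`` is -1 for the root; ``time`` is in generations backward
    from sampling; ``leaf_pop[i]`` indexes the sampled population of leaf i.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_pop: np.ndarray

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        lens = np.zeros(len(self.parent))
        nonroot = self.parent >= 0
        lens[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return lens


@dataclass
class GenealogySet:
    """Per-locus trees plus the sampling layout they share."""

    trees: list[LocusTree]
    populations: list[str]
    sample_sizes: list[int]  # diploids per population, same order
    params: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.trees)


def _resolve_samples(
    scenario: Scenario,
    params: Mapping[str, float],
    sample_config: Mapping[str, int] | None,
) -> tuple[list[str], list[int]]:
    pops: list[str] = []
    sizes: list[int] = []
    for ev in scenario.events:
        if not isinstance(ev, Sample):
            continue
        if resolve(ev.time, params) != 0.0:
            raise NotImplementedError("only present-day (time 0) sampling is supported")
        n = None
        if sample_config and ev.pop in sample_config:
            n = int(sample_config[ev.pop])
        elif ev.n is not None:
            n = int(resolve(ev.n, params))
        if n is None:
            raise ValueError(f"no sample size for population {ev.pop!r}")
        if n < 1:
            raise ValueError(f"sample size for {ev.pop!r} must be >= 1")
        pops.append(ev.pop)
        sizes.append(n)
    if not pops:
        raise ValueError("scenario has no sample events")
    return pops, sizes


def simulate_genealogies(
    scenario: Scenario,
    params: Mapping[str, float],
    rng_seed: int | np.random.Generator,
    sample_config: Mapping[str, int] | None = None,
    n_loci: int = 25,
) -> GenealogySet:
    """Simulate independent coalescent trees for ``n_loci`` unlinked loci."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pops, sizes = _resolve_samples(scenario, params, sample_config)

    ne0 = {p: resolve(scenario.ne[p], params) for p in scenario.populations}
    for p, v in ne0.items():
        if v <= 0:
            raise ValueError(f"effective size of {p!r} must be positive")
    schedule = []
    for ev in scenario.events:
        if isinstance(ev, Sample):
            continue
        t_ev = resolve(ev.time, params)
        if t_ev < 0:
            if isinstance(ev, SizeChange):
                # a bottleneck lasting longer than the time since founding:
                # the population is still at the reduced size when sampled
                t_ev = 0.0
            else:
                raise ValueError(f"event {ev} resolves to a negative time")
        schedule.append((t_ev, ev))
    schedule.sort(key=lambda pair: pair[0])

    n_leaves = 2 * sum(sizes)
    leaf_pop = np.repeat(np.arange(len(pops)), [2 * n for n in sizes])

    trees = [
        _simulate_one_tree(scenario, pops, sizes, ne0, schedule, params, rng, n_leaves, leaf_pop)
        for _ in range(n_loci)
    ]
    return GenealogySet(trees, pops, sizes, dict(params))


def _simulate_one_tree(
    scenario: Scenario,
    pops: list[str],
    sizes: list[int],
    ne0: dict[str, float],
    schedule: list,
    params: Mapping[str, float],
    rng: np.random.Generator,
    n_leaves: int,
    leaf_pop: np.ndarray,
) -> LocusTree:
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    next_node = n_leaves

    lineages: dict[str, list[int]] = {p: [] for p in scenario.populations}
    k = 0
    for p, n in zip(pops, sizes):
        lineages[p] = list(range(k, k + 2 * n))
        k += 2 * n
    ne = dict(ne0)

    t = 0.0
    ev_idx = 0
    while True:
        t_next = schedule[ev_idx][0] if ev_idx < len(schedule) else np.inf
        # populations are independent between events: batch-draw each
        # population's embedded coalescence chain up to the epoch end
        for p, pool in lineages.items():
            k = len(pool)
            if k < 2:
                continue
            js = np.arange(k, 1, -1, dtype=float)
            waits = rng.exponential(2.0 * ne[p] / (js * (js - 1) / 2.0))
            times = t + np.cumsum(waits)
            n_coal = int(np.searchsorted(times, t_next))
            for m in range(n_coal):
                i = int(rng.integers(len(pool)))
                a = pool[i]
                pool[i] = pool[-1]
                pool.pop()
                j = int(rng.integers(len(pool)))
                b = pool[j]
                parent[a] = parent[b] = next_node
                time[next_node] = times[m]
                pool[j] = next_node
                next_node += 1
                if next_node == n_nodes:
                    return LocusTree(parent, time, n_leaves, leaf_pop)
        t = t_next

        if ev_idx >= len(schedule):
            remaining = {p: len(l) for p, l in lineages.items() if l}
            raise ScenarioSimulationError(
                f"no common ancestral population reachable; lineages left in {remaining}"
            )
        _, ev = schedule[ev_idx]
        ev_idx += 1
        if isinstance(ev, Diverge):
            lineages[ev.source].extend(lineages[ev.derived])
            lineages[ev.derived] = []
        elif isinstance(ev, Admix):
            r = resolve(ev.rate, params)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"admixture rate resolves to {r}, outside [0, 1]")
            moved = lineages[ev.derived]
            go1 = rng.random(len(moved)) < r
            lineages[ev.source1].extend(x for x, g in zip(moved, go1) if g)
            lineages[ev.source2].extend(x for x, g in zip(moved, go1) if not g)
            lineages[ev.derived] = []
        elif isinstance(ev, SizeChange):
            v = resolve(ev.ne, params)
            if v <= 0:
                raise ValueError("size change to non-positive Ne")
            ne[ev.pop] = v


def _mutate_allele(
    allele: int,
    n_mut: int,
    p_geom: float,
    lo: int,
    hi: int,
    rng: np.random.Generator,
) -> int:
    for _ in range(n_mut):
        k = int(rng.geometric(1.0 - p_geom)) if p_geom > 0 else 1
        step = k if rng.random() < 0.5 else -k
        allele += step
        while allele < lo or allele > hi:  # reflecting boundaries
            if allele < lo:
                allele = 2 * lo - allele
            else:
                allele = 2 * hi - allele
    return allele


def drop_mutations(
    genealogies: GenealogySet,
    model: GSMModel,
    rng_seed: int | np.random.Generator,
) -> GenotypeDataset:
    """Place GSM mutations on the genealogies and emit diploid genotypes.

    Mutation counts per branch are Poisson(locus_rate × branch length); the
    root allele is the window midpoint; lineage pairs are grouped into
    diploid individuals in sampling order.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_loci = genealogies.n_loci
    rates = model.draw_locus_rates(n_loci, rng)

    leaf_alleles = np.empty((n_loci, genealogies.trees[0].n_leaves), dtype=np.int64)
    for li, tree in enumerate(genealogies.trees):
        lens = tree.branch_lengths()
        n_mut = rng.poisson(rates[li] * lens)
        children: list[list[int]] = [[] for _ in range(len(tree.parent))]
        for node, par in enumerate(tree.parent):
            if par >= 0:
                children[par].append(node)
        alleles = np.empty(len(tree.parent), dtype=np.int64)
        root = tree.root
        alleles[root] = model.root_allele
        stack = [root]
        while stack:
            node = stack.pop()
            for ch in children[node]:
                alleles[ch] = _mutate_allele(
                    int(alleles[node]),
                    int(n_mut[ch]),
                    model.p_geom,
                    model.window_lo,
                    model.window_hi,
                    rng,
                )
                stack.append(ch)
        leaf_alleles[li] = alleles[: tree.n_leaves]

    loci = [f"L{j + 1}" for j in range(n_loci)]
    genotypes: dict[str, np.ndarray] = {}
    offset = 0
    for pop, n in zip(genealogies.populations, genealogies.sample_sizes):
        block = leaf_alleles[:, offset : offset + 2 * n]  # (loci, 2n)
        genotypes[pop] = block.T.reshape(n, 2, n_loci).transpose(0, 2, 1).copy()
        offset += 2 * n
    return GenotypeDataset(
        populations=list(genealogies.populations),
        loci=loci,
        genotypes=genotypes,
    )


def simulate_dataset(
    scenario: Scenario,
    params: Mapping[str, float],
    sample_config: Mapping[str, int] | None,
    rng_seed: int,
    n_loci: int = 25,
    model: GSMModel | None = None,
) -> GenotypeDataset:
    """Simulate genealogies and drop mutations in one seeded call.

    If ``model`` is omitted, a GSM is assembled from the parameter vector
    when it carries ``mu`` / ``p_geom`` entries, else from the defaults.
    """
    ss = np.random.SeedSequence(rng_seed)
    rng_trees, rng_muts = (np.random.default_rng(s) for s in ss.spawn(2))
    gen = simulate_genealogies(
        scenario, params, rng_trees, sample_config=sample_config, n_loci=n_loci
    )
    if model is None:
        kwargs = {}
        if "mu" in params:
            kwargs["mu"] = float(params["mu"])
        if "p_geom" in params:
            kwargs["p_geom"] = float(params["p_geom"])
        model = GSMModel(**kwargs)
    return drop_mutations(gen, model, rng_muts)
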