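"""Invasion scenarios as backward-time demographic event lists, plus priors.

A :class:`Scenario` describes one competing invasion model: population labels
with stable effective sizes, and a list of events read backward from the
sampling date (time 0, in generations). An introduction is modeled as a
divergence without subsequent gene flow, immediately preceded (in backward
time) by a bottleneck interval of ``db`` generations at size ``Nb``; the
introduction time is fixed by the date of first record converted at a given
number of generations per year (default 12). Unsampled "ghost" populations
can be flagged to absorb source uncertainty within a structured native range.

Numeric slots (times, sizes, admixture rates) may be literal numbers, prior
parameter names, or small arithmetic expressions over parameter names such
as ``"t_inv - db_inv"``; they are resolved against a :class:`ParameterVector`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np

Value = Union[int, float, str]


def resolve(value: Value, params: Mapping[str, float] | None = None) -> float:
    """Resolve a numeric slot against a parameter mapping.

    Numbers pass through; strings are parameter names or arithmetic
    expressions (``+ - * /`` and parentheses) over parameter names.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot resolve value of type {type(value).__name__}")
    params = params or {}
    if value in params:
        return float(params[value])
    try:
        return float(eval(value, {"__builtins__": {}}, dict(params)))  # noqa: S307
    except Exception as exc:  # pragma: no cover - message path
        raise KeyError(f"cannot resolve {value!r} against parameters") from exc


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """Sampling of ``n`` diploids from ``pop`` at backward time ``time``."""

    pop: str
    n: Value | None = None  # None: taken from the sample configuration
    time: Value = 0.0


@dataclass(frozen=True)
class Diverge:
    """All lineages of ``derived`` merge into ``source`` at ``time``."""

    derived: str
    source: str
    time: Value


@dataclass(frozen=True)
class Admix:
    """Backward merge of ``derived``: each lineage goes to ``source1`` with
    probability ``rate`` and to ``source2`` otherwise, at ``time``."""

    derived: str
    source1: str
    source2: str
    rate: Value
    time: Value


@dataclass(frozen=True)
class SizeChange:
    """``pop`` has effective size ``ne`` from ``time`` backward (until the
    next older size change or merge)."""

    pop: str
    ne: Value
    time: Value


Event = Union[Sample, Diverge, Admix, SizeChange]


@dataclass
class Scenario:
    """One competing invasion model.

    ``ne`` maps each population to its stable diploid effective size (value
    or parameter name); ``events`` is ordered by backward time.
    """

    name: str
    populations: list[str]
    ne: dict[str, Value]
    events: list[Event]
    ghosts: set[str] = field(default_factory=set)

    def sampled_populations(self) -> list[str]:
        return [e.pop for e in self.events if isinstance(e, Sample)]

    def parameter_names(self) -> list[str]:
        """All parameter names referenced by the scenario, in first-use order."""
        import re

        names: list[str] = []

        def scan(v: Value | None) -> None:
            if isinstance(v, str):
                for tok in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", v):
                    if tok not in names:
                        names.append(tok)

        for v in self.ne.values():
            scan(v)
        for e in self.events:
            for f in ("n", "time", "ne", "rate"):
                if hasattr(e, f):
                    scan(getattr(e, f))
        return names


@dataclass(frozen=True)
class BottleneckSpec:
    """Founding bottleneck: ``db`` generations at diploid size ``Nb``.

    Severity is the ratio db/Nb — the quantity classified downstream as
    weak/moderate/strong.
    """

    population: str
    db: int
    nb: int

    def __post_init__(self) -> None:
        if self.db < 1:
            raise ValueError("bottleneck duration must be >= 1 generation")
        if self.nb < 2:
            raise ValueError("bottleneck size must be >= 2 diploids")

    @property
    def severity(self) -> float:
        return self.db / self.nb


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Distribution:
    """A bounded one-dimensional prior: uniform, log-uniform, or truncated
    normal (``args = (mean, sd)`` with bounds)."""

    kind: str  # "uniform" | "loguniform" | "truncnorm"
    lo: float
    hi: float
    args: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("prior bounds must be finite")
        if not self.lo < self.hi:
            raise ValueError("prior bounds must satisfy lo < hi")
        if self.kind not in ("uniform", "loguniform", "truncnorm"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "loguniform" and self.lo <= 0:
            raise ValueError("log-uniform needs a positive lower bound")
        if self.kind == "truncnorm" and len(self.args) != 2:
            raise ValueError("truncnorm needs args=(mean, sd)")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size)
        if self.kind == "loguniform":
            return np.exp(rng.uniform(np.log(self.lo), np.log(self.hi), size))
        mean, sd = self.args
        # truncated normal by rejection against the bounds
        n = 1 if size is None else int(size)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mean, sd, size=2 * (n - filled))
            ok = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out[0] if size is None else out


@dataclass
class PriorSpec:
    """Named parameter priors plus pairwise ordering constraints.

    ``constraints`` holds ``(a, b)`` pairs meaning "parameter a > parameter
    b"; draws violating any constraint are rejected and redrawn. ``name``
    labels the prior set ("set1" rectangular, "set2" peaked).
    """

    distributions: dict[str, Distribution]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    name: str = "set1"

    def __post_init__(self) -> None:
        for a, b in self.constraints:
            for p in (a, b):
                if p not in self.distributions:
                    raise KeyError(f"constraint references unknown parameter {p!r}")
        # constraint graph must be acyclic (a > b edges)
        graph = {p: set() for p in self.distributions}
        for a, b in self.constraints:
            graph[a].add(b)
        seen: dict[str, int] = {}

        def dfs(u: str) -> None:
            seen[u] = 1
            for v in graph[u]:
                if seen.get(v) == 1:
                    raise ValueError("ordering constraints form a cycle")
                if v not in seen:
                    dfs(v)
            seen[u] = 2

        for p in graph:
            if p not in seen:
                dfs(p)

    def bounds(self, name: str) -> tuple[float, float]:
        d = self.distributions[name]
        return (d.lo, d.hi)


@dataclass
class ParameterVector(Mapping[str, float]):
    """One realized parameter draw with provenance."""

    values: dict[str, float]
    prior_set: str = "set1"
    seed: int | None = None

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def draw_parameters(
    prior: PriorSpec,
    rng_seed: int | np.random.Generator,
    max_tries: int = 10_000,
) -> ParameterVector:
    """Draw one parameter vector satisfying all ordering constraints.

    Rejection resampling of the whole vector; identical seeds give identical
    vectors. Raises ``RuntimeError`` if the constraints cannot be satisfied
    within ``max_tries`` draws.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seed = rng_seed if isinstance(rng_seed, int) else None
    for _ in range(max_tries):
        vals = {name: float(d.sample(rng)) for name, d in prior.distributions.items()}
        if all(vals[a] > vals[b] for a, b in prior.constraints):
            return ParameterVector(vals, prior_set=prior.name, seed=seed)
    raise RuntimeError(
        f"could not satisfy prior constraints after {max_tries} draws"
    )


# ---------------------------------------------------------------------------
# Calendar conversion and scenario enumeration
# ---------------------------------------------------------------------------

def first_record_to_generations(
    first_record_year: int,
    sampling_year: int,
    generations_per_year: int = 12,
) -> int:
    """Convert a first-record date to backward generations at sampling."""
    if generations_per_year < 1:
        raise ValueError("generations_per_year must be >= 1")
    if sampling_year < first_record_year:
        raise ValueError("sampling year precedes the first record")
    return (sampling_year - first_record_year) * generations_per_year


def _intro_events(target: str, t_intro: Value) -> list[Event]:
    """Bottleneck motif: size Nb from (t_intro - db) back to the divergence."""
    return [SizeChange(target, f"Nb_{target}", f"{t_intro} - db_{target}")]


def enumerate_target_scenarios(
    sources: list[str],
    target: str,
    t_intro: Value | None = None,
    t_ancestral: Value | None = None,
) -> list[Scenario]:
    """Enumerate the competing models for one focal (target) population.

    With k candidate sources this yields k single-source scenarios plus
    C(k, 2) pairwise-admixture scenarios — k + k(k-1)/2 in total — each with
    a founding bottleneck on the target. Singles come first in source order,
    then pairs in lexicographic (source-order) sequence.

    The sources themselves are tied together by nested divergences into the
    first source at ``t_ancestral`` (a free prior parameter by default), so
    every scenario has a single common ancestral population.
    """
    if not sources:
        raise ValueError("need at least one candidate source")
    if len(set(sources)) != len(sources):
        raise ValueError("duplicate source labels")
    if target in sources:
        raise ValueError("target cannot be one of its candidate sources")
    t_intro = f"t_{target}" if t_intro is None else t_intro
    t_anc = "t_ancestral" if t_ancestral is None else t_ancestral

    pops = list(sources) + [target]
    ne = {p: f"N_{p}" for p in sources}
    ne[target] = f"N_{target}"
    samples: list[Event] = [Sample(p) for p in pops]
    backbone: list[Event] = [
        Diverge(src, sources[0], t_anc) for src in sources[1:]
    ]

    scenarios: list[Scenario] = []
    for src in sources:
        events = (
            samples
            + _intro_events(target, t_intro)
            + [Diverge(target, src, t_intro)]
            + backbone
        )
        scenarios.append(
            Scenario(f"{target}<-{src}", pops.copy(), dict(ne), events)
        )
    for s1, s2 in itertools.combinations(sources, 2):
        events = (
            samples
            + _intro_events(target, t_intro)
            + [Admix(target, s1, s2, f"r_{target}", t_intro)]
            + backbone
        )
        scenarios.append(
            Scenario(f"{target}<-{s1}+{s2}", pops.copy(), dict(ne), events)
        )
    return scenarios


def default_prior(
    scenarios: Iterable[Scenario],
    prior_set: str = "set1",
    t_intro_fixed: Mapping[str, float] | None = None,
) -> PriorSpec:
    """Editable default priors covering every parameter the scenarios use.

    Rectangular ("set1") or mid-range peaked truncated-normal ("set2")
    distributions; introduction times present in ``t_intro_fixed`` are not
    given priors (they are calendar-fixed). The ancestral split time gets a
    loose flat prior whose lower bound approaches zero.
    """
    t_intro_fixed = t_intro_fixed or {}
    scenarios = list(scenarios)
    names: list[str] = []
    for sc in scenarios:
        for p in sc.parameter_names():
            if p not in names and p not in t_intro_fixed:
                names.append(p)
    # the ancestral split must predate every calendar-fixed introduction
    latest_fixed = 0.0
    for sc in scenarios:
        for e in sc.events:
            if isinstance(e, (Diverge, Admix)) and isinstance(e.time, (int, float)):
                latest_fixed = max(latest_fixed, float(e.time))
    latest_fixed = max(latest_fixed, *t_intro_fixed.values()) if t_intro_fixed else latest_fixed

    def rect(lo: float, hi: float) -> Distribution:
        if prior_set == "set2":
            mid, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
            return Distribution("truncnorm", lo, hi, (mid, sd))
        return Distribution("uniform", lo, hi)

    dists: dict[str, Distribution] = {}
    constraints: list[tuple[str, str]] = []
    for p in names:
        if p.startswith("N_"):
            dists[p] = rect(1_000.0, 100_000.0)
        elif p.startswith("Nb_"):
            dists[p] = rect(2.0, 500.0)
        elif p.startswith("db_"):
            dists[p] = rect(1.0, 60.0)
        elif p.startswith("r_"):
            dists[p] = rect(0.05, 0.95)
        elif p == "t_ancestral":
            dists[p] = rect(latest_fixed + 1.0, latest_fixed + 10_000.0)
        elif p.startswith("t_"):
            dists[p] = rect(12.0, 600.0)
        elif p == "mu":
            dists[p] = Distribution("loguniform", 1e-5, 1e-3)
        elif p == "p_geom":
            dists[p] = rect(0.0 + 1e-9, 0.5)
        else:
            dists[p] = rect(0.0, 1.0)
    for p in names:
        # the ancestral split predates every free introduction time
        if p.startswith("t_") and p != "t_ancestral" and "t_ancestral" in dists:
            constraints.append(("t_ancestral", p))
    return PriorSpec(dists, constraints, name=prior_set)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_scenario(
    scenario: Scenario,
    params: Mapping[str, float] | None = None,
) -> list[str]:
    """Return human-readable findings; an empty list means the scenario is
    well-formed. With ``params`` given, event times are resolved and the
    lineage bookkeeping is checked numerically; otherwise the (time-ordered)
    event list order is used."""
    findings: list[str] = []
    declared = set(scenario.populations)

    sampled = [e.pop for e in scenario.events if isinstance(e, Sample)]
    for p in sampled:
        if p not in declared:
            findings.append(f"sample event references undeclared population {p!r}")
    dup = {p for p in sampled if sampled.count(p) > 1}
    for p in sorted(dup):
        findings.append(f"population {p!r} has more than one sample event")
    for p in scenario.populations:
        if p not in sampled and p not in scenario.ghosts:
            findings.append(
                f"population {p!r} is neither sampled nor flagged as a ghost"
            )
    for p in scenario.ne:
        if p not in declared:
            findings.append(f"effective size given for undeclared population {p!r}")
    for p in declared:
        if p not in scenario.ne:
            findings.append(f"population {p!r} has no effective size")

    # order events by resolved time when possible, else keep list order
    timed = scenario.events
    if params is not None:
        try:
            timed = sorted(scenario.events, key=lambda e: resolve(e.time, params))
            for e in timed:
                # size changes at negative times are clamped to the present
                # by the simulator (a bottleneck still ongoing at sampling)
                if resolve(e.time, params) < 0 and not isinstance(e, SizeChange):
                    findings.append(f"event {e} has negative time")
        except KeyError as exc:
            findings.append(str(exc))
            timed = scenario.events

    merged: set[str] = set()
    for e in timed:
        if isinstance(e, Sample):
            if e.pop in merged:
                findings.append(f"sampling from merged-away population {e.pop!r}")
        elif isinstance(e, Diverge):
            for p in (e.derived, e.source):
                if p not in declared:
                    findings.append(f"divergence references undeclared {p!r}")
            if e.derived in merged:
                findings.append(
                    f"population {e.derived!r} diverges after having merged away"
                )
            if e.source in merged:
                findings.append(
                    f"lineages sent into merged-away population {e.source!r}"
                )
            merged.add(e.derived)
        elif isinstance(e, Admix):
            for p in (e.derived, e.source1, e.source2):
                if p not in declared:
                    findings.append(f"admixture references undeclared {p!r}")
            if e.derived in merged:
                findings.append(
                    f"population {e.derived!r} admixes after having merged away"
                )
            for p in (e.source1, e.source2):
                if p in merged:
                    findings.append(
                        f"lineages sent into merged-away population {p!r}"
                    )
            merged.add(e.derived)
        elif isinstance(e, SizeChange):
            if e.pop not in declared:
                findings.append(f"size change on undeclared population {e.pop!r}")
            if e.pop in merged:
                findings.append(
                    f"size change on merged-away population {e.pop!r}"
                )
    survivors = declared - merged
    if len(survivors) != 1:
        findings.append(
            f"expected exactly one ancestral population after all events, "
            f"got {sorted(survivors)}"
        )
    return findings


# ---------------------------------------------------------------------------
# Serialization (YAML/JSON-friendly dicts)
# ---------------------------------------------------------------------------

_EVENT_TAGS = {"sample": Sample, "diverge": Diverge, "admix": Admix, "size_change": SizeChange}


def scenario_to_dict(sc: Scenario) -> dict:
    events = []
    for e in sc.events:
        tag = next(t for t, cls in _EVENT_TAGS.items() if isinstance(e, cls))
        d = {"event": tag}
        d.update({k: getattr(e, k) for k in e.__dataclass_fields__})
        events.append(d)
    return {
        "name": sc.name,
        "populations": list(sc.populations),
        "ne": dict(sc.ne),
        "ghosts": sorted(sc.ghosts),
        "events": events,
    }


def scenario_from_dict(d: dict) -> Scenario:
    events: list[Event] = []
    for ed in d["events"]:
        ed = dict(ed)
        cls = _EVENT_TAGS[ed.pop("event")]
        events.append(cls(**ed))
    return Scenario(
        name=d["name"],
        populations=list(d["populations"]),
        ne=dict(d["ne"]),
        events=events,
        ghosts=set(d.get("ghosts", [])),
    )


def prior_to_dict(prior: PriorSpec) -> dict:
    return {
        "name": prior.name,
        "distributions": {
            k: {"kind": v.kind, "lo": v.lo, "hi": v.hi, "args": list(v.args)}
            for k, v in prior.distributions.items()
        },
        "constraints": [list(c) for c in prior.constraints],
    }


def prior_from_dict(d: dict) -> PriorSpec:
    return PriorSpec(
        distributions={
            k: Distribution(v["kind"], v["lo"], v["hi"], tuple(v.get("args", ())))
            for k, v in d["distributions"].items()
        },
        constraints=[tuple(c) for c in d.get("constraints", [])],
        name=d.get("name", "set1"),
    )
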