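"""Demographic scenarios, prior specifications and parameter sampling.

A :class:`Scenario` is a directed demographic history: a set of populations,
timed events (founding of a new population from one source, admixed founding
from two sources) and priors for the event-time / admixture / mutation
parameters.  Two built-in scenarios describe competing invasion histories
with one native source, two sampled waves of introduced populations and one
unsampled ("ghost") population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml

__all__ = [
    "PopulationSpec",
    "DemographicEvent",
    "PriorSpec",
    "Scenario",
    "ParameterDraw",
    "ScenarioError",
    "build_builtin_scenario",
    "validate_scenario",
    "sample_parameters",
    "resolve_event_times",
    "prior_support",
    "save_scenario",
    "load_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
]

#: default number of diploid founding individuals for an introduction
DEFAULT_FOUNDERS = 25
#: default duration (generations) a founded population stays at founder size
DEFAULT_BOTTLENECK = 5.0

#: native effective size (diploid individuals)
NATIVE_SIZE = 5000
#: stable size reached by every introduced population
INTRODUCED_SIZE = 1000


class ScenarioError(ValueError):
    """A scenario or prior specification violates an invariant."""


@dataclass(frozen=True)
class PopulationSpec:
    """One population in a scenario.

    Parameters
    ----------
    name : str
        Unique label within the scenario.
    stable_size : float
        Long-term effective number of diploid individuals (>= 1).
    sampled : bool
        Whether the population is genotyped.  Ghost populations are
        demographically real but unsampled.
    """

    name: str
    stable_size: float
    sampled: bool = True


@dataclass(frozen=True)
class DemographicEvent:
    """A timed event in a demographic history.

    ``founding``: at time ``time_param`` (generations before present) all
    lineages of ``target`` move to ``sources[0]``; forward in time the target
    was founded by ``founders`` diploid individuals and stayed at that size
    for ``bottleneck_duration`` generations.

    ``admixture``: like founding but each lineage independently moves to
    ``sources[0]`` with probability given by the ``admixture_param``
    parameter, otherwise to ``sources[1]``.
    """

    time_param: str
    kind: str  # 'founding' | 'admixture'
    target: str
    sources: tuple[str, ...]
    founders: int = DEFAULT_FOUNDERS
    bottleneck_duration: float = DEFAULT_BOTTLENECK
    admixture_param: str | None = None


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one scalar parameter.

    ``dist`` is one of ``uniform`` (low, high), ``loguniform`` (low, high),
    ``gamma`` (shape, mean) or ``fixed`` (value,).  ``less_than`` lists
    parameter names this parameter must be strictly smaller than; the joint
    draw is rejection-resampled until all orderings hold.
    """

    name: str
    dist: str
    params: tuple[float, ...]
    less_than: tuple[str, ...] = ()


@dataclass(frozen=True)
class ParameterDraw:
    """One joint draw from the priors of a scenario."""

    values: dict[str, float]
    seed: int | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class Scenario:
    """A full demographic scenario: populations, events and priors."""

    label: str
    populations: list[PopulationSpec]
    events: list[DemographicEvent]
    priors: list[PriorSpec]

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def sampled_populations(self) -> list[str]:
        return [p.name for p in self.populations if p.sampled]

    @property
    def root(self) -> str:
        """Name of the unique population that is never founded."""
        targets = {e.target for e in self.events}
        roots = [p.name for p in self.populations if p.name not in targets]
        if len(roots) != 1:
            raise ScenarioError(f"expected exactly one root population, got {roots}")
        return roots[0]

    def prior(self, name: str) -> PriorSpec:
        for pr in self.priors:
            if pr.name == name:
                return pr
        raise KeyError(name)

    @property
    def parameter_names(self) -> list[str]:
        return [pr.name for pr in self.priors]


def _default_priors() -> list[PriorSpec]:
    # time priors wide enough to contain plausible posterior intervals;
    # orderings enforced by rejection.
    return [
        PriorSpec("t1", "uniform", (10.0, 500.0), less_than=("t2",)),
        PriorSpec("t2", "uniform", (10.0, 500.0), less_than=("t3",)),
        PriorSpec("t3", "uniform", (10.0, 500.0)),
        PriorSpec("r", "uniform", (0.05, 0.95)),
        PriorSpec("micro_mean_mu", "loguniform", (1e-4, 1e-3)),
        PriorSpec("mt_mu", "loguniform", (1e-7, 1e-5)),
    ]


def build_builtin_scenario(label: str) -> Scenario:
    """Return one of the two built-in invasion scenarios.

    ``scenario1``: two independent introductions from the native range at
    ``t3`` (ghostNZ and Cal); at ``t2`` Cal founds inva2 and NZ2 is founded
    by admixture between ghostNZ (proportion ``r``) and Cal.

    ``scenario2``: a serial chain — native founds ghostNZ at ``t3``, ghostNZ
    founds Cal at ``t2``; at ``t1`` Cal founds inva2 and NZ2 is founded by
    admixture between ghostNZ and Cal.

    Both scenarios share the same populations and priors, so their parameter
    vectors align row-wise in ABC reference tables.
    """
    populations = [
        PopulationSpec("native", NATIVE_SIZE, sampled=True),
        PopulationSpec("ghostNZ", INTRODUCED_SIZE, sampled=False),
        PopulationSpec("Cal", INTRODUCED_SIZE, sampled=True),
        PopulationSpec("inva2", INTRODUCED_SIZE, sampled=True),
        PopulationSpec("NZ2", INTRODUCED_SIZE, sampled=True),
    ]
    if label == "scenario1":
        events = [
            DemographicEvent("t3", "founding", "ghostNZ", ("native",)),
            DemographicEvent("t3", "founding", "Cal", ("native",)),
            DemographicEvent("t2", "founding", "inva2", ("Cal",)),
            DemographicEvent(
                "t2", "admixture", "NZ2", ("ghostNZ", "Cal"), admixture_param="r"
            ),
        ]
    elif label == "scenario2":
        events = [
            DemographicEvent("t3", "founding", "ghostNZ", ("native",)),
            DemographicEvent("t2", "founding", "Cal", ("ghostNZ",)),
            DemographicEvent("t1", "founding", "inva2", ("Cal",)),
            DemographicEvent(
                "t1", "admixture", "NZ2", ("ghostNZ", "Cal"), admixture_param="r"
            ),
        ]
    else:
        raise ScenarioError(f"unknown builtin scenario label: {label!r}")
    return validate_scenario(Scenario(label, populations, events, _default_priors()))


def validate_scenario(s: Scenario) -> Scenario:
    """Check every scenario invariant; raise :class:`ScenarioError` listing
    all violations, or return ``s`` unchanged."""
    problems: list[str] = []
    names = s.population_names
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        problems.append(f"duplicate population names: {dupes}")
    for p in s.populations:
        if p.stable_size < 1:
            problems.append(f"population {p.name!r} has stable_size < 1")

    prior_names = {pr.name for pr in s.priors}
    targets: list[str] = []
    for e in s.events:
        targets.append(e.target)
        if e.kind not in ("founding", "admixture"):
            problems.append(f"unknown event kind {e.kind!r}")
        if e.target not in names:
            problems.append(f"event targets unknown population {e.target!r}")
        for src in e.sources:
            if src not in names:
                problems.append(f"event source {src!r} is not a population")
        if e.kind == "founding" and len(e.sources) != 1:
            problems.append(f"founding of {e.target!r} needs exactly 1 source")
        if e.kind == "admixture":
            if len(e.sources) != 2:
                problems.append(f"admixture of {e.target!r} needs exactly 2 sources")
            if e.admixture_param is None:
                problems.append(f"admixture of {e.target!r} lacks a proportion parameter")
            elif e.admixture_param not in prior_names:
                problems.append(
                    f"admixture parameter {e.admixture_param!r} has no prior"
                )
        if e.founders < 1:
            problems.append(f"event on {e.target!r}: founders < 1")
        if e.bottleneck_duration < 0:
            problems.append(f"event on {e.target!r}: negative bottleneck duration")
        if e.time_param not in prior_names:
            problems.append(f"time parameter {e.time_param!r} has no prior")

    for t in set(targets):
        if targets.count(t) > 1:
            problems.append(f"population {t!r} is founded more than once")
    roots = [n for n in names if n not in targets]
    if len(roots) != 1:
        problems.append(f"expected exactly one root population, found {roots}")

    for pr in s.priors:
        if pr.dist not in ("uniform", "loguniform", "gamma", "fixed"):
            problems.append(f"prior {pr.name!r}: unknown dist {pr.dist!r}")
        if any(not math.isfinite(v) for v in pr.params):
            problems.append(f"prior {pr.name!r}: non-finite hyper-parameters")
        if pr.dist in ("uniform", "loguniform") and not pr.params[0] < pr.params[1]:
            problems.append(f"prior {pr.name!r}: lower bound must be < upper bound")
        for other in pr.less_than:
            if other not in prior_names:
                problems.append(
                    f"prior {pr.name!r}: ordering refers to unknown parameter {other!r}"
                )
    if _constraints_cyclic(s.priors):
        problems.append("ordering constraints among parameters form a cycle")

    if problems:
        raise ScenarioError(
            f"invalid scenario {s.label!r}:\n  - " + "\n  - ".join(problems)
        )
    return s


def _constraints_cyclic(priors: list[PriorSpec]) -> bool:
    edges = {pr.name: [o for o in pr.less_than] for pr in priors}
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str) -> bool:
        if state.get(node) == 1:
            return False
        if state.get(node) == 0:
            return True
        state[node] = 0
        for nxt in edges.get(node, ()):
            if nxt in edges and visit(nxt):
                return True
        state[node] = 1
        return False

    return any(visit(n) for n in edges)


def _draw_one(pr: PriorSpec, rng: np.random.Generator) -> float:
    if pr.dist == "uniform":
        return float(rng.uniform(pr.params[0], pr.params[1]))
    if pr.dist == "loguniform":
        lo, hi = pr.params
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if pr.dist == "gamma":
        shape, mean = pr.params
        return float(rng.gamma(shape, mean / shape))
    if pr.dist == "fixed":
        return float(pr.params[0])
    raise ScenarioError(f"unknown prior dist {pr.dist!r}")


def sample_parameters(
    priors: list[PriorSpec],
    rng_seed: int | np.random.Generator,
    max_tries: int = 100_000,
) -> ParameterDraw:
    """Draw one joint parameter set honoring all ordering constraints.

    Ordering constraints are enforced by rejection: the joint vector is
    redrawn until every ``less_than`` relation holds strictly.
    """
    if isinstance(rng_seed, np.random.Generator):
        rng, seed = rng_seed, None
    else:
        rng, seed = np.random.default_rng(rng_seed), int(rng_seed)
    for _ in range(max_tries):
        values = {pr.name: _draw_one(pr, rng) for pr in priors}
        ok = all(
            values[pr.name] < values[other]
            for pr in priors
            for other in pr.less_than
        )
        if ok:
            return ParameterDraw(values=values, seed=seed)
    raise ScenarioError(
        f"could not satisfy ordering constraints after {max_tries} draws"
    )


def prior_support(pr: PriorSpec) -> tuple[float, float]:
    """Marginal support of a prior (used to clamp adjusted posterior draws)."""
    if pr.dist in ("uniform", "loguniform"):
        return float(pr.params[0]), float(pr.params[1])
    if pr.dist == "gamma":
        return 0.0, math.inf
    if pr.dist == "fixed":
        v = float(pr.params[0])
        return v, v
    raise ScenarioError(f"unknown prior dist {pr.dist!r}")


def resolve_event_times(
    s: Scenario, draw: ParameterDraw
) -> list[tuple[float, DemographicEvent]]:
    """Events with concrete times, sorted by time ascending (pastward)."""
    resolved = [(float(draw[e.time_param]), e) for e in s.events]
    resolved.sort(key=lambda te: te[0])
    return resolved


# ---------------------------------------------------------------------------
# scenario configuration file (YAML) round trip


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "label": s.label,
        "populations": [asdict(p) for p in s.populations],
        "events": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(e).items()}
            for e in s.events
        ],
        "priors": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(pr).items()}
            for pr in s.priors
        ],
    }


def scenario_from_dict(d: dict) -> Scenario:
    pops = [PopulationSpec(**p) for p in d["populations"]]
    events = [
        DemographicEvent(
            time_param=e["time_param"],
            kind=e["kind"],
            target=e["target"],
            sources=tuple(e["sources"]),
            founders=e.get("founders", DEFAULT_FOUNDERS),
            bottleneck_duration=e.get("bottleneck_duration", DEFAULT_BOTTLENECK),
            admixture_param=e.get("admixture_param"),
        )
        for e in d["events"]
    ]
    priors = [
        PriorSpec(
            name=pr["name"],
            dist=pr["dist"],
            params=tuple(pr["params"]),
            less_than=tuple(pr.get("less_than", ())),
        )
        for pr in d["priors"]
    ]
    return validate_scenario(Scenario(d["label"], pops, events, priors))


def save_scenario(s: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
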