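"""Application task graphs for distributed health-monitoring pipelines.

A monitoring application is modelled as a directed acyclic graph whose
vertices are tasks (acquisition, signal-processing stages, sinks) and whose
edges are data flows carrying a per-user data volume in KB/s.  The canonical
instance is the nine-task sudden-death (SD) detection pipeline:

    t1 acquisition -> t2 noise reduction -> t3 filtering -> t4 segmentation
    -> t5 feature extraction -> t6 anomaly detection
    -> {t7 visualization, t8 store, t9 alarm}

``networkx`` provides the graph algorithms; this module owns the domain
types, their invariants and the canonical SD graph builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx

__all__ = [
    "TaskSpec",
    "DataFlow",
    "ApplicationGraph",
    "ValidationReport",
    "GraphValidationError",
    "build_sd_graph",
    "validate_graph",
    "topological_order",
    "SD_COMPUTE_TASKS",
]

StageKind = Literal["acquire", "transform", "analyze", "sink"]

#: the chain of priced compute stages of the SD pipeline
SD_COMPUTE_TASKS = ("t2", "t3", "t4", "t5", "t6")

#: default per-user acquisition rate of a 12-lead ECG stream, KB/s
DEFAULT_ACQUISITION_RATE_KBPS = 1.0


class GraphValidationError(ValueError):
    """Raised when an application graph violates a structural invariant."""


@dataclass(frozen=True)
class TaskSpec:
    """One application task (the framework's granularity unit)."""

    task_id: str
    name: str
    stage_kind: StageKind
    granularity: str = "task"
    per_user: bool = True


@dataclass(frozen=True)
class DataFlow:
    """A directed data flow between two tasks.

    ``volume`` is the per-user data volume in KB/s exchanged from ``src``
    to ``dst``.
    """

    src: str
    dst: str
    volume: float = DEFAULT_ACQUISITION_RATE_KBPS

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise GraphValidationError(f"self-loop flow on {self.src!r}")
        if self.volume < 0:
            raise GraphValidationError(f"negative flow volume {self.volume}")


@dataclass
class ApplicationGraph:
    """A directed graph of tasks and data flows."""

    tasks: list[TaskSpec] = field(default_factory=list)
    flows: list[DataFlow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.task_id for t in self.tasks]
        if len(ids) != len(set(ids)):
            raise GraphValidationError("duplicate task ids")

    @property
    def task_ids(self) -> list[str]:
        return [t.task_id for t in self.tasks]

    def task(self, task_id: str) -> TaskSpec:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(task_id)

    def compute_tasks(self) -> list[str]:
        """Tasks that carry compute cost: everything but acquisition/sinks."""
        return [t.task_id for t in self.tasks if t.stage_kind in ("transform", "analyze")]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for t in self.tasks:
            g.add_node(t.task_id, spec=t)
        for f in self.flows:
            g.add_edge(f.src, f.dst, volume=f.volume)
        return g

    def successors(self, task_id: str) -> list[str]:
        return sorted(f.dst for f in self.flows if f.src == task_id)

    def predecessors(self, task_id: str) -> list[str]:
        return sorted(f.src for f in self.flows if f.dst == task_id)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tasks": [
                {
                    "task_id": t.task_id,
                    "name": t.name,
                    "stage_kind": t.stage_kind,
                    "granularity": t.granularity,
                    "per_user": t.per_user,
                }
                for t in self.tasks
            ],
            "flows": [
                {"src": f.src, "dst": f.dst, "volume": f.volume} for f in self.flows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ApplicationGraph":
        tasks = [TaskSpec(**t) for t in d.get("tasks", [])]
        flows = [DataFlow(**f) for f in d.get("flows", [])]
        return cls(tasks=tasks, flows=flows)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_graph`: pass/fail plus every violation."""

    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


_SD_TASKS = [
    TaskSpec("t1", "data acquisition", "acquire"),
    TaskSpec("t2", "noise reduction", "transform"),
    TaskSpec("t3", "filtering", "transform"),
    TaskSpec("t4", "segmentation", "transform"),
    TaskSpec("t5", "feature extraction", "transform"),
    TaskSpec("t6", "anomaly detection", "analyze"),
    TaskSpec("t7", "visualization", "sink"),
    TaskSpec("t8", "store data", "sink"),
    TaskSpec("t9", "raise alarm", "sink"),
]


def build_sd_graph(
    acquisition_rate: float = DEFAULT_ACQUISITION_RATE_KBPS,
    volume_overrides: dict[tuple[str, str], float] | None = None,
    early_visualization_src: str | None = None,
) -> ApplicationGraph:
    """Build the canonical nine-task SD-detection graph.

    The processing chain t1..t6 is serial; t6 fans out to the three sinks
    (visualization t7, store t8, alarm t9 — the alarm edge is exercised at
    run time only on non-normal verdicts).  Every flow defaults to the
    acquisition rate (1 KB/s per monitored user); per-flow overrides are
    accepted because downstream volume reductions are model parameters, not
    measured quantities.

    ``early_visualization_src`` optionally adds a direct edge from an early
    stage (``"t1"`` or ``"t3"``) to the visualization sink, so the wearable
    can display raw-derived data such as the heartbeat count.
    """
    overrides = dict(volume_overrides or {})
    edges = [("t1", "t2"), ("t2", "t3"), ("t3", "t4"), ("t4", "t5"), ("t5", "t6"),
             ("t6", "t7"), ("t6", "t8"), ("t6", "t9")]
    if early_visualization_src is not None:
        if early_visualization_src not in ("t1", "t2", "t3"):
            raise GraphValidationError(
                f"early visualization edge must leave an early stage, got {early_visualization_src!r}"
            )
        edges.append((early_visualization_src, "t7"))
    flows = [
        DataFlow(src, dst, overrides.get((src, dst), acquisition_rate))
        for src, dst in edges
    ]
    return ApplicationGraph(tasks=list(_SD_TASKS), flows=flows)


def validate_graph(graph: ApplicationGraph) -> ValidationReport:
    """Check structural invariants: acyclicity, endpoint existence,
    reachability, and acquire/sink degree rules."""
    violations: list[str] = []
    ids = set(graph.task_ids)

    for f in graph.flows:
        for endpoint in (f.src, f.dst):
            if endpoint not in ids:
                violations.append(f"dangling flow endpoint {endpoint!r} in {f.src}->{f.dst}")
        if f.src == f.dst:
            violations.append(f"self-loop on {f.src!r}")

    g = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        try:
            cycle = nx.find_cycle(g)
            violations.append("cycle: " + " -> ".join(e[0] for e in cycle))
        except nx.NetworkXNoCycle:  # pragma: no cover - unreachable
            violations.append("graph is not acyclic")

    for t in graph.tasks:
        if t.stage_kind == "acquire" and graph.predecessors(t.task_id):
            violations.append(f"acquire task {t.task_id!r} has predecessors")
        if t.stage_kind == "sink" and graph.successors(t.task_id):
            violations.append(f"sink task {t.task_id!r} has successors")

    sources = [t.task_id for t in graph.tasks if t.stage_kind == "acquire"]
    if sources and nx.is_directed_acyclic_graph(g):
        reachable = set(sources)
        for s in sources:
            reachable |= nx.descendants(g, s)
        unreachable = sorted(ids - reachable)
        if unreachable:
            violations.append("unreachable tasks: " + ", ".join(unreachable))

    return ValidationReport(ok=not violations, violations=violations)


def topological_order(graph: ApplicationGraph) -> list[str]:
    """Deterministic precedence-respecting order (ties broken by task_id)."""
    g = graph.to_networkx()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise GraphValidationError("graph contains a cycle") from exc
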