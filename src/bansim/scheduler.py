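"""Task-to-device assignment, latency estimation and deadline feasibility.

The central semantics, inferred from the case study's timing tables:

* a stage assigned to a per-user BAN device (class ``B``) runs in parallel
  on every athlete's own device, so its latency is the per-user task cost,
  independent of how many athletes are monitored;
* a stage assigned to a shared staff device (class ``M``) serializes the
  work of all athletes, so its latency is ``n_users x task_cost``;
* environmental devices (class ``E``) never compute.

End-to-end latency is the sum over the serialized compute chain (the
acquisition task and the sinks carry zero compute cost by default).  The
real-time deadline follows from the highest physiologically possible heart
rate: at 220 beats/min no second beat can occur within 60/220 ~= 0.27 s, so
each beat must be fully analyzed within that window.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .app_graph import ApplicationGraph
from .devices import CostModel, DeviceProfile, task_cost

__all__ = [
    "MonitoringContext",
    "Assignment",
    "LatencyReport",
    "InvalidAssignmentError",
    "EnumerationSizeError",
    "stage_latency",
    "estimate_latency",
    "deadline_from_max_hr",
    "enumerate_assignments",
    "best_assignment",
    "MAX_ENUMERATION_TASKS",
]

#: tractability guard for exhaustive assignment enumeration
MAX_ENUMERATION_TASKS = 12

#: display rounding of the timing tables (full precision is kept internally)
DISPLAY_DECIMALS = 7


class InvalidAssignmentError(ValueError):
    """An assignment violates a placement invariant."""


class EnumerationSizeError(ValueError):
    """The assignment space is too large for exhaustive enumeration."""


@dataclass(frozen=True)
class MonitoringContext:
    """A monitoring scenario: how many athletes, and the deadline."""

    n_users: int
    deadline: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")


@dataclass(frozen=True)
class Assignment:
    """A mapping from compute task ids to device ids."""

    mapping: Mapping[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    def device_for(self, task_id: str) -> str:
        return self.mapping[task_id]

    def items(self):
        return self.mapping.items()


@dataclass
class LatencyReport:
    """Per-stage and total latency of one assignment in one context."""

    per_task_latency: dict[str, float]
    total: float
    feasible: bool
    context: MonitoringContext
    assignment: Assignment
    deadline: float = field(init=False)

    def __post_init__(self) -> None:
        self.deadline = self.context.deadline

    def rounded(self, decimals: int = DISPLAY_DECIMALS) -> dict[str, float]:
        """Display view: per-task latencies and total rounded."""
        out = {k: round(v, decimals) for k, v in self.per_task_latency.items()}
        out["total"] = round(self.total, decimals)
        return out

    def to_dict(self) -> dict:
        return {
            "context": {
                "label": self.context.label,
                "n_users": self.context.n_users,
                "deadline": self.context.deadline,
            },
            "assignment": {"label": self.assignment.label, "mapping": dict(self.assignment.mapping)},
            "per_task_latency": dict(self.per_task_latency),
            "total": self.total,
            "feasible": self.feasible,
        }


def deadline_from_max_hr(max_hr: float) -> float:
    """Real-time deadline in seconds implied by a maximum heart rate.

    60/max_hr, truncated (not rounded) to 2 decimals: 220 beats/min gives
    60/220 = 0.2727... -> 0.27 s.
    """
    if max_hr <= 0:
        raise ValueError("max_hr must be positive")
    return math.floor(100.0 * 60.0 / max_hr) / 100.0


def stage_latency(
    task_id: str,
    device: DeviceProfile,
    cost_model: CostModel,
    n_users: int,
) -> float:
    """Latency contributed by one pipeline stage.

    Per-user BAN devices run all athletes in parallel (one worn instance
    each); shared devices serialize the athletes' work.
    """
    if device.device_class == "E":
        raise InvalidAssignmentError(
            f"E-class device {device.device_id!r} cannot execute task {task_id!r}"
        )
    cost = task_cost(device, task_id, cost_model)
    if device.per_user_instance:
        return cost
    return n_users * cost


def _check_assignment(
    graph: ApplicationGraph,
    assignment: Assignment,
    devices: Mapping[str, DeviceProfile],
) -> None:
    for task_id, device_id in assignment.items():
        if device_id not in devices:
            raise InvalidAssignmentError(f"unknown device {device_id!r} for {task_id!r}")
        profile = devices[device_id]
        if profile.device_class == "E" or (
            not profile.can_compute and task_id in graph.compute_tasks()
        ):
            raise InvalidAssignmentError(
                f"device {device_id!r} cannot execute compute task {task_id!r}"
            )
    # acquisition stays on the BAN
    for t in graph.tasks:
        if t.stage_kind == "acquire" and t.task_id in assignment.mapping:
            cls = devices[assignment.device_for(t.task_id)].device_class
            if cls != "B":
                raise InvalidAssignmentError(
                    f"acquisition task {t.task_id!r} must run on a B-class device"
                )
    # no data stream back from staff devices into the BAN
    for f in graph.flows:
        if f.src in assignment.mapping and f.dst in assignment.mapping:
            src_cls = devices[assignment.device_for(f.src)].device_class
            dst_cls = devices[assignment.device_for(f.dst)].device_class
            if src_cls == "M" and dst_cls == "B":
                raise InvalidAssignmentError(
                    f"backflow {f.src}->{f.dst}: M-class to B-class is not contemplated"
                )


def estimate_latency(
    graph: ApplicationGraph,
    assignment: Assignment,
    devices: Mapping[str, DeviceProfile],
    cost_model: CostModel,
    context: MonitoringContext,
    transmission_bandwidth_kbit: float | None = None,
) -> LatencyReport:
    """End-to-end latency of ``assignment`` under ``context``.

    Sums :func:`stage_latency` over the serialized compute chain — the
    tasks that carry a cost entry.  Acquisition and sinks default to zero
    compute cost and contribute nothing unless priced in the cost model.
    Full precision is kept internally; round only for display.

    Communication delay is excluded by default (the reference timing tables
    contain compute terms only).  Passing ``transmission_bandwidth_kbit``
    enables an additive volume/bandwidth term for every flow that crosses
    devices: one second's aggregate data (``n_users x volume`` KB, 8 kbit
    per KB) over the shared link.
    """
    _check_assignment(graph, assignment, devices)

    def priced(task_id: str) -> bool:
        if task_id in cost_model.base_costs:
            return True
        d = assignment.mapping.get(task_id)
        return d is not None and task_id in devices[d].accelerators

    per_task: dict[str, float] = {}
    for task_id in graph.task_ids:
        if not priced(task_id):
            continue
        if task_id not in assignment.mapping:
            raise InvalidAssignmentError(f"priced task {task_id!r} is unassigned")
        device = devices[assignment.device_for(task_id)]
        per_task[task_id] = stage_latency(task_id, device, cost_model, context.n_users)
    total = sum(per_task.values())
    if transmission_bandwidth_kbit is not None:
        if transmission_bandwidth_kbit <= 0:
            raise ValueError("transmission bandwidth must be positive")
        comm = sum(
            context.n_users * f.volume * 8.0 / transmission_bandwidth_kbit
            for f in graph.flows
            if f.src in assignment.mapping and f.dst in assignment.mapping
            and assignment.device_for(f.src) != assignment.device_for(f.dst)
        )
        if comm:
            per_task["transmission"] = comm
            total += comm
    return LatencyReport(
        per_task_latency=per_task,
        total=total,
        feasible=total <= context.deadline,
        context=context,
        assignment=assignment,
    )


def enumerate_assignments(
    graph: ApplicationGraph,
    devices: Mapping[str, DeviceProfile],
) -> Iterator[Assignment]:
    """Exhaustively yield every valid compute-task assignment.

    Valid means: only B/M devices, acquisition pinned to a B device, and the
    processing flow is monotone from the BAN outward — once a task runs on a
    shared M device, no successor along any flow returns to a B device.
    Deterministic order: tasks in graph order, candidate devices sorted by id.
    """
    compute = graph.compute_tasks()
    if len(compute) > MAX_ENUMERATION_TASKS:
        raise EnumerationSizeError(
            f"{len(compute)} compute tasks exceed the enumeration guard "
            f"({MAX_ENUMERATION_TASKS})"
        )
    candidates = sorted(
        d for d, p in devices.items() if p.device_class in ("B", "M") and p.can_compute
    )
    if not candidates:
        return
    flows = [(f.src, f.dst) for f in graph.flows]
    cls = {d: devices[d].device_class for d in candidates}
    for combo in itertools.product(candidates, repeat=len(compute)):
        mapping = dict(zip(compute, combo))
        ok = all(
            not (cls[mapping[s]] == "M" and cls[mapping[d]] == "B")
            for s, d in flows
            if s in mapping and d in mapping
        )
        if ok:
            yield Assignment(mapping=mapping)


def best_assignment(
    graph: ApplicationGraph,
    devices: Mapping[str, DeviceProfile],
    cost_model: CostModel,
    context: MonitoringContext,
) -> tuple[Assignment, LatencyReport]:
    """The minimal-latency assignment for ``context``.

    Ties are broken by preferring more tasks on B-class devices (compute the
    raw bio-signals nearest the user), then lexicographically on the device
    sequence.  If no assignment meets the deadline the fastest one is
    returned with ``feasible=False``.
    """
    best: tuple | None = None
    compute = graph.compute_tasks()
    for assignment in enumerate_assignments(graph, devices):
        report = estimate_latency(graph, assignment, devices, cost_model, context)
        n_ban = sum(
            1 for d in assignment.mapping.values() if devices[d].device_class == "B"
        )
        key = (report.total, -n_ban, tuple(assignment.mapping[t] for t in compute))
        if best is None or key < best[0]:
            best = (key, assignment, report)
    if best is None:
        raise InvalidAssignmentError("no valid assignment exists for these devices")
    return best[1], best[2]
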