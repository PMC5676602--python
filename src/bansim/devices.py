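"""Heterogeneous device profiles, per-task cost models and network links.

Devices fall into three classes:

* ``B`` — body-area-network (BAN) devices worn by each monitored athlete
  (chest strap, smartwatch).  One instance per user; they may compute.
* ``M`` — shared staff computers (tablet, laptop).  One instance serves all
  users, so per-user work serializes on them.
* ``E`` — external environmental sensors.  They only send data and never
  execute pipeline tasks.

Per-task execution costs are expressed on a reference device (the
smartwatch) and scaled by each device's dimensionless speedup; an optional
per-task *accelerator* (e.g., DSP hardware for the wavelet stage) overrides
the scaled cost with an absolute measured value.
"""

from __future__ import annotations

import re
import statistics
import time
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

__all__ = [
    "DeviceProfile",
    "CostModel",
    "NetworkLink",
    "CostModelError",
    "UnitError",
    "task_cost",
    "required_bandwidth",
    "link_feasible",
    "parse_rate_kbit",
    "calibrate_cost_model",
]

DeviceClass = Literal["B", "M", "E"]


class CostModelError(KeyError):
    """A task has no cost entry in the model."""


class UnitError(ValueError):
    """A data-rate unit string could not be normalized."""


@dataclass(frozen=True)
class DeviceProfile:
    """One computing (or sensing-only) device of the deployment."""

    device_id: str
    device_class: DeviceClass
    speedup: float = 1.0
    accelerators: Mapping[str, float] = field(default_factory=dict)
    per_user_instance: bool | None = None
    can_compute: bool | None = None  # chest strap senses only; E-class never computes

    def __post_init__(self) -> None:
        if self.speedup <= 0:
            raise ValueError(f"speedup must be positive, got {self.speedup}")
        if self.can_compute is None:
            object.__setattr__(self, "can_compute", self.device_class != "E")
        if self.device_class == "E" and self.can_compute:
            raise ValueError("E-class devices never execute pipeline tasks")
        if self.per_user_instance is None:
            # B-class devices are worn, one per athlete; shared otherwise
            object.__setattr__(self, "per_user_instance", self.device_class == "B")
        if self.device_class == "B" and not self.per_user_instance:
            raise ValueError("B-class devices are worn per user (per_user_instance)")


@dataclass
class CostModel:
    """Per-task seconds-per-user on a reference device."""

    base_costs: dict[str, float]
    reference_device: str

    def __post_init__(self) -> None:
        for task_id, cost in self.base_costs.items():
            if cost < 0:
                raise ValueError(f"negative cost for {task_id}: {cost}")

    @property
    def tasks(self) -> list[str]:
        return sorted(self.base_costs)


@dataclass(frozen=True)
class NetworkLink:
    """A wireless/wired link with its nominal data rate (taken as printed)."""

    technology: str
    data_rate: str  # value + unit, e.g. "100 Kbps"
    range_m: float
    shared: bool = True

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ValueError("range must be positive")
        if self.data_rate_kbit <= 0:
            raise ValueError("data rate must be positive")

    @property
    def data_rate_kbit(self) -> float:
        return parse_rate_kbit(self.data_rate)


_RATE_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*([A-Za-z/]+)\s*$")
_RATE_UNITS_KBIT = {
    "bps": 1e-3, "bit/s": 1e-3,
    "kbps": 1.0, "kbit/s": 1.0,
    "mbps": 1e3, "mbit/s": 1e3,
    "gbps": 1e6, "gbit/s": 1e6,
}


def parse_rate_kbit(rate: str | float) -> float:
    """Normalize a data-rate string ("1.3 Mbps", "100 Kbps") to kbit/s.

    Bare numbers are taken to already be kbit/s.
    """
    if isinstance(rate, (int, float)):
        return float(rate)
    m = _RATE_RE.match(rate)
    if not m:
        raise UnitError(f"unrecognized data rate {rate!r}")
    value, unit = float(m.group(1)), m.group(2).lower()
    if unit not in _RATE_UNITS_KBIT:
        raise UnitError(f"unrecognized data-rate unit {unit!r} in {rate!r}")
    return value * _RATE_UNITS_KBIT[unit]


def task_cost(device: DeviceProfile, task_id: str, cost_model: CostModel) -> float:
    """Seconds per user for ``task_id`` on ``device``.

    Accelerator overrides are absolute measured costs; otherwise the
    reference cost is divided by the device's speedup at full floating
    precision (no intermediate rounding — the printed tables round only
    for display).
    """
    if task_id in device.accelerators:
        return float(device.accelerators[task_id])
    if task_id not in cost_model.base_costs:
        raise CostModelError(f"no cost entry for task {task_id!r}")
    return cost_model.base_costs[task_id] / device.speedup


def required_bandwidth(n_users: int, per_user_rate_kbps: float = 1.0) -> float:
    """Aggregate uplink rate in kbit/s for ``n_users`` streams of
    ``per_user_rate_kbps`` KB/s each (1 KB/s = 8 kbit/s)."""
    if n_users < 0:
        raise ValueError("n_users must be >= 0")
    return n_users * per_user_rate_kbps * 8.0


@dataclass(frozen=True)
class LinkVerdict:
    feasible: bool
    margin_kbit: float


def link_feasible(link: NetworkLink, aggregate_rate_kbit: float) -> LinkVerdict:
    """Whether the shared link can carry ``aggregate_rate_kbit`` (kbit/s)."""
    capacity = link.data_rate_kbit
    return LinkVerdict(
        feasible=aggregate_rate_kbit <= capacity,
        margin_kbit=capacity - aggregate_rate_kbit,
    )


def calibrate_cost_model(
    pipeline_runner: Mapping[str, Callable[[], object]] | None = None,
    *,
    signal=None,
    repetitions: int = 5,
    reference_device: str = "host",
    clock: Callable[[], float] = time.perf_counter,
) -> CostModel:
    """Measure per-task wall time of the reference pipeline on this host.

    ``pipeline_runner`` maps task ids to zero-argument callables executing
    one stage on the sample signal (see
    :func:`bansim.ecg.make_calibration_runner`).  Each stage is timed
    ``repetitions`` times; the median is retained (robust to scheduler
    jitter) and normalized per second of signal, yielding a
    :class:`CostModel` whose reference device is the host.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if pipeline_runner is None:
        from .ecg import make_calibration_runner

        if signal is None:
            raise ValueError("either pipeline_runner or signal is required")
        pipeline_runner = make_calibration_runner(signal)
    duration = getattr(signal, "duration", None)
    costs: dict[str, float] = {}
    for task_id, stage in pipeline_runner.items():
        times = []
        for _ in range(repetitions):
            t0 = clock()
            stage()
            times.append(clock() - t0)
        cost = statistics.median(times)
        if duration:
            cost /= duration
        costs[task_id] = cost
    return CostModel(base_costs=costs, reference_device=reference_device)
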