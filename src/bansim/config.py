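"""Framework configuration: schema, loading, fixtures and report writers.

A single YAML document drives every simulator run: the task graph options,
the device profiles with their speedups and accelerators, the network
links, the per-task reference cost model, the monitoring contexts (A/B/C
presets) and the pipeline parameters.  Validation is strict — unknown keys
are rejected and every violation is reported with its field path.

The shipped fixture ``data/reference_costs.yaml`` encodes the case study's
measured setup: smartwatch base costs, the 3.93x tablet and 4.56x laptop
speedups, the laptop's DSP-accelerated wavelet stage, the WLAN link table,
the three monitoring contexts and the named distributed configurations.
"""

from __future__ import annotations

import csv
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .app_graph import ApplicationGraph, build_sd_graph
from .devices import CostModel, DeviceProfile, NetworkLink
from .scheduler import Assignment, LatencyReport, MonitoringContext

__all__ = [
    "FrameworkConfig",
    "ConfigError",
    "load_config",
    "reference_config_path",
    "load_reference_config",
    "write_report",
    "read_report",
]


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GraphOptions(_Strict):
    early_visualization_src: Optional[str] = None
    volume_overrides: list["FlowVolume"] = Field(default_factory=list)


class FlowVolume(_Strict):
    src: str
    dst: str
    volume: float = Field(ge=0)


class DeviceConfig(_Strict):
    device_id: str
    device_class: Literal["B", "M", "E"]
    speedup: float = Field(default=1.0, gt=0)
    accelerators: dict[str, float] = Field(default_factory=dict)
    can_compute: Optional[bool] = None
    per_user_instance: Optional[bool] = None

    @field_validator("accelerators")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for task, cost in v.items():
            if cost < 0:
                raise ValueError(f"negative accelerator cost for {task}")
        return v

    def to_profile(self) -> DeviceProfile:
        return DeviceProfile(
            device_id=self.device_id,
            device_class=self.device_class,
            speedup=self.speedup,
            accelerators=dict(self.accelerators),
            per_user_instance=self.per_user_instance,
            can_compute=self.can_compute,
        )


class LinkConfig(_Strict):
    technology: str
    data_rate: str
    range_m: float = Field(gt=0)
    shared: bool = True

    def to_link(self) -> NetworkLink:
        return NetworkLink(self.technology, self.data_rate, self.range_m, self.shared)


class CostModelConfig(_Strict):
    reference_device: str
    base_costs: dict[str, float]

    @field_validator("base_costs")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for task, cost in v.items():
            if cost < 0:
                raise ValueError(f"negative base cost for {task}")
        return v

    def to_model(self) -> CostModel:
        return CostModel(base_costs=dict(self.base_costs),
                         reference_device=self.reference_device)


class ContextConfig(_Strict):
    n_users: int = Field(ge=1)
    deadline: float = Field(gt=0)


class PipelineConfig(_Strict):
    low_cut: float = 0.5
    high_cut: float = 40.0
    notch_freq: float = 50.0
    refractory: float = 0.27
    wavelet: str = "db4"
    levels: int = 4
    hr_low: float = 40.0
    hr_high: float = 200.0
    lead: Optional[str] = None


class FrameworkConfig(_Strict):
    """The validated top-level configuration document."""

    acquisition_rate_kbps: float = Field(default=1.0, gt=0)
    #: enable the additive volume/bandwidth communication term (kbit/s)
    transmission_bandwidth_kbit: Optional[float] = Field(default=None, gt=0)
    graph: GraphOptions = Field(default_factory=GraphOptions)
    devices: list[DeviceConfig] = Field(default_factory=list)
    links: list[LinkConfig] = Field(default_factory=list)
    cost_model: Optional[CostModelConfig] = None
    contexts: dict[str, ContextConfig] = Field(default_factory=dict)
    assignments: dict[str, dict[str, str]] = Field(default_factory=dict)
    pipeline: PipelineConfig = Field(default_factory=PipelineConfig)

    # -- domain-object accessors -------------------------------------------

    def application_graph(self) -> ApplicationGraph:
        overrides = {(f.src, f.dst): f.volume for f in self.graph.volume_overrides}
        return build_sd_graph(
            acquisition_rate=self.acquisition_rate_kbps,
            volume_overrides=overrides,
            early_visualization_src=self.graph.early_visualization_src,
        )

    def device_profiles(self) -> dict[str, DeviceProfile]:
        return {d.device_id: d.to_profile() for d in self.devices}

    def network_links(self) -> list[NetworkLink]:
        return [l.to_link() for l in self.links]

    def reference_cost_model(self) -> CostModel:
        if self.cost_model is None:
            raise ConfigError("config carries no cost model")
        return self.cost_model.to_model()

    def context(self, label: str) -> MonitoringContext:
        if label not in self.contexts:
            raise ConfigError(f"unknown context {label!r}; have {sorted(self.contexts)}")
        c = self.contexts[label]
        return MonitoringContext(n_users=c.n_users, deadline=c.deadline, label=label)

    def assignment(self, name: str) -> Assignment:
        if name not in self.assignments:
            raise ConfigError(f"unknown assignment {name!r}; have {sorted(self.assignments)}")
        return Assignment(mapping=dict(self.assignments[name]), label=name)

    def config_hash(self) -> str:
        """Stable provenance hash of the validated document."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> FrameworkConfig:
    """Load and schema-validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    try:
        return FrameworkConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n" + "\n".join(lines)) from exc


def reference_config_path() -> Path:
    """Path of the shipped case-study fixture configuration."""
    return Path(str(resources.files("bansim").joinpath("data/reference_costs.yaml")))


def load_reference_config() -> FrameworkConfig:
    return load_config(reference_config_path())


# -- report writers ----------------------------------------------------------

def write_report(report: LatencyReport, path: str | Path, fmt: str = "json") -> Path:
    """Write a latency report as JSON, CSV, or an aligned text table.

    JSON round-trips losslessly via :func:`read_report`.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["task", "device", "latency_s"])
            for task, latency in report.per_task_latency.items():
                w.writerow([task, report.assignment.mapping.get(task, ""), f"{latency:.7f}"])
            w.writerow(["total", "", f"{report.total:.7f}"])
    elif fmt == "table":
        path.write_text(format_table(report))
    else:
        raise ConfigError(f"unknown report format {fmt!r} (json, csv, table)")
    return path


def format_table(report: LatencyReport) -> str:
    """Human-readable per-task table, 7-decimal display rounding."""
    ctx = report.context
    lines = [
        f"Context {ctx.label or '?'} — {ctx.n_users} user(s), deadline {ctx.deadline} s",
        f"Assignment: {report.assignment.label or 'custom'}",
        f"{'Task':<6}{'Device':<10}{'Latency (s)':>14}",
    ]
    for task, latency in report.per_task_latency.items():
        device = report.assignment.mapping.get(task, "")
        lines.append(f"{task:<6}{device:<10}{latency:>14.7f}")
    verdict = "feasible" if report.feasible else "INFEASIBLE"
    lines.append(f"{'Total':<16}{report.total:>14.7f}  [{verdict}]")
    return "\n".join(lines) + "\n"


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
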