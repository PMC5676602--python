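"""Assignment semantics, latency estimation and the optimality oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bansim.devices import CostModel, DeviceProfile
from bansim.scheduler import (Assignment, EnumerationSizeError,
                              InvalidAssignmentError, MonitoringContext,
                              best_assignment, deadline_from_max_hr,
                              enumerate_assignments, estimate_latency,
                              stage_latency)


# -- stage latency: parallel per-user BAN vs serialized shared device --------

def test_ban_stage_is_parallel_across_athletes(devices, cost_model):
    """Feature extraction on each athlete's own smartwatch costs one
    per-user unit regardless of squad size."""
    assert round(stage_latency("t5", devices["b2"], cost_model, 11), 7) == 0.18
    assert stage_latency("t5", devices["b2"], cost_model, 1) == stage_latency(
        "t5", devices["b2"], cost_model, 26
    )


def test_shared_device_serializes_athletes(devices, cost_model):
    assert round(stage_latency("t6", devices["m1"], cost_model, 11), 7) == 0.0625405
    one = stage_latency("t4", devices["m1"], cost_model, 1)
    from bansim.devices import task_cost

    assert one == task_cost(devices["m1"], "t4", cost_model)


def test_environmental_device_cannot_compute(devices, cost_model):
    with pytest.raises(InvalidAssignmentError):
        stage_latency("t4", devices["e1"], cost_model, 1)


# -- end-to-end estimation ----------------------------------------------------

def test_fig3c_context_b_meets_the_deadline(sd_graph, devices, cost_model, ref_config):
    report = estimate_latency(sd_graph, ref_config.assignment("fig3c"), devices,
                              cost_model, ref_config.context("B"))
    assert report.total == pytest.approx(0.2627457, abs=1e-6)
    assert report.feasible


def test_all_on_smartwatch_single_athlete_total(sd_graph, devices, cost_model, ref_config):
    report = estimate_latency(sd_graph, ref_config.assignment("all_b2"), devices,
                              cost_model, ref_config.context("A"))
    assert report.total == pytest.approx(0.2225492, abs=1e-6)


def test_zero_cost_chain_is_trivially_feasible(sd_graph, devices, ref_config):
    zero = CostModel(base_costs={t: 0.0 for t in sd_graph.compute_tasks()},
                     reference_device="b2")
    # strip the laptop's accelerator so every stage really costs nothing
    devs = dict(devices)
    devs["m2"] = DeviceProfile("m2", "M", speedup=4.56)
    report = estimate_latency(sd_graph, ref_config.assignment("fig3d"), devs,
                              zero, ref_config.context("C"))
    assert report.total == 0.0
    assert report.feasible


def test_backflow_to_ban_is_rejected(sd_graph, devices, cost_model, ref_config):
    backflow = Assignment(mapping={"t1": "b2", "t2": "m1", "t3": "b2", "t4": "m1",
                                   "t5": "m1", "t6": "m1"})
    with pytest.raises(InvalidAssignmentError, match="backflow"):
        estimate_latency(sd_graph, backflow, devices, cost_model, ref_config.context("A"))


def test_acquisition_must_stay_on_the_ban(sd_graph, devices, cost_model, ref_config):
    bad = Assignment(mapping={"t1": "m1", "t2": "m1", "t3": "m1", "t4": "m1",
                              "t5": "m1", "t6": "m1"})
    with pytest.raises(InvalidAssignmentError, match="B-class"):
        estimate_latency(sd_graph, bad, devices, cost_model, ref_config.context("A"))


def test_optional_transmission_term(sd_graph, devices, cost_model, ref_config):
    """Enabling the volume/bandwidth term adds one second's aggregate data
    transfer time for every device-crossing flow."""
    context = ref_config.context("B")
    assignment = ref_config.assignment("fig3c")
    plain = estimate_latency(sd_graph, assignment, devices, cost_model, context)
    with_comm = estimate_latency(sd_graph, assignment, devices, cost_model, context,
                                 transmission_bandwidth_kbit=100.0)
    # one crossing flow (t5 on the watch -> t6 on the tablet) at 1 KB/s/user:
    # 11 users x 8 kbit / 100 kbit/s
    assert with_comm.per_task_latency["transmission"] == pytest.approx(0.88)
    assert with_comm.total == pytest.approx(plain.total + 0.88)
    with pytest.raises(ValueError):
        estimate_latency(sd_graph, assignment, devices, cost_model, context,
                         transmission_bandwidth_kbit=-1.0)


# -- deadline ----------------------------------------------------------------

@pytest.mark.parametrize("max_hr,expected", [(220, 0.27), (60, 1.00), (120, 0.50)])
def test_deadline_truncates_beat_interval(max_hr, expected):
    assert deadline_from_max_hr(max_hr) == expected


def test_deadline_rejects_nonpositive_rate():
    with pytest.raises(ValueError):
        deadline_from_max_hr(0)


# -- enumeration and the brute-force oracle ----------------------------------

def _subset(devices, ids):
    return {d: devices[d] for d in ids}


def test_chain_enumeration_counts_cut_points(sd_graph, devices):
    """Two devices (one worn, one shared) admit exactly the 6 prefix/suffix
    cuts of the 5-stage chain, including all-worn and all-shared."""
    assignments = list(enumerate_assignments(sd_graph, _subset(devices, ["b2", "m1"])))
    assert len(assignments) == 6
    mappings = {tuple(a.mapping[t] for t in sd_graph.compute_tasks()) for a in assignments}
    assert ("b2",) * 5 in mappings and ("m1",) * 5 in mappings


def test_single_device_enumeration(sd_graph, devices):
    assignments = list(enumerate_assignments(sd_graph, _subset(devices, ["b2"])))
    assert len(assignments) == 1


def test_published_configurations_appear_in_enumeration(sd_graph, devices, ref_config):
    compute = sd_graph.compute_tasks()
    enumerated = {
        tuple(a.mapping[t] for t in compute)
        for a in enumerate_assignments(sd_graph, _subset(devices, ["b2", "m1", "m2"]))
    }
    for name in ("fig3b", "fig3c", "fig3d"):
        mapping = ref_config.assignment(name).mapping
        assert tuple(mapping[t] for t in compute) in enumerated


def test_enumeration_guard():
    from bansim.app_graph import ApplicationGraph, TaskSpec

    g = ApplicationGraph(tasks=[TaskSpec(f"t{i}", f"x{i}", "transform") for i in range(14)])
    with pytest.raises(EnumerationSizeError):
        list(enumerate_assignments(g, {"b2": DeviceProfile("b2", "B")}))


def _brute_force_min(graph, devices, cost_model, context):
    return min(
        estimate_latency(graph, a, devices, cost_model, context).total
        for a in enumerate_assignments(graph, devices)
    )


@pytest.mark.parametrize("device_ids", [
    ("b2",), ("b2", "m1"), ("b2", "m2"), ("b2", "m1", "m2"),
])
@pytest.mark.parametrize("n_users", [1, 11, 26])
def test_best_assignment_matches_brute_force(sd_graph, devices, cost_model,
                                             device_ids, n_users):
    context = MonitoringContext(n_users=n_users, deadline=0.27, label="X")
    devs = _subset(devices, device_ids)
    _, report = best_assignment(sd_graph, devs, cost_model, context)
    assert report.total == pytest.approx(
        _brute_force_min(sd_graph, devs, cost_model, context), abs=1e-12
    )


def test_tie_break_prefers_the_ban():
    """With an equally fast shared device and one user, every assignment
    ties; the winner keeps all stages on the worn device."""
    from bansim.app_graph import build_sd_graph

    graph = build_sd_graph()
    devs = {"b2": DeviceProfile("b2", "B"), "m1": DeviceProfile("m1", "M", speedup=1.0)}
    model = CostModel(base_costs={t: 0.01 for t in graph.compute_tasks()},
                      reference_device="b2")
    assignment, _ = best_assignment(graph, devs, model,
                                    MonitoringContext(n_users=1, deadline=10.0))
    assert all(assignment.mapping[t] == "b2" for t in graph.compute_tasks())


def test_infeasible_deadline_is_reported(sd_graph, devices, cost_model):
    context = MonitoringContext(n_users=26, deadline=1e-9, label="tiny")
    _, report = best_assignment(sd_graph, devices, cost_model, context)
    assert not report.feasible


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n_small=st.integers(1, 25))
def test_latency_is_monotone_in_squad_size(sd_graph, devices, cost_model, ref_config,
                                           n_small):
    """More athletes never reduce total latency, and worn-device stages
    contribute a constant."""
    assignment = ref_config.assignment("fig3b")
    small = estimate_latency(sd_graph, assignment, devices, cost_model,
                             MonitoringContext(n_users=n_small, deadline=0.27))
    big = estimate_latency(sd_graph, assignment, devices, cost_model,
                           MonitoringContext(n_users=n_small + 1, deadline=0.27))
    assert big.total >= small.total
    for task in ("t2", "t3"):  # worn-device stages
        assert big.per_task_latency[task] == small.per_task_latency[task]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(factor=st.floats(1.01, 10.0))
def test_faster_device_never_hurts(sd_graph, cost_model, factor):
    """Replacing the shared device with a strictly faster one (same
    accelerators) never increases the optimum."""
    base = {"b2": DeviceProfile("b2", "B"), "m1": DeviceProfile("m1", "M", speedup=3.93)}
    fast = {"b2": DeviceProfile("b2", "B"),
            "m1": DeviceProfile("m1", "M", speedup=3.93 * factor)}
    context = MonitoringContext(n_users=11, deadline=0.27)
    _, slow_best = best_assignment(sd_graph, base, cost_model, context)
    _, fast_best = best_assignment(sd_graph, fast, cost_model, context)
    assert fast_best.total <= slow_best.total + 1e-12
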