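"""Simulator service contract, reference LIF simulator and experiment lifecycle.

The simulator layer is an abstraction over numerical engines: a *simulator* is
any callable registered by id that takes neuron dynamics plus a time grid and
returns a membrane-potential trace.  The built-in reference engine integrates
the leaky integrate-and-fire (LIF) point neuron

    tau_m * dV/dt = -(V - V_rest) + R_m * I_ext

with classical fixed-step RK4 from ``V(0) = V_rest``.  When ``V`` reaches the
threshold ``V_thr`` after a step, a spike is recorded at that step's end time
and ``V`` is clamped at ``V_reset`` for the refractory period ``t_ref``.  For
constant drive and ``t_ref = 0``, the interspike interval has the closed form

    ISI = tau_m * ln( R_m I / (R_m I - (V_thr - V_rest)) )     (V_reset = V_rest)

which the test suite uses as an independent oracle.

Experiments follow a five-state lifecycle DESIGN → QUEUED → RUNNING →
{COMPLETED, ERROR}.  Runs are modelled in the asynchronous style: run-time
failures never raise — they land the experiment in ERROR with a message and
empty results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import BoundsError, IllegalStateError, NeurometaError
from .instancetree import (
    PARAMETER_CAPABILITY,
    STATE_VARIABLE_CAPABILITY,
    get_capability_view,
)
from .meta import TimeSeries

# lifecycle states
DESIGN = "DESIGN"
QUEUED = "QUEUED"
RUNNING = "RUNNING"
COMPLETED = "COMPLETED"
ERROR = "ERROR"

LEGAL_TRANSITIONS = {
    DESIGN: {QUEUED},
    QUEUED: {RUNNING},
    RUNNING: {COMPLETED, ERROR},
    COMPLETED: set(),
    ERROR: set(),
}


@dataclass
class NeuronDynamics:
    """LIF membrane parameters.

    v_rest, v_thr, v_reset in mV; r_m in MΩ; tau_m and t_ref in ms; i_ext in
    nA.  With these units R_m·I_ext is in mV and the equation needs no
    conversion factors.
    """

    v_rest: float = -65.0
    v_thr: float = -50.0
    v_reset: float = -65.0
    r_m: float = 10.0
    tau_m: float = 10.0
    i_ext: float = 0.0
    t_ref: float = 0.0

    def check(self):
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if not self.r_m > 0:
            raise ValueError(f"r_m must be > 0, got {self.r_m}")
        if not (self.v_reset <= self.v_rest < self.v_thr):
            raise ValueError(
                f"require v_reset <= v_rest < v_thr, got "
                f"{self.v_reset}, {self.v_rest}, {self.v_thr}")
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be >= 0, got {self.t_ref}")


@dataclass
class LifResult:
    trace: TimeSeries        # membrane potential, times in ms, values in mV
    spike_times: tuple       # ms


def simulate_lif(d: NeuronDynamics, duration: float, dt: float = 0.025) -> LifResult:
    """Integrate the LIF equation with fixed-step RK4.

    The trace has ``floor(duration/dt) + 1`` samples starting at t = 0.
    Threshold crossing is detected after each full RK4 step (no sub-step
    interpolation); the spike time is the step's end time, an O(dt) bias that
    keeps the integrator simple and fully deterministic.  During the
    refractory period the potential is held at ``v_reset``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    d.check()

    n_steps = int(math.floor(duration / dt))
    times = np.arange(n_steps + 1) * dt
    v = np.empty(n_steps + 1)
    v[0] = d.v_rest
    spikes: list = []

    drive = d.v_rest + d.r_m * d.i_ext  # asymptotic potential

    def f(vm: float) -> float:
        return (drive - vm) / d.tau_m

    refractory_until = -math.inf
    for i in range(n_steps):
        t_end = times[i + 1]
        if t_end <= refractory_until:
            v[i + 1] = d.v_reset
            continue
        vm = v[i]
        k1 = f(vm)
        k2 = f(vm + 0.5 * dt * k1)
        k3 = f(vm + 0.5 * dt * k2)
        k4 = f(vm + dt * k3)
        vm_next = vm + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if vm_next >= d.v_thr:
            spikes.append(float(t_end))
            vm_next = d.v_reset
            refractory_until = t_end + d.t_ref
        v[i + 1] = vm_next

    trace = TimeSeries(times=tuple(float(t) for t in times),
                       values=tuple(float(x) for x in v), unit="mV")
    return LifResult(trace=trace, spike_times=tuple(spikes))


def lif_isi_closed_form(d: NeuronDynamics) -> float:
    """Closed-form interspike interval for constant drive (requires v_reset = v_rest)."""
    ri = d.r_m * d.i_ext
    gap = d.v_thr - d.v_rest
    if ri <= gap:
        return math.inf  # subthreshold: never fires
    return d.tau_m * math.log(ri / (ri - gap)) + d.t_ref


def lif_subthreshold_closed_form(d: NeuronDynamics, times) -> np.ndarray:
    """Exact subthreshold solution V(t) = V_rest + R_m I (1 − e^(−t/τ))."""
    t = np.asarray(times, dtype=float)
    return d.v_rest + d.r_m * d.i_ext * (1.0 - np.exp(-t / d.tau_m))


#: Registered simulator engines: id -> callable(dynamics, duration, dt) -> LifResult.
SIMULATORS: dict = {
    "lif": simulate_lif,
}


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """A configured simulation run with a strict lifecycle.

    ``parameter_overrides`` maps parameter instance paths to values applied
    (bounds-checked) before the run; ``watched`` is the set of state-variable
    instance paths whose traces are recorded.  ``results`` is non-empty only in
    the COMPLETED state.
    """

    id: str
    name: str = ""
    state: str = DESIGN
    parameter_overrides: dict = field(default_factory=dict)
    watched: set = field(default_factory=set)
    duration: float = 100.0  # ms
    dt: float = 0.025        # ms
    simulator_id: str = "lif"
    results: dict = field(default_factory=dict)  # path -> TimeSeries
    error_message: Optional[str] = None

    def transition(self, new_state: str):
        if new_state not in LEGAL_TRANSITIONS.get(self.state, set()):
            raise IllegalStateError(
                f"experiment {self.id!r}: illegal transition "
                f"{self.state} -> {new_state}")
        self.state = new_state

    def copy_design(self, new_id: str, new_name: str) -> "Experiment":
        return Experiment(
            id=new_id, name=new_name, state=DESIGN,
            parameter_overrides=dict(self.parameter_overrides),
            watched=set(self.watched), duration=self.duration, dt=self.dt,
            simulator_id=self.simulator_id)


def _find_experiment(project, experiment_id: str) -> Experiment:
    for exp in project.experiments:
        if exp.id == experiment_id:
            return exp
    raise IllegalStateError(f"no experiment with id {experiment_id!r}")


def _cell_dynamics(tree, cell_instance) -> NeuronDynamics:
    """Assemble LIF parameters from a cell instance's parameter children."""
    kwargs = {}
    for child in cell_instance.children:
        if PARAMETER_CAPABILITY in child.capabilities and \
                child.name in NeuronDynamics.__dataclass_fields__:
            kwargs[child.name] = get_capability_view(
                child, PARAMETER_CAPABILITY).get_value()
    return NeuronDynamics(**kwargs)


def run_experiment(project, experiment_id: str,
                   simulator_id: Optional[str] = None) -> Experiment:
    """Execute an experiment against the project's instantiated model.

    Walks DESIGN → QUEUED → RUNNING, applies parameter overrides through the
    parameter capability, runs the registered simulator once per watched cell,
    attaches one trace per watched path and lands in COMPLETED.  Any failure
    (bad dt, unknown path, out-of-bounds override, unknown simulator) lands the
    experiment in ERROR with the message and empty results; nothing is raised
    for run-time failures.
    """
    exp = _find_experiment(project, experiment_id)
    if exp.state not in (DESIGN, QUEUED):
        raise IllegalStateError(
            f"experiment {exp.id!r} cannot run from state {exp.state}")
    if exp.state == DESIGN:
        exp.transition(QUEUED)
    exp.transition(RUNNING)

    try:
        if exp.dt <= 0:
            raise ValueError(f"dt must be > 0, got dt={exp.dt}")
        if exp.duration < 0:
            raise ValueError(f"duration must be >= 0, got {exp.duration}")
        sim_id = simulator_id or exp.simulator_id
        if sim_id not in SIMULATORS:
            raise NeurometaError(f"no simulator registered under id {sim_id!r}")
        engine = SIMULATORS[sim_id]
        tree = project.tree()

        for path, value in sorted(exp.parameter_overrides.items()):
            view = get_capability_view(tree.resolve(path), PARAMETER_CAPABILITY)
            view.set_value(value)

        results = {}
        for path in sorted(exp.watched):
            inst = tree.resolve(path)
            view = get_capability_view(inst, STATE_VARIABLE_CAPABILITY)
            cell = tree.resolve(path.rsplit(".", 1)[0]) if "." in path else None
            dynamics = _cell_dynamics(tree, cell) if cell is not None \
                else NeuronDynamics()
            out = engine(dynamics, exp.duration, exp.dt)
            results[path] = out.trace
            inst.values["time_series"] = out.trace
        exp.results = results
        exp.transition(COMPLETED)
    except Exception as exc:  # asynchronous-style contract: failures -> ERROR
        exp.results = {}
        exp.error_message = f"{type(exc).__name__}: {exc}"
        exp.transition(ERROR)
    return exp


def sweep(project, template_experiment: Experiment, parameter_path: str,
          values) -> list:
    """Create one DESIGN experiment per value, overriding one parameter (atomic).

    Every value is bounds-checked against the parameter's declared bounds
    before any experiment is created; a single out-of-bounds value rejects the
    whole sweep.  Names and ids are suffixed deterministically with the value's
    position.  The new experiments are appended to the project.
    """
    values = list(values)
    tree = project.tree()
    view = get_capability_view(tree.resolve(parameter_path), PARAMETER_CAPABILITY)
    bounds = view.get_bounds()
    if bounds is not None:
        lo, hi = bounds
        for v in values:
            if not (lo <= v <= hi):
                raise BoundsError(v, lo, hi, what=f"sweep value for {parameter_path!r}")
    created = []
    for i, v in enumerate(values):
        exp = template_experiment.copy_design(
            new_id=f"{template_experiment.id}_sweep{i}",
            new_name=f"{template_experiment.name or template_experiment.id} [{i}]")
        exp.parameter_overrides[parameter_path] = v
        created.append(exp)
    project.experiments.extend(created)
    return created


def watch_all(project, experiment_id: str, kind: str = "state_variable") -> Experiment:
    """Watch every instance carrying the given capability ('record all with one click')."""
    exp = _find_experiment(project, experiment_id)
    if exp.state != DESIGN:
        raise IllegalStateError(
            f"experiment {exp.id!r}: watched set is editable only in DESIGN "
            f"(state is {exp.state})")
    tree = project.tree()
    exp.watched |= {inst.path for inst in tree.instances_with_capability(kind)}
    return exp
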