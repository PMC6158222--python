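"""Reference LIF simulator and experiment lifecycle."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurometa import (
    Experiment,
    NeuronDynamics,
    lif_isi_closed_form,
    lif_subthreshold_closed_form,
    run_experiment,
    simulate_lif,
    sweep,
    watch_all,
)
from neurometa.errors import BoundsError, IllegalStateError
from neurometa.simulation import (
    COMPLETED,
    DESIGN,
    ERROR,
    LEGAL_TRANSITIONS,
    QUEUED,
    RUNNING,
)

SUB = NeuronDynamics(v_rest=-65, v_thr=-50, v_reset=-65, r_m=10, tau_m=10, i_ext=1)
SUPRA = NeuronDynamics(v_rest=-65, v_thr=-50, v_reset=-65, r_m=10, tau_m=10, i_ext=2)


class TestLif:
    def test_zero_drive_stays_at_rest(self):
        d = NeuronDynamics(i_ext=0.0)
        result = simulate_lif(d, duration=50, dt=0.1)
        assert set(result.trace.values) == {d.v_rest}
        assert result.spike_times == ()

    def test_subthreshold_matches_closed_form_charging_curve(self):
        result = simulate_lif(SUB, duration=100, dt=0.01)
        assert result.spike_times == ()
        assert result.trace.values[-1] == pytest.approx(-55.0, abs=1e-3)
        exact = lif_subthreshold_closed_form(SUB, result.trace.times)
        assert np.max(np.abs(np.array(result.trace.values) - exact)) < 1e-6

    def test_suprathreshold_spike_count_matches_isi_oracle(self):
        result = simulate_lif(SUPRA, duration=1000, dt=0.01)
        predicted = math.floor(1000 / lif_isi_closed_form(SUPRA))
        assert predicted == 72  # = floor(1000 / (10 ln 4))
        assert abs(len(result.spike_times) - predicted) <= 1

    def test_refractory_period_lengthens_the_interspike_interval(self):
        d = NeuronDynamics(v_rest=-65, v_thr=-50, v_reset=-65, r_m=10,
                           tau_m=10, i_ext=2, t_ref=5.0)
        result = simulate_lif(d, duration=1000, dt=0.01)
        predicted = math.floor(1000 / lif_isi_closed_form(d))
        assert abs(len(result.spike_times) - predicted) <= 1
        isis = np.diff(result.spike_times)
        assert np.all(isis >= 5.0)

    def test_rk4_convergence_is_fourth_order(self):
        errs = []
        for dt in (0.1, 0.05, 0.025):
            result = simulate_lif(SUB, duration=100, dt=dt)
            exact = lif_subthreshold_closed_form(SUB, result.trace.times)
            errs.append(np.max(np.abs(np.array(result.trace.values) - exact)))
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(o >= 3.5 for o in orders)

    def test_series_length_is_floor_duration_over_dt_plus_one(self):
        for duration, dt in [(10, 0.1), (1, 0.3), (0, 0.1), (7.5, 0.25)]:
            result = simulate_lif(SUB, duration=duration, dt=dt)
            assert len(result.trace) == math.floor(duration / dt) + 1
            assert result.trace.times[0] == 0.0

    @pytest.mark.parametrize("bad", [dict(dt=0), dict(dt=-1), dict(duration=-5)])
    def test_bad_arguments_rejected(self, bad):
        kwargs = {"duration": 10, "dt": 0.1, **bad}
        with pytest.raises(ValueError):
            simulate_lif(SUB, **kwargs)

    def test_spike_count_monotone_in_drive(self):
        counts = [len(simulate_lif(
            NeuronDynamics(v_rest=-65, v_thr=-50, v_reset=-65, r_m=10,
                           tau_m=10, i_ext=i), duration=500, dt=0.05).spike_times)
            for i in np.arange(1.6, 3.01, 0.2)]
        assert counts == sorted(counts)

    def test_invalid_dynamics_rejected(self):
        with pytest.raises(ValueError):
            simulate_lif(NeuronDynamics(tau_m=-1), duration=1, dt=0.1)
        with pytest.raises(ValueError):
            simulate_lif(NeuronDynamics(v_thr=-80), duration=1, dt=0.1)


class TestRunExperiment:
    def test_completed_run_records_one_series_per_watched_path(self, project):
        exp = project.experiment("exp0")
        exp.watched = {"net.pop0[0].v", "net.pop0[1].v"}
        exp.duration, exp.dt = 10.0, 0.1
        run_experiment(project, "exp0")
        assert exp.state == COMPLETED
        assert sorted(exp.results) == ["net.pop0[0].v", "net.pop0[1].v"]
        assert all(len(ts) == 101 for ts in exp.results.values())

    def test_zero_watched_variables_completes_with_empty_results(self, project):
        exp = project.experiment("exp0")
        exp.watched = set()
        run_experiment(project, "exp0")
        assert exp.state == COMPLETED and exp.results == {}

    def test_zero_dt_lands_in_error_mentioning_dt(self, project):
        exp = project.experiment("exp0")
        exp.dt = 0
        run_experiment(project, "exp0")
        assert exp.state == ERROR
        assert exp.results == {}
        assert "dt" in exp.error_message

    def test_out_of_bounds_override_lands_in_error(self, project):
        exp = project.experiment("exp0")
        exp.parameter_overrides["net.pop0[0].i_ext"] = 999.0
        run_experiment(project, "exp0")
        assert exp.state == ERROR and exp.results == {}

    def test_override_changes_the_recorded_trace(self, project):
        exp = project.experiment("exp0")
        exp.watched = {"net.pop0[0].v"}
        exp.duration, exp.dt = 100.0, 0.1
        exp.parameter_overrides["net.pop0[0].i_ext"] = 1.0  # subthreshold
        run_experiment(project, "exp0")
        trace = exp.results["net.pop0[0].v"]
        assert trace.values[-1] == pytest.approx(-55.0, abs=1e-3)

    def test_run_from_terminal_state_is_refused(self, project):
        exp = project.experiment("exp0")
        exp.watched = set()
        run_experiment(project, "exp0")
        with pytest.raises(IllegalStateError):
            run_experiment(project, "exp0")


class TestSweep:
    def test_three_values_create_three_design_experiments(self, project):
        template = project.experiment("exp0")
        created = sweep(project, template, "net.pop0[0].i_ext", [0.0, 1.0, 2.0])
        assert len(created) == 3
        assert all(e.state == DESIGN for e in created)
        assert [e.parameter_overrides["net.pop0[0].i_ext"] for e in created] == \
            [0.0, 1.0, 2.0]
        assert all(e in project.experiments for e in created)

    def test_empty_value_list_creates_nothing(self, project):
        assert sweep(project, project.experiment("exp0"),
                     "net.pop0[0].i_ext", []) == []

    def test_one_out_of_bounds_value_rejects_whole_sweep(self, project):
        n_before = len(project.experiments)
        with pytest.raises(BoundsError):
            sweep(project, project.experiment("exp0"),
                  "net.pop0[0].i_ext", [1.0, 99.0, 2.0])
        assert len(project.experiments) == n_before


class TestWatchAll:
    def test_watches_every_membrane_potential(self, project):
        exp = project.experiment("exp0")
        exp.watched = set()
        watch_all(project, "exp0")
        assert len(exp.watched) == 5  # populations of 2 and 3

    def test_set_semantics_no_duplicates(self, project):
        exp = project.experiment("exp0")
        watch_all(project, "exp0")
        once = set(exp.watched)
        watch_all(project, "exp0")
        assert exp.watched == once

    def test_refused_outside_design_state(self, project):
        exp = project.experiment("exp0")
        exp.transition(QUEUED)
        with pytest.raises(IllegalStateError):
            watch_all(project, "exp0")


STATES = [DESIGN, QUEUED, RUNNING, COMPLETED, ERROR]


class TestStateMachine:
    @given(st.lists(st.sampled_from(STATES), max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_no_sequence_of_requests_produces_an_illegal_transition(self, requests):
        exp = Experiment(id="e")
        for target in requests:
            before = exp.state
            try:
                exp.transition(target)
            except IllegalStateError:
                assert exp.state == before  # refused cleanly
            else:
                assert target in LEGAL_TRANSITIONS[before]

    def test_randomized_run_failures_always_land_in_error_with_empty_results(
            self, project):
        rng = random.Random(0)
        for _ in range(20):
            exp = Experiment(id=f"x{rng.random()}", watched={"net.pop0[0].v"},
                             duration=1.0, dt=0.1)
            project.experiments.append(exp)
            kind = rng.choice(["bad_dt", "bad_path", "bad_sim"])
            if kind == "bad_dt":
                exp.dt = rng.choice([0, -0.1])
            elif kind == "bad_path":
                exp.watched = {"net.ghost[0].v"}
            else:
                exp.simulator_id = "missing_engine"
            run_experiment(project, exp.id)
            assert exp.state == ERROR
            assert exp.results == {} and exp.error_message
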