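import io

import numpy as np
import pytest

from cellrear.ode_builder import CompiledModel, ElementaryReaction, RateParameter, compile_model
from cellrear.simulator import (
    Event,
    SimulationSettings,
    Trajectory,
    observable,
    simulate,
    steady_state,
)
from cellrear.wiring import StateAssignment


def single_species_model(k_turn=0.01):
    """One species, pure first-order turnover: closed-form exponential decay."""
    return CompiledModel(
        pools=("X_a", "X_i"),
        reactions=(
            ElementaryReaction("turnover_X", (("X_a", 1),), (("X_i", 1),), "kturn_X", "turnover"),
        ),
        parameters={"kturn_X": RateParameter("kturn_X", k_turn, "turnover")},
        observables={"X": "X_a"},
    )


def scaled_model(model, factor):
    params = {
        name: RateParameter(name, p.value * factor, p.rate_class, p.is_reverse, p.paired_forward)
        for name, p in model.parameters.items()
    }
    return CompiledModel(
        model.pools, model.reactions, params, model.observables,
        model.clamped_species, model.diagram,
    )


class TestClosedFormDecay:
    def test_exponential_decay_matches_closed_form(self):
        m = single_species_model(0.01)
        ics = StateAssignment({"X": 100.0}, {"X": 0.0})
        traj = simulate(
            m, ics,
            settings=SimulationSettings(1000.0, 25.0, rtol=1e-12, atol=1e-14),
        )
        expected = 100.0 * np.exp(-0.01 * traj.times)
        np.testing.assert_allclose(
            observable(traj, "X").values, expected, rtol=1e-8, atol=1e-10
        )
        assert observable(traj, "X").final() == pytest.approx(100 * np.exp(-10), rel=1e-8)


class TestGridAndEvents:
    def test_default_grid_has_401_points(self, model, ics):
        traj = simulate(model, ics)
        assert len(traj.times) == 401
        assert traj.times[0] == 0.0 and traj.times[-1] == 10000.0
        assert traj.times[1] - traj.times[0] == 25.0

    def test_interval_must_divide_t_end(self):
        with pytest.raises(ValueError, match="divide"):
            SimulationSettings(t_end=10000.0, output_interval=33.0)

    def test_event_outside_horizon_rejected(self, model, ics):
        with pytest.raises(ValueError, match="event time"):
            simulate(model, ics, [Event(20000.0, "set_parameter", "kturn_Src", 0.1)])

    def test_event_with_unknown_parameter_rejected(self, model, ics):
        with pytest.raises(KeyError, match="unknown parameter"):
            simulate(model, ics, [Event(100.0, "set_parameter", "nope", 0.1)])

    def test_species_event_moves_pool_and_conserves(self, model, ics):
        traj = simulate(
            model, ics,
            [Event(4000.0, "set_species", "PolarizedSubstrateStiffness", 0.0)],
        )
        series = observable(traj, "PolarizedSubstrateStiffness")
        assert series.at(3975.0) == pytest.approx(100.0)
        assert series.at(4000.0) == 0.0
        assert series.at(10000.0) == 0.0
        assert traj.conservation_error() < 1e-9

    def test_parameter_event_takes_effect(self, model, ics):
        # raising tension-node turnover 1000-fold collapses its active pool
        traj = simulate(
            model, ics, [Event(4000.0, "set_parameter", "kturn_MembraneTension", 10.0)]
        )
        mt = observable(traj, "MembraneTension")
        assert mt.at(4000.0 - 25) > 10.0
        assert mt.at(4100.0) < 0.5

    def test_halving_output_interval_keeps_shared_grid_values(self, model, ics):
        coarse = simulate(model, ics, settings=SimulationSettings(2000.0, 50.0))
        fine = simulate(model, ics, settings=SimulationSettings(2000.0, 25.0))
        np.testing.assert_allclose(coarse.states, fine.states[::2], atol=1e-5, rtol=1e-7)


class TestInvariants:
    def test_conservation_on_canonical_run(self, scenarios):
        assert scenarios["unperturbed"].trajectory.conservation_error() < 1e-6

    def test_bounds_zero_to_hundred_per_observable(self, scenarios):
        traj = scenarios["unperturbed"].trajectory
        for sp in traj.model.observables:
            values = observable(traj, sp).values
            assert values.min() >= -1e-7
            assert values.max() <= 100.0 + 1e-7

    def test_time_rescaling_invariance(self, model, ics):
        base = simulate(model, ics, settings=SimulationSettings(10000.0, 250.0))
        fast = simulate(scaled_model(model, 10.0), ics, settings=SimulationSettings(1000.0, 25.0))
        np.testing.assert_allclose(base.states, fast.states, atol=1e-6, rtol=1e-8)

    def test_agreement_with_fixed_step_rk4(self, model, ics):
        settings = SimulationSettings(t_end=200.0, output_interval=25.0)
        traj = simulate(model, ics, settings=settings)
        k = model.rate_vector()
        y = model.initial_vector(ics)
        h = 0.005
        out = [y.copy()]
        t = 0.0
        for step in range(int(200.0 / h)):
            k1 = model.derivative(t, y, k)
            k2 = model.derivative(t + h / 2, y + h / 2 * k1, k)
            k3 = model.derivative(t + h / 2, y + h / 2 * k2, k)
            k4 = model.derivative(t + h, y + h * k3, k)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if abs(t / 25.0 - round(t / 25.0)) < 1e-9:
                out.append(y.copy())
        np.testing.assert_allclose(traj.states, np.array(out), atol=1e-3)


class TestSteadyState:
    def test_constant_trajectory_converges(self):
        times = np.arange(0.0, 5001.0, 25.0)
        states = np.full((len(times), 1), 42.0)
        traj = Trajectory(times, states, ("X_a",), SimulationSettings(5000.0, 25.0))
        report = steady_state(traj)
        assert report.converged
        assert report.final_state[0] == 42.0

    def test_decay_past_ten_half_lives_converges_near_zero(self):
        m = single_species_model(0.01)
        ics = StateAssignment({"X": 100.0}, {"X": 0.0})
        traj = simulate(m, ics, settings=SimulationSettings(10000.0, 25.0))
        report = steady_state(traj, window=1000.0, rel_tol=0.01)
        assert report.converged
        assert report.final_state[0] == pytest.approx(0.0, abs=1e-10)

    def test_sinusoid_does_not_converge(self):
        times = np.arange(0.0, 5001.0, 25.0)
        states = 50 + 10 * np.sin(times / 200.0)[:, None]
        traj = Trajectory(times, states, ("X_a",), SimulationSettings(5000.0, 25.0))
        assert not steady_state(traj).converged

    def test_window_larger_than_span_rejected(self):
        times = np.arange(0.0, 101.0, 25.0)
        traj = Trajectory(times, np.zeros((len(times), 1)), ("X_a",), SimulationSettings(100.0, 25.0))
        with pytest.raises(ValueError, match="window"):
            steady_state(traj, window=500.0)


class TestObservableAndCsv:
    def test_unknown_species_rejected(self, scenarios):
        with pytest.raises(KeyError):
            observable(scenarios["unperturbed"].trajectory, "NotASpecies")

    def test_unperturbed_retraction_rises_to_plateau(self, scenarios):
        rr = observable(scenarios["unperturbed"].trajectory, "RearRetraction").values
        drops = np.diff(rr).min()
        assert drops > -1e-6          # non-decreasing up to solver tolerance
        assert rr[-1] == pytest.approx(rr[-40], rel=0.01)   # flat tail

    def test_csv_round_trip_is_lossless(self, model, ics, tmp_path):
        traj = simulate(model, ics, settings=SimulationSettings(500.0, 25.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert back.pools == traj.pools
        np.testing.assert_allclose(back.states, traj.states, rtol=0, atol=0)

    def test_csv_header_names_time_first(self, model, ics):
        traj = simulate(model, ics, settings=SimulationSettings(100.0, 50.0))
        text = traj.to_csv()
        header = text.splitlines()[0].split(",")
        assert header[0] == "time_s"
        assert set(header[1:]) == set(model.pools)
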