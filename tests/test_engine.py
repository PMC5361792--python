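"""Integration engine and trajectory analytics."""

import dataclasses

import numpy as np
import pytest

import chemoresist as cr
from conftest import make_single_population_spec


def logistic(t, r, K, x0):
    e = np.exp(r * t)
    return K * x0 * e / (K + x0 * (e - 1.0))


def make_trajectory(times, **populations):
    """Synthetic trajectory from per-population arrays (missing ones are 0)."""
    times = np.asarray(times, float)
    cols = [np.asarray(populations.get(p, np.zeros_like(times)), float) for p in cr.POPULATIONS]
    return cr.Trajectory(times=times, values=np.column_stack(cols))


class TestIntegrate:
    def test_all_rates_zero_gives_constant_trajectory(self):
        spec = cr.ScenarioSpec(
            name="frozen", model="extended",
            params=cr.ModelParams(r_N=0, r_T=0, r_R=0, r_M=0, kappa=0),
            drug1=cr.DrugSchedule(C0=0.0),
            initial_state=cr.PopulationState(N=5.0, T=3.0, T_R=2.0, T_M=1.0),
            horizon=100.0,
        )
        traj = cr.integrate(spec)
        for label, value in (("N", 5.0), ("T", 3.0), ("T_R", 2.0), ("T_M", 1.0)):
            assert np.allclose(traj.population(label), value, rtol=1e-9, atol=1e-9)

    def test_matches_logistic_closed_form(self):
        spec = make_single_population_spec(r=0.25, K=1e6, T0=1e4, C0=0.0)
        traj = cr.integrate(spec)
        expected = logistic(traj.times, 0.25, 1e6, 1e4)
        assert np.allclose(traj.population("T"), expected, rtol=1e-6, atol=0.0)

    def test_normal_cells_follow_logistic_without_coupling(self):
        spec = cr.ScenarioSpec(
            name="normal-only", model="intrinsic",
            params=cr.ModelParams(r_N=0.5, K_N=1e6, kappa=0.0),
            drug1=cr.DrugSchedule(C0=0.0),
            initial_state=cr.PopulationState(N=1e4, T=0.0),
            horizon=100.0,
        )
        traj = cr.integrate(spec)
        expected = logistic(traj.times, 0.5, 1e6, 1e4)
        assert np.allclose(traj.population("N"), expected, rtol=1e-6, atol=0.0)

    def test_grid_spacing_and_horizon(self):
        spec = make_single_population_spec(horizon=500.0)
        traj = cr.integrate(spec)
        assert traj.times.size == 1001
        assert traj.times[0] == 0.0
        assert traj.times[-1] == 500.0
        assert np.allclose(np.diff(traj.times), 0.5)

    def test_extended_run_reduces_to_intrinsic_run(self):
        """A full extended-model run with the mutated pathway switched off
        reproduces the intrinsic-model run at every grid point."""
        tau = 1e-3
        params = cr.ModelParams(tau=tau, tau1=tau, tau2=0.0, tau_MR=0.0)
        drug = cr.DrugSchedule(C0=0.2, t_start=50.0, kill_T=0.15, kill_N=0.15, kill_TM=0.15)
        common = dict(params=params, drug1=drug,
                      initial_state=cr.PopulationState(N=1e6, T=1e4), horizon=500.0)
        traj_int = cr.integrate(cr.ScenarioSpec(name="i", model="intrinsic", **common))
        traj_ext = cr.integrate(cr.ScenarioSpec(name="e", model="extended", **common))
        for label in ("T", "T_R", "N"):
            assert np.allclose(traj_ext.population(label), traj_int.population(label),
                               rtol=1e-6, atol=0.5)
        assert np.all(traj_ext.population("T_M") == 0.0)

    def test_monotone_dose_response(self):
        """For the wild-tumor-only subsystem the trajectory is pointwise
        non-increasing in the drug concentration."""
        doses = [0.0, 0.1, 0.2, 0.4]
        runs = [cr.integrate(make_single_population_spec(C0=c)).population("T") for c in doses]
        for lower, higher in zip(runs, runs[1:]):
            assert np.all(higher <= lower * (1 + 1e-9) + 1e-9)

    def test_nonnegative_after_clamping(self, scenario_results):
        for result in scenario_results.values():
            traj = result.trajectory
            assert traj.values.min() >= 0.0
            assert min(traj.meta["min_before_clamp"].values()) >= -1e-6

    def test_event_times_stable_under_tolerance_halving(self):
        spec = cr.preset("a")
        t1 = cr.first_crossing_time(cr.integrate(spec), "T_R", spec.detection_threshold)
        t2 = cr.first_crossing_time(
            cr.integrate(spec, rtol=cr.RTOL / 2, atol=cr.ATOL / 2), "T_R",
            spec.detection_threshold)
        assert abs(t1 - t2) < 0.5

    def test_unknown_model_rejected(self):
        spec = make_single_population_spec()
        with pytest.raises(ValueError, match="model"):
            cr.integrate(spec, model="gompertz")

    def test_intrinsic_rejects_initial_mutated_cells(self):
        spec = make_single_population_spec()
        spec = dataclasses.replace(
            spec, initial_state=cr.PopulationState(N=0.0, T=1e4, T_M=10.0))
        with pytest.raises(ValueError, match="T_M"):
            cr.integrate(spec)


class TestFirstCrossing:
    def test_linear_ramp_midpoint(self):
        times = np.linspace(0, 100, 11)
        traj = make_trajectory(times, T_R=4e5 * times / 100.0)
        assert cr.first_crossing_time(traj, "T_R", 2e5) == pytest.approx(50.0)

    def test_never_reached_is_absent(self):
        traj = make_trajectory([0.0, 1.0, 2.0], T=[1.0, 2.0, 3.0])
        assert cr.first_crossing_time(traj, "T", 10.0) is None

    def test_already_above_at_start(self):
        traj = make_trajectory([0.0, 1.0], T=[5.0, 6.0])
        assert cr.first_crossing_time(traj, "T", 2.0) == 0.0

    def test_unknown_population_rejected(self):
        traj = make_trajectory([0.0, 1.0], T=[0.0, 1.0])
        with pytest.raises(KeyError):
            cr.first_crossing_time(traj, "X", 1.0)

    def test_nonpositive_threshold_rejected(self):
        traj = make_trajectory([0.0, 1.0], T=[0.0, 1.0])
        with pytest.raises(ValueError):
            cr.first_crossing_time(traj, "T", 0.0)


class TestExtinction:
    def test_monotone_decay_crossing(self):
        # linear decay from 20 to 0 over [0, 100] crosses eps = 4 at t = 80
        times = np.linspace(0, 100, 26)
        traj = make_trajectory(times, T=20.0 * (1 - times / 100.0))
        assert cr.extinction_time(traj, "T", eps=4.0) == pytest.approx(80.0)

    def test_population_above_eps_at_horizon_is_absent(self):
        traj = make_trajectory([0.0, 1.0, 2.0], T=[5.0, 5.0, 5.0])
        assert cr.extinction_time(traj, "T", eps=1.0) is None

    def test_rebound_above_eps_is_absent(self):
        traj = make_trajectory([0.0, 1.0, 2.0], T=[5.0, 0.1, 5.0])
        assert cr.extinction_time(traj, "T", eps=1.0) is None

    def test_never_populated_extinct_from_start(self):
        traj = make_trajectory([0.0, 1.0, 2.0])
        assert cr.extinction_time(traj, "T", eps=1.0) == 0.0


class TestDominance:
    def test_largest_tumor_population_wins(self):
        traj = make_trajectory([0.0], T=[5.0], T_R=[3.0], T_M=[1.0], N=[100.0])
        assert cr.dominant_population(traj, 0.0) == "T"

    def test_normal_cells_are_excluded(self):
        traj = make_trajectory([0.0], T=[1.0], N=[100.0])
        assert cr.dominant_population(traj, 0.0) == "T"

    def test_tie_broken_in_fixed_order(self):
        traj = make_trajectory([0.0], T=[5.0], T_M=[5.0], T_R=[5.0])
        assert cr.dominant_population(traj, 0.0) == "T"
        traj = make_trajectory([0.0], T_M=[5.0], T_R=[5.0])
        assert cr.dominant_population(traj, 0.0) == "T_M"

    def test_empty_tumor_has_no_dominant(self):
        traj = make_trajectory([0.0], N=[100.0])
        assert cr.dominant_population(traj, 0.0) is None

    def test_time_outside_horizon_rejected(self):
        traj = make_trajectory([0.0, 1.0], T=[1.0, 2.0])
        with pytest.raises(ValueError):
            cr.dominant_population(traj, 5.0)


class TestAnalyze:
    def test_zero_trajectory_report(self):
        traj = make_trajectory(np.linspace(0, 10, 5))
        report = cr.analyze(traj, threshold=1.0, eps=1.0)
        assert all(v is None for v in report.detection_times.values())
        assert all(v == 0.0 for v in report.extinction_times.values())
        assert report.dominant is None
        assert report.final_state == cr.PopulationState(0.0, 0.0, 0.0, 0.0)

    def test_report_consistent_with_underlying_operations(self, scenario_results):
        result = scenario_results["a"]
        traj, spec = result.trajectory, result.spec
        assert result.report.detection_times["T_R"] == cr.first_crossing_time(
            traj, "T_R", spec.detection_threshold)
        assert result.report.dominant == cr.dominant_population(traj, spec.horizon)
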