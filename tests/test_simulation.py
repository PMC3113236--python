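import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvremodel import (
    InterventionSpec,
    ModelParameters,
    ModelState,
    ScenarioSpec,
    StimulusProfile,
    Trajectory,
    calibrate_baseline_activation,
    complex_equilibrium,
    initial_state,
    normalize_to_baseline,
    peak_metrics,
    simulate,
)
from lvremodel.core import ModelOptions
from lvremodel.simulation import (
    FAST_SOLVER,
    STATE_SCALE,
    SolverSettings,
    baseline_residual,
    homeostatic_offsets,
)

P = ModelParameters()


class TestInitialState:
    def test_printed_normal_lv_state(self, params):
        s = initial_state(params)
        assert (s.M_phi, s.F, s.T_beta, s.M9A, s.C, s.CM9, s.CID) == (
            5.0, 20.0, 0.21, 7.1, 839.5, 447.6, 0.0
        )

    def test_round_trip_through_array(self):
        s = initial_state()
        assert ModelState.from_array(s.as_array()) == s


class TestComplexEquilibrium:
    def test_reproduces_published_normal_lv_complex(self, params):
        # hand oracle: 3e-4 * 839.5 * 7.1 / 0.004 = 447.03...
        value = complex_equilibrium(839.5, 7.1, params)
        assert value == pytest.approx(3e-4 * 839.5 * 7.1 / 0.004, rel=1e-12)
        assert value == pytest.approx(447.6, rel=0.01)

    def test_zero_collagen_gives_zero_complex(self, params):
        assert complex_equilibrium(0.0, 7.1, params) == 0.0

    def test_linearity_in_enzyme(self, params):
        assert complex_equilibrium(839.5, 14.2, params) == pytest.approx(
            2 * complex_equilibrium(839.5, 7.1, params)
        )

    def test_alternative_loss_variant_is_smaller(self, params):
        both = complex_equilibrium(
            839.5, 7.1, params, ModelOptions(complex_loss="koff+konc")
        )
        assert both == pytest.approx(3e-4 * 839.5 * 7.1 / (4e-4 + 0.004), rel=1e-12)
        assert both < complex_equilibrium(839.5, 7.1, params)


class TestBaselineActivation:
    def test_closed_form_for_printed_baseline(self, params):
        # 15*0.21 - 0.07*5 - 0.004*20 = 2.72
        assert calibrate_baseline_activation(params, 0.21) == pytest.approx(2.72)

    def test_zero_activation_target(self, params):
        target = (0.07 * 5 + 0.004 * 20) / 15  # cell production alone
        assert calibrate_baseline_activation(params, target) == pytest.approx(0.0, abs=1e-12)

    def test_unreachably_low_target_rejected(self, params):
        with pytest.raises(ValueError):
            calibrate_baseline_activation(params, 1e-6)
        with pytest.raises(ValueError):
            calibrate_baseline_activation(params, 0.0)


class TestSimulate:
    def test_trajectory_grid_contract(self, median_trajectory):
        t = median_trajectory.t
        assert t[0] == 0.0 and t[-1] == 30.0
        assert np.allclose(np.diff(t), 0.01)
        np.testing.assert_array_equal(
            median_trajectory.y[0], initial_state().as_array()
        )

    def test_deterministic_bit_identical(self, params, curves):
        sc = ScenarioSpec("d", StimulusProfile(amplitude=30.0))
        a = simulate(sc, params, curves, solver=FAST_SOLVER)
        b = simulate(sc, params, curves, solver=FAST_SOLVER)
        np.testing.assert_array_equal(a.y, b.y)

    def test_all_components_non_negative(self, median_trajectory):
        assert median_trajectory.y.min() >= 0.0

    def test_cid_monotone_non_decreasing_without_clearance(self, median_trajectory):
        cid = median_trajectory.component("CID")
        assert np.all(np.diff(cid) >= -1e-9)

    def test_peak_metrics_stable_under_tighter_tolerances(self, params, curves,
                                                          median_trajectory):
        tight = SolverSettings(rtol=0.5e-8, atol_scale=0.5e-10)
        sc = ScenarioSpec("median", StimulusProfile(amplitude=30.0, peak_day=2.0))
        traj = simulate(sc, params, curves, solver=tight)
        for comp in ("M_phi", "M9A"):
            d0, v0 = peak_metrics(median_trajectory, comp)
            d1, v1 = peak_metrics(traj, comp)
            assert v1 == pytest.approx(v0, rel=1e-3)
            assert d1 == pytest.approx(d0, abs=0.01)

    def test_clamp_holds_mmp9_from_onset(self, params, curves):
        sc = ScenarioSpec(
            "clamp", StimulusProfile(amplitude=30.0),
            InterventionSpec("clamp", 200.0, 7.0),
        )
        traj = simulate(sc, params, curves, solver=FAST_SOLVER)
        m9a = traj.component("M9A")
        after = traj.t >= 7.0
        assert np.all(m9a[after] == 200.0)
        assert np.all(m9a[~after] < 200.0)

    @settings(max_examples=15, deadline=None)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 5), st.floats(0, 250), st.floats(0, 600),
    )
    def test_non_negativity_from_arbitrary_starts(self, params, curves,
                                                  m_frac, f_frac, c_frac,
                                                  tb, m9a, cm9):
        """No component escapes below -1e-9 of its scale from any
        non-negative start within the tissue's packing capacity (initial
        crowding <= 1).  Within that domain every positive flux is gated
        by the crowding limiter, so occupancy cannot cross 1 and collagen
        production never turns negative; over-packed starts lie outside
        the model's domain and are signalled by simulate."""
        capacity = 1.0 - 0.73  # day-0 structural occupancy
        m = m_frac * capacity * params.rho_Mphi
        capacity -= m / params.rho_Mphi
        f = f_frac * capacity * params.rho_F
        capacity -= f / params.rho_F
        c = c_frac * capacity * params.rho_C
        sc = ScenarioSpec(
            "h", StimulusProfile(amplitude=30.0),
            initial=ModelState(m, f, tb, m9a, c, cm9, 0.0),
        )
        traj = simulate(sc, params, curves, solver=FAST_SOLVER)
        assert traj.y.min() >= 0.0  # simulate enforces the -1e-9*scale contract


class TestBalancedBaseline:
    def test_printed_state_is_not_a_fixed_point_of_bare_equations(self, params, curves):
        res = baseline_residual(params, curves)
        assert np.abs(res / STATE_SCALE).max() > 0.01

    def test_offsets_zero_the_physical_residual(self, params, curves):
        p = params.replace(u_T0=calibrate_baseline_activation(params, 0.21))
        off = homeostatic_offsets(p, curves)
        assert np.allclose((baseline_residual(p, curves) + off)[:6], 0.0, atol=1e-12)
        assert off[6] == 0.0  # CID left as an accumulator

    def test_zero_stimulus_persistence_within_one_percent(self, params, curves):
        p = params.replace(u_T0=calibrate_baseline_activation(params, 0.21))
        sc = ScenarioSpec("healthy", StimulusProfile(amplitude=0.0),
                          baseline_mode="balanced")
        traj = simulate(sc, p, curves)
        y0 = traj.y[0, :6]
        drift = np.abs(traj.y[:, :6] - y0).max(axis=0) / y0
        assert drift.max() < 0.01


class TestPeakMetrics:
    def test_constant_series_ties_break_to_earliest_time(self):
        traj = Trajectory(t=np.linspace(0, 1, 11), y=np.ones((11, 7)))
        day, value = peak_metrics(traj, "C")
        assert (day, value) == (0.0, 1.0)

    def test_quadratic_refinement_recovers_off_grid_peak(self):
        t = np.linspace(0, 10, 101)
        y = np.zeros((101, 7))
        y[:, 4] = -((t - 4.037) ** 2)  # parabola peaking between grid points
        y[:, 4] -= y[:, 4].min()
        day, _ = peak_metrics(Trajectory(t=t, y=y), "C")
        assert day == pytest.approx(4.037, abs=1e-6)

    def test_unknown_component_rejected(self, median_trajectory):
        with pytest.raises(KeyError):
            peak_metrics(median_trajectory, "TIMP1")


class TestNormalization:
    def test_all_ones_at_time_zero(self, median_trajectory):
        fold = normalize_to_baseline(median_trajectory)
        np.testing.assert_allclose(fold.y[0, :6], 1.0)

    def test_fold_change_scales_linearly(self):
        y = np.tile(initial_state().as_array(), (3, 1))
        y[2, 0] = 50.0  # macrophages 5 -> 50
        fold = normalize_to_baseline(Trajectory(t=np.array([0.0, 1.0, 2.0]), y=y))
        assert fold.component("M_phi")[2] == pytest.approx(10.0)

    def test_denormalization_recovers_original(self, median_trajectory):
        fold = normalize_to_baseline(median_trajectory)
        baseline = np.array([
            fold.provenance["normalized_to_baseline"][k]
            for k in ("M_phi", "F", "T_beta", "M9A", "C", "CM9")
        ])
        recovered = fold.y[:, :6] * baseline
        np.testing.assert_allclose(recovered, median_trajectory.y[:, :6], rtol=1e-12)

    def test_cid_reported_absolute(self, median_trajectory):
        fold = normalize_to_baseline(median_trajectory)
        np.testing.assert_array_equal(
            fold.component("CID"), median_trajectory.component("CID")
        )

    def test_zero_baseline_component_rejected(self):
        y = np.tile(initial_state().as_array(), (2, 1))
        y[:, 3] = 0.0  # MMP-9 baseline zero
        with pytest.raises(ValueError, match="zero baseline"):
            normalize_to_baseline(Trajectory(t=np.array([0.0, 1.0]), y=y))


class TestTrajectoryIO:
    def test_csv_round_trip(self, median_trajectory, tmp_path):
        path = tmp_path / "traj.csv"
        median_trajectory.to_csv(path)
        loaded = Trajectory.from_csv(path)
        np.testing.assert_allclose(loaded.y, median_trajectory.y, rtol=1e-12)

    def test_schema_has_time_and_all_components(self, median_trajectory):
        frame = median_trajectory.to_frame()
        assert list(frame.columns) == [
            "time_day", "M_phi", "F", "T_beta", "M9A", "C", "CM9", "CID"
        ]
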