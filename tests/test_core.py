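import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvremodel import (
    InterventionSpec,
    ModelParameters,
    ModelState,
    StimulusProfile,
    crowding_fraction,
    initial_state,
    myocyte_crowding,
    rhs,
    tgf_activation_input,
    timp_inhibition,
)
from lvremodel.core import ModelOptions
from lvremodel.simulation import calibrate_baseline_activation

P = ModelParameters()


class TestMyocyteCrowding:
    def test_day_zero_is_total_structural_fraction(self):
        assert myocyte_crowding(0.0, P) == pytest.approx(0.73)

    def test_long_time_limit_is_vascular_floor(self):
        assert myocyte_crowding(1e6, P) == pytest.approx(0.17)

    def test_myocyte_half_life(self):
        # at t = ln2/d_mc the myocyte term has halved: 0.17 + 0.28
        assert myocyte_crowding(math.log(2) / P.d_mc, P) == pytest.approx(0.45)

    def test_monotone_non_increasing_and_bounded(self):
        t = np.linspace(0, 60, 500)
        k = myocyte_crowding(t, P)
        assert np.all(np.diff(k) <= 0)
        assert np.all((k >= P.frac_endo_smc) & (k <= 0.73 + 1e-12))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            myocyte_crowding(-0.1, P)


class TestCrowdingFraction:
    def test_baseline_state_is_fully_packed(self):
        # 0.73 + 5/2500 + 20/1250 + 839.5/3300
        value = crowding_fraction(initial_state(), 0.0, P)
        assert value == pytest.approx(0.73 + 5 / 2500 + 20 / 1250 + 839.5 / 3300)
        assert 0.99 <= value <= 1.01

    def test_empty_tissue_late_leaves_only_vascular_floor(self):
        empty = ModelState(0, 0, 0, 0, 0, 0, 0)
        assert crowding_fraction(empty, 1e6, P) == pytest.approx(0.17)

    def test_saturated_tissue_late(self):
        full = ModelState(P.rho_Mphi, P.rho_F, 0, 0, P.rho_C, 0, 0)
        assert crowding_fraction(full, 1e6, P) == pytest.approx(3.17)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 2500), st.floats(0, 1250), st.floats(0, 3300),
        st.floats(0.1, 100, allow_nan=False),
    )
    def test_limiter_strictly_decreases_in_each_density(self, m, f, c, bump):
        base = ModelState(m, f, 0, 0, c, 0, 0)
        lim0 = 1 - crowding_fraction(base, 1.0, P)
        for kwargs in ({"M_phi": m + bump}, {"F": f + bump}, {"C": c + bump}):
            state = ModelState(**{**base.to_dict(), **kwargs})
            assert 1 - crowding_fraction(state, 1.0, P) < lim0


class TestTimpInhibition:
    @pytest.mark.parametrize("t_beta,expected", [(0.0, 1.0), (6.0, 0.5), (18.0, 0.25)])
    def test_hill_values(self, t_beta, expected):
        assert timp_inhibition(t_beta, P) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 100, 1000)
        assert np.all(np.diff(timp_inhibition(grid, P)) < 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            timp_inhibition(-1.0, P)


class TestActivationInput:
    def test_pulse_attains_amplitude_at_peak_day(self):
        stim = StimulusProfile(amplitude=15.0, peak_day=2.0)
        assert tgf_activation_input(2.0, stim, P) == pytest.approx(15.0 + P.u_T0)
        t = np.linspace(0.01, 30, 2000)
        assert stim.pulse(t).max() <= 15.0 + 1e-12

    def test_zero_amplitude_returns_baseline(self):
        stim = StimulusProfile(amplitude=0.0, peak_day=2.0)
        p = ModelParameters(u_T0=2.72)
        for t in (0.0, 2.0, 17.3):
            assert tgf_activation_input(t, stim, p) == pytest.approx(2.72)

    def test_tail_negligible_by_day_30(self):
        stim = StimulusProfile(amplitude=30.0, peak_day=2.0)
        assert stim.pulse(30.0) < 0.01 * 30.0

    def test_activation_small_after_day_7(self):
        # the expression profile it mimics returns to normal after day 7
        stim = StimulusProfile(amplitude=30.0, peak_day=2.0)
        assert stim.pulse(7.0) < 0.05 * 30.0

    def test_gamma_shape_also_peaks_at_peak_day(self):
        stim = StimulusProfile(amplitude=10.0, peak_day=3.0, shape="gamma", width=1.0)
        t = np.linspace(0.01, 30, 3000)
        values = stim.pulse(t)
        assert stim.pulse(3.0) == pytest.approx(10.0)
        assert values.max() <= 10.0 + 1e-12

    def test_pulse_zero_at_time_zero(self):
        assert StimulusProfile(amplitude=30.0).pulse(0.0) == 0.0


class TestRhs:
    def test_empty_state_is_absorbing(self, curves):
        zero = ModelState(0, 0, 0, 0, 0, 0, 0)
        d = rhs(0.0, zero, P, StimulusProfile(amplitude=0.0), InterventionSpec(), curves)
        assert np.allclose(d.as_array(), 0.0)

    def test_calibrated_baseline_zeroes_tgf_derivative(self, curves):
        p = P.replace(u_T0=calibrate_baseline_activation(P, 0.21))
        d = rhs(0.0, initial_state(), p, StimulusProfile(amplitude=0.0),
                InterventionSpec(), curves)
        assert abs(d.T_beta) < 1e-12

    def test_stimulus_peak_drives_tgf_up(self, curves):
        d = rhs(2.0, initial_state(), P, StimulusProfile(amplitude=30.0, peak_day=2.0),
                InterventionSpec(), curves)
        assert d.T_beta > 0

    def test_meaningfully_negative_state_rejected(self, curves):
        bad = ModelState(-1.0, 20, 0.21, 7.1, 839.5, 447.6, 0)
        with pytest.raises(ValueError, match="negative state"):
            rhs(0.0, bad, P, StimulusProfile(amplitude=0.0), InterventionSpec(), curves)

    def test_clamp_zeroes_mmp9_derivative_after_onset(self, curves):
        iv = InterventionSpec("clamp", 200.0, 1.0)
        before = rhs(0.5, initial_state(), P, StimulusProfile(amplitude=30.0), iv, curves)
        after = rhs(2.0, initial_state(), P, StimulusProfile(amplitude=30.0), iv, curves)
        assert before.M9A != 0.0
        assert after.M9A == 0.0

    def test_complex_loss_variant_changes_complex_balance(self, curves):
        s = initial_state()
        stim = StimulusProfile(amplitude=0.0)
        d_konc = rhs(0.0, s, P, stim, InterventionSpec(), curves)
        d_both = rhs(0.0, s, P, stim, InterventionSpec(), curves,
                     options=ModelOptions(complex_loss="koff+konc"))
        assert d_both.CM9 == pytest.approx(d_konc.CM9 - P.k_off * s.CM9)


def test_intervention_validation():
    with pytest.raises(ValueError):
        InterventionSpec("clamp", level=-1.0)
    with pytest.raises(ValueError):
        InterventionSpec("pulse")
    assert not InterventionSpec().active
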