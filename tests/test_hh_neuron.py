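"""Single-neuron dynamics: rate functions, currents, and bistability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isrnet import (
    HHParams,
    NeuronState,
    rate_constants,
    steady_state_gates,
    ionic_currents,
    membrane_rhs,
    find_resting_equilibrium,
    deterministic_orbit,
)


class TestRateConstants:
    def test_removable_singularities_match_analytic_limits(self):
        # L'Hopital limits of the alpha expressions at their singular points
        r25 = rate_constants(25.0)
        assert r25.alpha_m == pytest.approx(1.0, rel=1e-12)
        r10 = rate_constants(10.0)
        assert r10.alpha_n == pytest.approx(0.1, rel=1e-12)
        # continuity: approach from both sides within 1e-6 relative
        for dv in (1e-6, -1e-6, 1e-3, -1e-3):
            assert rate_constants(25.0 + dv).alpha_m == pytest.approx(1.0, rel=2e-4)
            assert rate_constants(10.0 + dv).alpha_n == pytest.approx(0.1, rel=2e-4)
        assert rate_constants(25.0 + 1e-6).alpha_m == pytest.approx(1.0, rel=1e-6)

    def test_classic_table_values(self):
        r0 = rate_constants(0.0)
        assert r0.beta_m == pytest.approx(4.0)
        assert r0.alpha_h == pytest.approx(0.07)
        assert r0.beta_n == pytest.approx(0.125)
        assert r0.alpha_m == pytest.approx(0.1 * 25 / (np.exp(2.5) - 1))

    @given(V=st.floats(min_value=-100.0, max_value=200.0))
    @settings(max_examples=200, deadline=None)
    def test_rates_nonnegative_and_finite(self, V):
        r = rate_constants(V)
        for val in r:
            assert np.isfinite(val)
            assert val >= 0

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            rate_constants(np.nan)
        with pytest.raises(ValueError):
            rate_constants(np.inf)

    def test_vectorized_matches_scalar(self):
        V = np.linspace(-80, 150, 47)
        vec = rate_constants(V)
        for i, v in enumerate(V):
            scal = rate_constants(float(v))
            for a, b in zip(vec, scal):
                assert a[i] == pytest.approx(float(b), rel=1e-14)


class TestIonicCurrents:
    def test_zero_gates_leave_only_leak(self, params):
        st_ = NeuronState(np.array([3.0]), np.zeros(1), np.zeros(1), np.zeros(1))
        cur = ionic_currents(st_, params)
        assert cur.G_Na == pytest.approx(0.0)
        assert cur.G_K == pytest.approx(0.0)
        assert cur.I_L == pytest.approx(0.3 * (3.0 - 10.6))

    def test_fully_open_sodium_conductance(self, params):
        st_ = NeuronState(np.array([0.0]), np.ones(1), np.ones(1), np.zeros(1))
        assert ionic_currents(st_, params).G_Na == pytest.approx(120.0)

    def test_zero_driving_force_at_reversal(self, params):
        st_ = NeuronState(np.array([params.E_Na]), np.full(1, 0.7),
                          np.full(1, 0.4), np.full(1, 0.3))
        assert ionic_currents(st_, params).I_Na == pytest.approx(0.0)


class TestMembraneRHS:
    def test_bias_only_when_gates_closed_at_leak_reversal(self, params):
        st_ = NeuronState(np.array([params.E_L]), np.zeros(1), np.zeros(1), np.zeros(1))
        assert membrane_rhs(st_, params) == pytest.approx(6.8)

    def test_term_by_term_hand_evaluation(self, params):
        # independent arithmetic on the membrane equation at a generic point
        V, m, h, n = 0.0, 0.05, 0.6, 0.32
        expected = (
            -120.0 * m**3 * h * (V - 115.0)
            - 36.0 * n**4 * (V + 12.0)
            - 0.3 * (V - 10.6)
            + 6.8
        )
        st_ = NeuronState(np.array([V]), np.array([m]), np.array([h]), np.array([n]))
        assert membrane_rhs(st_, params) == pytest.approx(expected, rel=1e-14)

    def test_rhs_vanishes_at_root_found_equilibrium(self, params, resting_state):
        # oracle: 4-D root-finder on the full vector field
        from scipy.optimize import root

        def field(y):
            s = NeuronState(np.array([y[0]]), np.array([y[1]]),
                            np.array([y[2]]), np.array([y[3]]))
            dm, dh, dn = (
                rate_constants(y[0]).alpha_m * (1 - y[1]) - rate_constants(y[0]).beta_m * y[1],
                rate_constants(y[0]).alpha_h * (1 - y[2]) - rate_constants(y[0]).beta_h * y[2],
                rate_constants(y[0]).alpha_n * (1 - y[3]) - rate_constants(y[0]).beta_n * y[3],
            )
            return [membrane_rhs(s, params).item(), dm.item(), dh.item(), dn.item()]

        sol = root(field, [5.0, 0.1, 0.4, 0.4], tol=1e-12)
        assert sol.success
        eq = resting_state
        assert sol.x[0] == pytest.approx(eq.V.item(), abs=1e-6)
        st_ = NeuronState(np.array([sol.x[0]]), np.array([sol.x[1]]),
                          np.array([sol.x[2]]), np.array([sol.x[3]]))
        assert membrane_rhs(st_, params) == pytest.approx(0.0, abs=1e-9)


class TestBistability:
    def test_rest_is_stationary_and_silent(self, resting_state):
        res = deterministic_orbit(resting_state, 5000.0)
        assert res.raster.n_spikes == 0
        assert res.final_state.V.item() == pytest.approx(resting_state.V.item(), abs=1e-6)

    def test_limit_cycle_spikes_with_constant_isi(self, limit_cycle_state):
        res = deterministic_orbit(limit_cycle_state, 5000.0)
        isis = np.diff(res.raster.spike_times[0])
        assert isis.size > 100
        assert isis.std() / isis.mean() < 1e-3

    def test_rate_independent_of_phase_on_cycle(self, limit_cycle_state):
        # advance along the cycle by a fraction of a period and remeasure
        quarter = deterministic_orbit(limit_cycle_state, 4.0).final_state
        r1 = deterministic_orbit(limit_cycle_state, 3000.0).raster.n_spikes
        r2 = deterministic_orbit(quarter, 3000.0).raster.n_spikes
        assert abs(r1 - r2) <= 1

    def test_kernel_rates_match_reference_implementation(self):
        from isrnet._kernel import _rates

        for v in np.linspace(-80.0, 150.0, 113):
            ref = rate_constants(float(v))
            ker = _rates.py_func(float(v))
            assert np.allclose(ker, [float(x) for x in ref], rtol=1e-12)
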